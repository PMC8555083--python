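# braintopo

Graph-topology analysis and deep-learning classification of functional
connectomes, built for two-group resting-state fMRI studies — for example,
distinguishing pediatric posttraumatic stress disorder (PTSD) from healthy
controls — together with a ground-truth synthetic-cohort generator so the
entire chain can be validated without access to clinical imaging data.

It is aimed at methods researchers who want a tested, seeded, end-to-end
reference implementation of this family of analyses: network neuroscientists
checking what a sparsity-thresholded, AUC-integrated topological feature set
can and cannot recover, and machine-learning practitioners who need a
leakage-free baseline for small-n neuroimaging classification.

## The analysis

For each subject with time series from N = 90 regions (AAL atlas):

1. **Preprocessing** — discard 10 initial volumes, linear detrend, zero-phase
   band-pass 0.01–0.08 Hz, regression on motion parameters and the global
   signal; subjects moving > 1.0 mm or > 1.0° in any direction are flagged.
2. **Network** — partial correlations p_ij = −Θ_ij/√(Θ_ii Θ_jj) from the
   Ledoit–Wolf-shrunk precision matrix Θ; binarized at every sparsity
   S ∈ {0.05, 0.06, …, 0.40} by keeping the top round(S·N(N−1)/2) edges
   by |p|.
3. **Topology** — per threshold: clustering Cp, harmonic-mean path length Lp
   (so Lp·Eglob ≡ 1 on disconnected graphs too), γ = Cp/⟨Cp_null⟩,
   λ = Lp/⟨Lp_null⟩ and σ = γ/λ against 100 Maslov–Sneppen degree-preserving
   rewired nulls, global/local efficiency, and nodal degree, betweenness and
   efficiency. Each metric's curve over S is integrated (trapezoid) into one
   AUC scalar → a fixed-order 277-dimensional feature vector
   (7 globals + 3 × 90 nodal).
4. **Classification** — stacked autoencoder 277–128–64–32–10 (greedy
   unsupervised pretraining, then supervised fine-tuning with a softmax label
   layer) encodes each subject to 10 dimensions; a linear SVM with C chosen
   by nested stratified 5-fold grid search over {10⁻³…10⁴} classifies;
   evaluation is stratified 10-fold CV reporting balanced accuracy
   = (sensitivity + specificity)/2. Significance comes from re-running the
   whole pipeline under permuted labels.
5. **Attribution** — from the fine-tuned network's weight matrices
   W1…W4, contributions are propagated backward from layer l4 (keeping the
   nodes holding > 50% of each layer's absolute-weight contribution) down to
   the 277 raw features; the top 10 are reported with anatomical names.

The synthetic cohort (default 33 vs 53 subjects, 200 volumes at TR = 2 s)
plants the group difference in the precision matrix: entries incident to five
designated regions are scaled by (1 + effect_size) in one group, so degree,
efficiency and betweenness of exactly those regions should separate the
groups — an answer key for every downstream stage. See `docs/methods.md`
for the generative model and its limits.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
small summaries to `results/` (bulky intermediates go to `scratch/`):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_extract_features.py --seed 1    # the slow stage, ~5 min
python analysis/03_classify.py --seed 1
python analysis/04_permutation_test.py --seed 1
python analysis/05_attribution.py --seed 1
python analysis/06_null_calibration.py --seed 1    # ~8 min
```

With seed 1 this prints, in order:

```
simulated 86 subjects (33 A / 53 B), 0 would fail the motion-exclusion rule
feature table: 86 subjects x 277 features in 229.9s -> scratch/analysis/features.tsv
balanced accuracy 92.3% (sensitivity 97.5%, specificity 87.0%) over 10-fold CV
observed balanced accuracy 87.1%, permutation p < 0.010101 (99 permutations)
planted effect regions recovered in top-10: 4/5
grand mean balanced accuracy 0.494; p > 0.05 in 20/20 runs
```

Reading: the classifier separates the planted groups far above chance (the
permutation run re-evaluates with reduced autoencoder epochs, hence its
slightly lower observed accuracy); the permutation p is at its floor — no
permuted labelling reached the observed accuracy. The attribution pass
places features of 4 of the 5 perturbed regions (Caudate nucleus L,
Inferior frontal gyrus opercular L, Fusiform gyrus R, Amygdala L) among its
top 10; the fifth is diluted among spillover neighbours. And the zero-effect
calibration batch sits at chance with non-significant permutation p in every
run, confirming the pipeline invents no signal under the null.

The same chain is available as one command with provenance:

```bash
braintopo run-all --seed 1 --out-dir runs/demo --n-perm 99
```

## Layout

- `src/braintopo/` — the library: `cohort` (synthetic generator),
  `timeseries` (preprocessing), `connectome` (partial correlation,
  thresholds), `topology` (metrics and nulls), `features`, `sae`,
  `classify`, `attribution`, `io`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — the model, its assumptions, parameter defaults,
  numerical conventions and limitations.
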