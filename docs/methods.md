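# Methods

`braintopo` re-creates, as tested code, a complete analysis chain for
two-group resting-state functional-connectome studies: ROI time series →
temporal preprocessing → partial-correlation network → binary graphs over a
sparsity grid → threshold-integrated topology features → stacked-autoencoder
(SAE) + linear-SVM classification with cross-validation and permutation
testing → backward weight-propagation attribution. Because the clinical
imaging data such studies use are not publicly deposited, the package ships a
synthetic-cohort generator with a known ground truth; every claim the test
suite makes is a claim about what the pipeline recovers from that ground
truth.

## The pipeline model

**Nodes and edges.** The brain is parcellated into N = 90 regions (the AAL
atlas labels ship with the package). The edge weight between two regions is
their *partial correlation* — the correlation of their time series
conditional on the other 88 regions — computed from the precision matrix Θ of
the column-standardized data as p_ij = −Θ_ij / √(Θ_ii Θ_jj). With ~190
retained frames and 90 regions the sample covariance is near-singular, so the
default estimation policy applies Ledoit–Wolf shrinkage before (pseudo-)
inversion; a `"none"` policy inverts the empirical covariance and refuses to
run when T < N + 2.

**Thresholding.** Each subject's |p| matrix is binarized at fixed *sparsity*
S (edge density): the top `round(S·N(N−1)/2)` upper-triangle entries by
absolute value become edges. Fixed density (rather than a fixed correlation
cutoff) makes graphs comparable across subjects. The grid is S = 0.05 to 0.40
inclusive in steps of 0.01 (36 values). Rounding is half-away-from-zero and
ties at the cut break by (row, column) index, so edge sets are
bit-reproducible; edge sets are nested across thresholds by construction.

**Graph metrics.** Per threshold the package computes the clustering
coefficient Cp (per-node 2·triangles/k(k−1), zero for degree < 2),
the *harmonic-mean* characteristic path length Lp — defined as the inverse of
the mean inverse shortest-path distance so that disconnected graphs stay
finite, which makes Lp·Eglob = 1 an exact identity — global and local
efficiency, and per-node degree, unnormalized Brandes betweenness and nodal
efficiency. Normalized clustering γ = Cp/⟨Cp_null⟩ and path length
λ = Lp/⟨Lp_null⟩ use an ensemble of M = 100 Maslov–Sneppen degree-preserving
rewired graphs per (subject, threshold), each applying 10·|E| successful
double-edge swaps (capped at 100·|E| attempts; graphs admitting no swap, such
as stars, yield copies with a warning). Small-worldness is σ = γ/λ; a
Watts–Strogatz ground-truth graph scores σ ≈ 4.5 against its rewired nulls,
comfortably above the σ > 1 selection bound. All swap/BFS kernels are
numba-compiled with bitset adjacency rows; a full cohort evaluates ~3·10⁵
null graphs in a few minutes on one core.

**Features.** Each metric's 36-point curve is integrated over S with the
trapezoidal rule into one threshold-independent AUC scalar. The feature
vector is fixed-order: 7 globals (Cp, Lp, γ, λ, σ, Eloc, Eglob) followed by
the degree, betweenness and efficiency blocks in atlas order — 7 + 3·90 = 277
features. σ is counted among the globals because 7 + 3N is the only layout
consistent with a 277-dimensional vector for N = 90.

**Classifier.** Outer evaluation is stratified 10-fold CV. Within each
training fold: features are z-scored with fold statistics (non-finite AUCs —
possible when a null ensemble has zero clustering — are imputed with the fold
median); an SAE with layers 277–128–64–32–10 (sigmoid activations) is greedily
pretrained (each autoencoder reconstructs the previous code with a linear
decoder under MSE, 30 epochs) and then fine-tuned end-to-end with a 2-unit
softmax label layer (cross-entropy, 100 epochs); both partitions are encoded
to the 10-dimensional bottleneck; and a linear SVM is fitted with C selected
from {10⁻³…10⁴} by inner stratified 5-fold CV maximizing balanced accuracy
(ties resolve to the smallest C, i.e. the strongest regularization). No
held-out subject influences any training statistic. Balanced accuracy is
(sensitivity + specificity)/2, computed per fold and averaged.

The optimizer is full-batch Adam at learning rate 10⁻². The rate matters:
at 10⁻³ with these epoch counts the network demonstrably undertrains — the
fine-tuning loss barely moves, and the attribution pass (below) degrades from
recovering 4 of 5 planted regions to ~1 of 5 — so 10⁻² is the default and
every result JSON echoes the configuration actually used.

**Significance.** The permutation test reruns the *entire* cross-validated
pipeline under randomly permuted labels and reports
p = #(permuted ≥ observed)/n_perm; ties count against significance, and a
zero count is reported as "< 1/n_perm" rather than p = 0. The study-scale
test uses 1000 permutations; desk-scale runs use 99 with reduced SAE epochs
(pretraining 5, fine-tuning 25), which changes the null's cost, not its
validity.

**Attribution.** From the fine-tuned interpretation model (one SAE trained on
the full cohort, distinct from the CV models), each node's contribution in a
layer is the sum of absolute weights into the *kept* set of the layer above,
normalized to sum to one. The pass seeds at l4 through W4 (all bottleneck
nodes kept; an option seeds from the label layer's positive-class row
instead), applies the minimal->50% retention rule, walks back through W3 and
W2, and scores all 277 raw features against the kept l2 set without a final
cut. Squared-weight contributions are available via an option. The ranking is
invariant to rescaling any weight matrix and equivariant under feature
permutation. The top-10 report maps features to "Nodal degree / betweenness /
efficiency" and full anatomical region names.

## The synthetic cohort: what it emulates and what it does not

The generator plants a *topological* group difference with a known answer
key. Both groups share one conditional-dependence structure: a Watts–Strogatz
support graph (90 nodes, mean degree 10, rewiring probability 0.1), chosen so
the estimated networks are genuinely small-world (σ > 1, the selection
criterion the pipeline assumes). Edge weights are two-tier: the ring-lattice
backbone edges are strong (|w| ~ U(0.9, 1.1)) and the long-range/rewired
edges weak (|w| ~ U(0.22, 0.30)), with random signs. This heavy-tailed
profile mirrors real connectomes (a backbone of strong short-range
connections plus weaker distributed ones) and guarantees every node — hence
every effect region — carries a comparable, recoverable dose of signal. The
two tiers were calibrated together so that two properties hold at once:
every support edge's partial correlation is individually detectable at
T = 2000 (support AUROC > 0.9), and the planted effect (below) survives the
whole pipeline at study scale. Homogeneous weights achieve the first and lose
the second; near-zero long-range weights do the reverse.

**The planted effect.** In group B every off-diagonal precision entry
incident to the five designated effect regions (defaults: indices 10, 25, 40,
55, 70 → IFGoperc.L, ORBsupmed.R, AMYG.L, FFG.R, CAU.L) is multiplied by
(1 + effect_size); the default effect_size is 3.0, a deliberately strong,
clearly-detectable perturbation. Positive definiteness comes from diagonal
dominance: the diagonal is the row-wise absolute off-diagonal sum *of the
perturbed matrix* plus a margin of 0.2, and — deliberately — both groups
share this one diagonal. A per-group diagonal would renormalize the
multiplicative effect almost entirely out of the partial correlations
(p_ij = −Θ_ij/√(Θ_ii Θ_jj) is scale-invariant per row); the shared diagonal
keeps both matrices diagonally dominant and confines the group difference
exactly to the off-diagonal rows/columns of the effect regions.

**Temporal structure.** Subject time series are multivariate normal rows with
covariance Σ = Θ⁻¹. At the level of the single-subject simulation primitive
the rows are i.i.d. (temporally white); at the cohort level the temporal
innovations are band-limited to the analysis band (0.01–0.08 Hz at TR = 2 s)
before spatial colouring, and rescaled to preserve Σ. The reason is
statistical, not cosmetic: band-passing *white* series at these acquisition
parameters keeps only ~28% of the spectrum, collapsing ~190 frames to ~53
effective samples and making the sample covariance rank-deficient — the
planted structure would be destroyed by the pipeline's own (correct)
filtering stage. Real BOLD fluctuations are themselves band-limited, so the
banded generator is the more faithful model. Motion traces are scaled random
walks (3 translations mm, 3 rotations degrees; severity 0.2 by default, so
subjects rarely violate the 1.0 mm/1.0° exclusion rule, which is exercised
separately in tests).

**What the generator does not model** — and therefore what passing tests do
not show about real data: hemodynamic response shape and its autocorrelation
beyond band-limiting, scanner drift and physiological noise (the detrend and
nuisance stages are exercised on clean surrogates), spatial heterogeneity of
SNR across regions, subject-level variation in network topology within a
group (all subjects of a group share one precision matrix; only the sampling
noise differs), and site/batch effects. Recovery results here bound what the
pipeline can do under favourable, correctly-specified conditions; they do not
certify performance on clinical data.

## Preprocessing conventions

The ROI-level chain is: discard the first 10 volumes → per-region linear
detrend → zero-phase 4th-order Butterworth band-pass 0.01–0.08 Hz
(`sosfiltfilt`) → least-squares nuisance regression on an intercept, the six
motion parameters (band-pass filtered with the same filter so they cannot
re-introduce excluded frequencies) and the global signal (ROI-level
surrogate: the across-region mean). WM/CSF surrogates can be supplied as
extra confound columns. Framewise displacement is the Power formulation:
the sum of absolute frame-to-frame translation changes plus rotation changes
converted to arc length on a 50 mm sphere, padded with a leading zero.
Motion *exclusion* is a separate, stricter-sounding rule — any frame with an
absolute realignment parameter above 1.0 mm or 1.0° (strict inequality)
flags the subject — matching the common practice of screening on absolute
parameters while reporting mean FD descriptively.

## Numerical and degenerate-case choices

- Lp of a graph with no finite-distance pair is +∞ (sentinel, with a
  warning); any metric curve containing a non-finite value integrates to +∞
  and is imputed downstream from training-fold medians.
- γ is +∞ when the null ensemble's mean clustering is zero (possible for
  very sparse graphs); handled by the same imputation route.
- The rewiring kernel uses an inline xorshift64* generator seeded per
  (subject, threshold, replicate) from a master seed; all randomness in the
  package flows from explicit seeds and the fused bitset path is tested to be
  bit-identical to the graph-returning reference path.
- Edge-count rounding, tie-breaking, fold construction and C tie-breaks are
  all deterministic and documented above, so repeated runs are byte-identical.

## Reduced problem sizes

Routine runs and the test suite use the following scaled-down settings,
chosen as the package's own desk-scale defaults:

- Permutation tests: 99 permutations with SAE epochs 5/25 on the
  planted-effect cohort (study scale: 1000 permutations, epochs 30/100).
- Null-calibration batch: 20 zero-effect cohorts of 12+12 subjects, grid
  step 0.05 (8 thresholds), 10 nulls per threshold, SAE 277–32–8,
  epochs 3/15, 4-fold outer CV, 39 permutations. At 39 permutations the
  smallest achievable p above zero is 1/39 ≈ 0.026, so "p > 0.05" is the
  event that at least two permuted accuracies reach the observed one — the
  test's operating characteristics are the same as at study scale.

## Known limitations

- The SAE is a plain sigmoid stack with full-batch Adam; no regularization
  beyond early architecture choices, no batching, no early stopping. This is
  adequate at n ≈ 86 but not a general-purpose deep-learning stack.
- The attribution formula (absolute-weight column sums through kept sets) is
  one reading of "contribution estimated from the weight matrix"; a
  squared-weight variant is provided, and the two can disagree on borderline
  features.
- Group labels enter the generator only through the precision perturbation;
  demographic covariates, and any analysis of them, are out of scope.
- Betweenness is unnormalized; since features are z-scored per training fold
  downstream, normalization would only rescale columns.
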