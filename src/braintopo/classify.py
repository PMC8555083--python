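"""Two-stage classification: SAE dimensionality reduction + linear SVM.

The pipeline is evaluated with stratified 10-fold outer cross-validation.
Inside every outer training fold: features are z-scored with that fold's
statistics (non-finite entries imputed with the fold median), the SAE is
pretrained and fine-tuned on the fold, both partitions are encoded to the
bottleneck, and a linear SVM is fitted with its regularization constant C
chosen by an inner stratified 5-fold grid search over
{1e-3, ..., 1e4} maximizing inner balanced accuracy (ties -> smallest C,
i.e. the strongest regularization).  No held-out subject influences any
training statistic.

Significance is assessed by a label-permutation test: the entire
procedure is re-run under permuted labels and the p value is the
fraction of permuted runs whose balanced accuracy is at least the
observed one (ties count against significance; a zero count is reported
as "< 1/n_perm").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from braintopo.sae import SaeConfig, SaeModel, encode, train_sae

DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3, 1e4)
DEFAULT_K_OUTER = 10
DEFAULT_K_INNER = 5
DEFAULT_N_PERMUTATIONS = 1000


def balanced_accuracy_from_rates(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy is the arithmetic mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


@dataclass(frozen=True)
class FoldResult:
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    chosen_c: float
    test_indices: np.ndarray


@dataclass(frozen=True)
class CvResult:
    folds: list[FoldResult]
    seed: int

    @property
    def balanced_accuracies(self) -> np.ndarray:
        return np.array([f.balanced_accuracy for f in self.folds])

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(self.balanced_accuracies.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([f.sensitivity for f in self.folds]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([f.specificity for f in self.folds]))

    def summary(self) -> dict:
        accs = self.balanced_accuracies
        return {
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "sd_balanced_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "per_fold": [
                {
                    "balanced_accuracy": f.balanced_accuracy,
                    "sensitivity": f.sensitivity,
                    "specificity": f.specificity,
                    "chosen_c": f.chosen_c,
                }
                for f in self.folds
            ],
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float
    seed: int
    n_permutations: int = field(default=0)

    def formatted_p(self) -> str:
        if self.p_value == 0:
            return f"< {1.0 / self.n_permutations:.6g}"
        return f"{self.p_value:.6g}"


@dataclass(frozen=True)
class Standardizer:
    """Training-fold z-scoring with median imputation of non-finite entries."""

    mean: np.ndarray
    sd: np.ndarray
    median: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=float)
        finite = np.isfinite(x)
        masked = np.where(finite, x, np.nan)
        median = np.nanmedian(masked, axis=0)
        median = np.where(np.isfinite(median), median, 0.0)
        filled = np.where(finite, x, median)
        mean = filled.mean(axis=0)
        sd = filled.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=mean, sd=sd, median=median)

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        filled = np.where(np.isfinite(x), x, self.median)
        return (filled - self.mean) / self.sd


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    pos = y_true == 1
    neg = y_true == 0
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else np.nan
    return balanced_accuracy_from_rates(sens, spec), sens, spec


def _linear_svc(c: float) -> SVC:
    # libsvm has no default iteration cap; degenerate inputs (e.g. saturated
    # codes under permuted labels) can otherwise spin for minutes at large C
    return SVC(kernel="linear", C=c, max_iter=200_000)


def train_svm_nested(
    z: np.ndarray,
    y: np.ndarray,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    k_inner: int = DEFAULT_K_INNER,
    seed: int = 0,
) -> tuple[SVC, float]:
    """Inner stratified CV grid search for C, then refit on all of ``z``.

    Ties in mean inner balanced accuracy resolve to the smallest C.  If a
    class has fewer members than ``k_inner`` the fold count is reduced
    with a warning.
    """
    y = np.asarray(y).astype(int)
    min_class = int(np.bincount(y, minlength=2).min())
    if min_class < 2:
        raise ValueError("each class needs at least 2 members for inner CV")
    k = min(k_inner, min_class)
    if k < k_inner:
        import warnings

        warnings.warn(
            f"reducing inner folds from {k_inner} to {k}: smallest class has "
            f"{min_class} members",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(z, y))
    grid = sorted(float(c) for c in c_grid)
    mean_scores = []
    for c in grid:
        scores = []
        for tr, te in splits:
            clf = _linear_svc(c).fit(z[tr], y[tr])
            scores.append(balanced_accuracy_score(y[te], clf.predict(z[te])))
        mean_scores.append(float(np.mean(scores)))
    best = int(np.argmax(mean_scores))  # first maximum = smallest C on ties
    chosen_c = grid[best]
    final = _linear_svc(chosen_c).fit(z, y)
    return final, chosen_c


def cross_validate_pipeline(
    x: np.ndarray,
    y: np.ndarray,
    k_outer: int = DEFAULT_K_OUTER,
    seed: int = 0,
    sae_config: SaeConfig | None = None,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    k_inner: int = DEFAULT_K_INNER,
) -> CvResult:
    """Stratified k-fold evaluation of the full SAE + SVM pipeline."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k_outer:
        raise ValueError(
            f"smallest class has {counts.min()} subjects, too few for "
            f"stratified {k_outer}-fold CV; use a smaller k_outer"
        )
    base_cfg = sae_config or SaeConfig()
    skf = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    for fold_i, (tr, te) in enumerate(skf.split(x, y)):
        std = Standardizer.fit(x[tr])
        x_tr, x_te = std.transform(x[tr]), std.transform(x[te])
        fold_cfg = SaeConfig(
            hidden_sizes=base_cfg.hidden_sizes,
            pretrain_epochs=base_cfg.pretrain_epochs,
            finetune_epochs=base_cfg.finetune_epochs,
            learning_rate=base_cfg.learning_rate,
            seed=base_cfg.seed + fold_i,
        )
        model = train_sae(x_tr, y[tr], fold_cfg)
        z_tr, z_te = encode(model, x_tr), encode(model, x_te)
        svm, chosen_c = train_svm_nested(z_tr, y[tr], c_grid, k_inner, seed=seed + fold_i)
        y_pred = svm.predict(z_te)
        bal, sens, spec = _rates(y[te], y_pred)
        folds.append(
            FoldResult(
                balanced_accuracy=bal,
                sensitivity=sens,
                specificity=spec,
                chosen_c=chosen_c,
                test_indices=te,
            )
        )
    return CvResult(folds=folds, seed=seed)


def fit_interpretation_model(
    x: np.ndarray, y: np.ndarray, sae_config: SaeConfig | None = None
) -> tuple[SaeModel, Standardizer]:
    """One SAE fine-tuned on the whole cohort, for the contribution report."""
    std = Standardizer.fit(x)
    model = train_sae(std.transform(x), np.asarray(y).astype(int),
                      sae_config or SaeConfig())
    return model, std


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    k_outer: int = DEFAULT_K_OUTER,
    sae_config: SaeConfig | None = None,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    k_inner: int = DEFAULT_K_INNER,
    observed: float | None = None,
) -> PermutationResult:
    """Full-pipeline label-permutation test of the balanced accuracy.

    Every permutation reruns the complete cross-validated pipeline on
    shuffled labels.  ``p = #(perm >= observed) / n_perm``; a permuted
    accuracy equal to the observed one counts against significance.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    y = np.asarray(y).astype(int)
    if observed is None:
        observed = cross_validate_pipeline(
            x, y, k_outer, seed, sae_config, c_grid, k_inner
        ).mean_balanced_accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        res = cross_validate_pipeline(
            x, y_perm, k_outer, seed + 1 + i, sae_config, c_grid, k_inner
        )
        null[i] = res.mean_balanced_accuracy
    p = float((null >= observed).sum()) / n_perm
    return PermutationResult(
        observed=float(observed),
        null_distribution=null,
        p_value=p,
        seed=seed,
        n_permutations=n_perm,
    )
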