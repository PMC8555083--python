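"""Partial-correlation network estimation and density thresholding.

The edge between two regions is their partial correlation: the
correlation conditional on all other regions, obtained from the
precision (inverse covariance) matrix of the column-standardized time
series as ``p_ij = -theta_ij / sqrt(theta_ii * theta_jj)``.  With 90
regions and ~190 retained frames the sample covariance is
near-singular, so the default policy applies Ledoit-Wolf shrinkage
before inversion; ``"none"`` inverts the empirical covariance and is
meant for long series.

Binarization is at fixed *sparsity* (edge density): the top
``round(S * N(N-1)/2)`` upper-triangle entries by absolute value become
edges, which makes graphs comparable across subjects at equal density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf

DEFAULT_SPARSITY_RANGE = (0.05, 0.40)
DEFAULT_SPARSITY_STEP = 0.01


@dataclass(frozen=True)
class PartialCorrMatrix:
    """Symmetric N x N partial-correlation edge weights, zero diagonal."""

    values: np.ndarray
    region_labels: list[str]
    shrinkage: str = "auto"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("partial-correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("partial correlations must lie in [-1, 1]")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if len(self.region_labels) != v.shape[0]:
            raise ValueError("region_labels length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary symmetric adjacency at a given sparsity, zero diagonal."""

    entries: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        e = np.asarray(self.entries)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("entries must be square")
        if not np.array_equal(e, e.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("entries must be binary")
        if np.any(np.diag(e) != 0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "entries", e.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.entries.sum()) // 2


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered sparsity thresholds; default 0.05..0.40 in steps of 0.01."""

    values: np.ndarray
    s_min: float
    s_max: float
    step: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size == 0:
            raise ValueError("sparsity grid is empty")
        if np.any(np.diff(v) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    def __iter__(self):
        return iter(self.values)


def sparsity_grid(
    s_min: float = DEFAULT_SPARSITY_RANGE[0],
    s_max: float = DEFAULT_SPARSITY_RANGE[1],
    step: float = DEFAULT_SPARSITY_STEP,
) -> SparsityGrid:
    """Inclusive arithmetic grid of sparsity values (defaults: 36 values)."""
    if not 0 < s_min <= s_max < 1:
        raise ValueError(f"need 0 < s_min <= s_max < 1, got ({s_min}, {s_max})")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((s_max - s_min) / step + 1e-9)) + 1
    values = s_min + step * np.arange(n)
    if values.size == 0 or (s_min != s_max and values.size < 2):
        raise ValueError("sparsity grid is empty for the given endpoints/step")
    return SparsityGrid(values=values, s_min=s_min, s_max=s_max, step=step)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def partial_correlation(ts, shrinkage: str = "auto") -> PartialCorrMatrix:
    """Estimate the partial-correlation matrix of an :class:`RoiTimeSeries`.

    ``shrinkage="auto"`` applies Ledoit-Wolf shrinkage to the covariance
    of the column-standardized data; ``"none"`` uses the empirical
    covariance and raises if there are too few timepoints for a stable
    inverse.
    """
    data = ts.data
    t, n = data.shape
    if t <= 2:
        raise ValueError("need more than 2 timepoints")
    if n < 2:
        raise ValueError("need at least 2 regions")
    sd = data.std(axis=0)
    if np.any(sd <= 1e-13 * (np.abs(data.mean(axis=0)) + 1)):
        bad = sd <= 1e-13 * (np.abs(data.mean(axis=0)) + 1)
        const = [ts.region_labels[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"constant columns cannot be correlated: {const}")
    z = (data - data.mean(axis=0)) / sd
    if shrinkage == "auto":
        cov, _ = ledoit_wolf(z, assume_centered=True)
    elif shrinkage == "none":
        if t < n + 2:
            raise ValueError(
                f"{t} timepoints are too few to invert a {n}x{n} covariance "
                "without regularization; use shrinkage='auto'"
            )
        cov = z.T @ z / t
    else:
        raise ValueError(f"unknown shrinkage policy {shrinkage!r}")
    theta = np.linalg.pinv(cov)
    d = np.sqrt(np.diag(theta))
    p = -theta / np.outer(d, d)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 0.0)
    np.clip(p, -1.0, 1.0, out=p)
    return PartialCorrMatrix(
        values=p, region_labels=list(ts.region_labels), shrinkage=shrinkage
    )


def binarize_at_sparsity(pc: PartialCorrMatrix, s: float) -> AdjacencyMatrix:
    """Keep the ``round(s * N(N-1)/2)`` strongest edges by |partial correlation|.

    Ties at the cut are broken by (row, column) index so results are
    identical across platforms.
    """
    if not 0 < s < 1:
        raise ValueError(f"sparsity must be in (0, 1), got {s}")
    n = pc.n_regions
    n_pairs = n * (n - 1) // 2
    k = _round_half_away(s * n_pairs)
    if k == 0:
        raise ValueError(f"sparsity {s} keeps zero edges for N={n}")
    iu = np.triu_indices(n, 1)
    weights = np.abs(pc.values[iu])
    # stable sort on descending |weight|; original (row-major) order breaks ties
    order = np.argsort(-weights, kind="stable")
    keep = order[:k]
    entries = np.zeros((n, n), dtype=np.int8)
    entries[iu[0][keep], iu[1][keep]] = 1
    entries = entries + entries.T
    return AdjacencyMatrix(entries=entries, sparsity=float(s))
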