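"""Synthetic two-group cohort generator.

Emulates a two-group resting-state study (default 33 vs 53 subjects, 90
regions, 200 volumes at TR = 2 s) in which the group difference lives in
network topology: both groups share a small-world conditional-dependence
structure (Watts-Strogatz support, mean degree 10, rewiring 0.1), and in
the non-reference group the precision-matrix entries incident to a set of
designated *effect regions* are multiplicatively scaled.  Downstream
stages can therefore be validated against a known ground truth.

Design of the precision matrices
--------------------------------
Edge weights are deliberately heavy-tailed: lattice (ring-neighbour)
edges of the Watts-Strogatz support carry strong weights, long-range and
rewired edges weak ones.  This mirrors the empirical observation that
functional connectomes have a backbone of strong short-range connections
plus many weaker distributed ones, and it gives every node -- hence
every effect region -- a comparable "dose" of recoverable signal.
Positive definiteness is enforced by diagonal dominance; both groups
share one diagonal (computed from the perturbed group's row sums), so
their matrices differ only in the off-diagonal entries incident to the
effect regions.

Subject time series are multivariate normal with covariance equal to the
inverse precision.  At the cohort level the innovations are band-limited
to the analysis band (0.01-0.08 Hz by default) before being coloured
spatially: resting-state BOLD is itself band-limited, and temporally
white series would have most of their variance discarded by the
band-pass stage of the preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import signal as _signal

from braintopo.atlas import load_atlas_labels
from braintopo.timeseries import MotionParams, RoiTimeSeries

DEFAULT_EFFECT_REGIONS = (10, 25, 40, 55, 70)

# weight scales for the backbone / long-range split of the support graph
_W_STRONG = (0.9, 1.1)
_W_WEAK = (0.22, 0.30)
_DIAGONAL_MARGIN = 0.2


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``effect_size`` is the relative perturbation of precision entries
    incident to ``effect_regions`` in group B: entries are multiplied by
    ``1 + effect_size``.  ``noise_sd`` adds white measurement noise on
    top of the network-structured signal (in units of the signal's
    standard deviation; 0 by default so the sample covariance converges
    to the inverse precision exactly).
    """

    n_group_a: int = 33
    n_group_b: int = 53
    n_regions: int = 90
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    effect_regions: tuple[int, ...] = DEFAULT_EFFECT_REGIONS
    effect_size: float = 3.0
    noise_sd: float = 0.0
    motion_severity: float = 0.2
    signal_band: tuple[float, float] | None = (0.01, 0.08)
    seed: int = 0
    ws_neighbors: int = 10
    ws_rewire_prob: float = 0.1
    region_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_regions", "n_timepoints"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.motion_severity < 0:
            raise ValueError("motion_severity must be non-negative")
        bad = [r for r in self.effect_regions if not 0 <= r < self.n_regions]
        if bad:
            raise ValueError(f"effect_regions out of range [0, {self.n_regions}): {bad}")
        if not self.region_labels:
            labels = (
                load_atlas_labels()
                if self.n_regions == 90
                else [f"R{i + 1:03d}" for i in range(self.n_regions)]
            )
            object.__setattr__(self, "region_labels", tuple(labels))
        if len(self.region_labels) != self.n_regions:
            raise ValueError("region_labels length must equal n_regions")


@dataclass(frozen=True)
class PrecisionSpec:
    """A group's ground-truth precision matrix and its edge support."""

    matrix: np.ndarray
    ground_truth_adjacency: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("precision matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("precision matrix must be symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("precision diagonal must be positive")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def partial_correlations(self) -> np.ndarray:
        """Analytic partial correlations implied by the precision matrix."""
        d = np.sqrt(np.diag(self.matrix))
        p = -self.matrix / np.outer(d, d)
        np.fill_diagonal(p, 0.0)
        return p


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    timeseries: RoiTimeSeries
    motion: MotionParams


def _base_weighted_support(config: CohortConfig) -> np.ndarray:
    """Signed, weighted upper-triangular support common to both groups."""
    n = config.n_regions
    rng = np.random.default_rng(config.seed)
    graph = nx.watts_strogatz_graph(
        n, config.ws_neighbors, config.ws_rewire_prob, seed=config.seed
    )
    support = np.triu(nx.to_numpy_array(graph), 1)
    idx = np.arange(n)
    circ = np.abs(np.subtract.outer(idx, idx))
    ring = np.minimum(circ, n - circ) == 1
    weights = np.where(
        ring,
        rng.uniform(*_W_STRONG, (n, n)),
        rng.uniform(*_W_WEAK, (n, n)),
    )
    signs = rng.choice([-1.0, 1.0], (n, n))
    m = support * weights * signs
    return m + m.T


def make_group_precision(config: CohortConfig, group: str) -> PrecisionSpec:
    """Build the ground-truth precision matrix for group ``"A"`` or ``"B"``.

    Group A is the reference; group B has off-diagonal entries incident
    to ``config.effect_regions`` scaled by ``1 + effect_size``.  Both
    groups receive the same diagonal (row-wise absolute off-diagonal sum
    of the perturbed matrix plus a fixed margin), which keeps both
    diagonally dominant and confines the group difference to the rows
    and columns of the effect regions.
    """
    if group not in ("A", "B"):
        raise ValueError(f"group must be 'A' or 'B', got {group!r}")
    base = _base_weighted_support(config)
    mask = np.zeros(config.n_regions, dtype=bool)
    mask[list(config.effect_regions)] = True
    incident = mask[:, None] | mask[None, :]
    np.fill_diagonal(incident, False)
    perturbed = base.copy()
    perturbed[incident] *= 1.0 + config.effect_size
    diagonal = np.abs(perturbed).sum(axis=1) + _DIAGONAL_MARGIN
    matrix = base.copy() if group == "A" else perturbed
    np.fill_diagonal(matrix, diagonal)
    eigmin = float(np.linalg.eigvalsh(matrix)[0])
    assert eigmin > 0, f"precision construction lost positive definiteness ({eigmin})"
    return PrecisionSpec(matrix=matrix, ground_truth_adjacency=(base != 0).astype(int))


def simulate_subject_timeseries(
    spec: PrecisionSpec,
    n_timepoints: int,
    seed: int,
    *,
    tr_seconds: float = 2.0,
    band: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    region_labels: list[str] | None = None,
) -> RoiTimeSeries:
    """Draw one subject's ROI time series from a precision spec.

    Rows are multivariate normal with covariance equal to the inverse of
    ``spec.matrix``.  With ``band=None`` (default) the rows are i.i.d.;
    with a band the temporal innovations are band-pass filtered first
    (and rescaled to unit variance), so the spatial covariance is
    preserved while the spectrum matches resting-state acquisition.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be at least 2")
    n = spec.n_regions
    rng = np.random.default_rng(seed)
    covariance = np.linalg.inv(spec.matrix)
    chol = np.linalg.cholesky(covariance)
    if band is None:
        innovations = rng.standard_normal((n_timepoints, n))
    else:
        pad = 60  # discard filter warm-up
        white = rng.standard_normal((n_timepoints + pad, n))
        sos = _signal.butter(
            4, band, btype="band", fs=1.0 / tr_seconds, output="sos"
        )
        filtered = _signal.sosfilt(sos, white, axis=0)[pad:]
        innovations = filtered / filtered.std(axis=0).mean()
    data = innovations @ chol.T
    if noise_sd > 0:
        data = data + noise_sd * data.std(axis=0, keepdims=True) * rng.standard_normal(
            data.shape
        )
    labels = (
        list(region_labels)
        if region_labels is not None
        else [f"R{i + 1:03d}" for i in range(n)]
    )
    return RoiTimeSeries(data=data, region_labels=labels, tr_seconds=tr_seconds)


def simulate_motion(n_timepoints: int, severity: float, seed: int) -> MotionParams:
    """Random-walk realignment-parameter trace (3 translations mm, 3 rotations deg).

    ``severity`` sets the typical endpoint amplitude of each parameter;
    0 gives an all-zero trace.
    """
    if severity < 0:
        raise ValueError("severity must be non-negative")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_timepoints, 6))
    trace = severity * np.cumsum(steps, axis=0) / np.sqrt(n_timepoints)
    if severity == 0:
        trace = np.zeros((n_timepoints, 6))
    return MotionParams(data=trace)


def _subject_seeds(config: CohortConfig, n: int) -> list[int]:
    ss = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=2 * n)
    return [int(s) for s in ss]


def simulate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Simulate the full two-group cohort, deterministically from ``config.seed``."""
    spec_a = make_group_precision(config, "A")
    spec_b = make_group_precision(config, "B")
    n_total = config.n_group_a + config.n_group_b
    seeds = _subject_seeds(config, n_total)
    records: list[SubjectRecord] = []
    for i in range(n_total):
        group = "A" if i < config.n_group_a else "B"
        spec = spec_a if group == "A" else spec_b
        ts = simulate_subject_timeseries(
            spec,
            config.n_timepoints,
            seeds[2 * i],
            tr_seconds=config.tr_seconds,
            band=config.signal_band,
            noise_sd=config.noise_sd,
            region_labels=list(config.region_labels),
        )
        motion = simulate_motion(
            config.n_timepoints, config.motion_severity, seeds[2 * i + 1]
        )
        records.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:03d}", group=group, timeseries=ts, motion=motion
            )
        )
    return records


def zero_effect(config: CohortConfig) -> CohortConfig:
    """The same study conditions with the group difference switched off."""
    return replace(config, effect_size=0.0)
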