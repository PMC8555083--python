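"""Global and nodal graph metrics over the sparsity grid.

Global metrics per binary graph: clustering coefficient Cp, harmonic-mean
characteristic path length Lp (finite on disconnected graphs; identically
``1 / Eglob``), normalized clustering gamma and path length lambda against
degree-preserving rewired null graphs, small-worldness sigma = gamma /
lambda, and local / global efficiency.  Nodal metrics: degree, Brandes
betweenness (unnormalized), and nodal efficiency.  Each metric's curve
over the sparsity grid is integrated with the trapezoidal rule into one
threshold-independent scalar (its AUC).

All-pairs shortest-path distances are computed by boolean matrix powers
(the graphs are small and dense enough that BLAS beats queue-based BFS),
and the Maslov-Sneppen double-edge swaps are numba-compiled: a cohort
run evaluates hundreds of thousands of null graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

from braintopo.connectome import (
    AdjacencyMatrix,
    PartialCorrMatrix,
    SparsityGrid,
    binarize_at_sparsity,
)

DEFAULT_NULL_ENSEMBLE_SIZE = 100
_SWAPS_PER_EDGE = 10
_MAX_ATTEMPT_FACTOR = 100

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eloc", "Eglob")
NODAL_METRIC_NAMES = ("degree", "betweenness", "efficiency")


@dataclass(frozen=True)
class GlobalMetrics:
    c_p: float
    l_p: float
    gamma: float
    lambda_: float
    sigma: float
    e_loc: float
    e_glob: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.c_p, self.l_p, self.gamma, self.lambda_, self.sigma,
                self.e_loc, self.e_glob)


@dataclass(frozen=True)
class NodalMetrics:
    degree: np.ndarray
    betweenness: np.ndarray
    efficiency: np.ndarray


@dataclass(frozen=True)
class ThresholdedMetricCurves:
    """Per-threshold metric records for one subject."""

    grid: SparsityGrid
    global_metrics: list[GlobalMetrics]
    nodal_metrics: list[NodalMetrics]
    null_ensemble_size: int
    seed: int
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.global_metrics) != len(self.grid):
            raise ValueError("one GlobalMetrics record per grid value required")
        if len(self.nodal_metrics) != len(self.grid):
            raise ValueError("one NodalMetrics record per grid value required")
        if self.null_ensemble_size < 1:
            raise ValueError("null_ensemble_size must be >= 1")


@njit(cache=True)
def _apsp_bfs(adj):
    """All-pairs unweighted shortest-path distances by repeated BFS."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    order = np.empty(n, np.int64)
    level = np.empty(n, np.int64)
    for s in range(n):
        for j in range(n):
            level[j] = -1
        level[s] = 0
        order[0] = s
        head, tail = 0, 1
        while head < tail:
            u = order[head]
            head += 1
            du = level[u]
            for j in range(n):
                if adj[u, j] and level[j] < 0:
                    level[j] = du + 1
                    order[tail] = j
                    tail += 1
        for j in range(n):
            if level[j] >= 0:
                dist[s, j] = level[j]
    return dist


@njit(cache=True)
def _cp_eglob_jit(adj):
    """(mean clustering, global efficiency) of a boolean adjacency matrix."""
    n = adj.shape[0]
    # adjacency lists (CSR-style) so BFS is O(N + E) per source
    deg = np.zeros(n, np.int64)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                deg[i] += 1
    offset = np.zeros(n + 1, np.int64)
    for i in range(n):
        offset[i + 1] = offset[i] + deg[i]
    nbr = np.empty(offset[n], np.int64)
    fill = offset[:n].copy()
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                nbr[fill[i]] = j
                fill[i] += 1
    cp_sum = 0.0
    for i in range(n):
        k = deg[i]
        if k >= 2:
            links = 0
            for a in range(offset[i], offset[i + 1]):
                ja = nbr[a]
                for b in range(a + 1, offset[i + 1]):
                    if adj[ja, nbr[b]]:
                        links += 1
            cp_sum += 2.0 * links / (k * (k - 1))
    inv_sum = 0.0
    level = np.empty(n, np.int64)
    order = np.empty(n, np.int64)
    for s in range(n):
        for j in range(n):
            level[j] = -1
        level[s] = 0
        order[0] = s
        head, tail = 0, 1
        while head < tail:
            u = order[head]
            head += 1
            du = level[u]
            for e in range(offset[u], offset[u + 1]):
                j = nbr[e]
                if level[j] < 0:
                    level[j] = du + 1
                    order[tail] = j
                    tail += 1
        for j in range(n):
            if level[j] > 0:
                inv_sum += 1.0 / level[j]
    return cp_sum / n, inv_sum / (n * (n - 1))


def shortest_path_distances(entries: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf for disconnected)."""
    return _apsp_bfs(np.ascontiguousarray(np.asarray(entries) != 0))


def clustering_coefficient(a: AdjacencyMatrix) -> tuple[float, np.ndarray]:
    """Mean and per-node clustering: 2*triangles_i / (k_i (k_i - 1)), 0 if k_i < 2."""
    m = a.entries.astype(np.float64)
    k = m.sum(axis=1)
    closed = np.diag(m @ m @ m)  # 2 * triangles per node
    denom = k * (k - 1)
    nodal = np.divide(closed, denom, out=np.zeros_like(closed), where=denom > 0)
    return float(nodal.mean()), nodal


@njit(cache=True)
def _local_efficiency_jit(adj):
    """Mean over nodes of the neighborhood subgraph's global efficiency."""
    n = adj.shape[0]
    total = 0.0
    nbrs = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[k] = j
                k += 1
        if k < 2:
            continue
        sub = np.empty((k, k), np.bool_)
        for a in range(k):
            for b in range(k):
                sub[a, b] = adj[nbrs[a], nbrs[b]]
        _, eg = _cp_eglob_jit(sub)
        total += eg
    return total / n


def _efficiency_terms(entries: np.ndarray) -> np.ndarray:
    dist = shortest_path_distances(entries)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return inv


def efficiencies(a: AdjacencyMatrix) -> tuple[float, float, np.ndarray]:
    """(global efficiency, local efficiency, per-node efficiency).

    Nodal efficiency of i is the mean of 1/d_ij over j != i; local
    efficiency averages the global efficiency of each node's
    neighborhood subgraph (0 for degree < 2).
    """
    n = a.n_nodes
    inv = _efficiency_terms(a.entries)
    nodal_efficiency = inv.sum(axis=1) / (n - 1)
    e_glob = float(nodal_efficiency.mean())
    e_loc = float(_local_efficiency_jit(np.ascontiguousarray(a.entries != 0)))
    return e_glob, e_loc, nodal_efficiency


def characteristic_path_length_harmonic(a: AdjacencyMatrix) -> float:
    """Harmonic-mean path length: inverse of the mean inverse distance.

    Finite on disconnected graphs (1/inf = 0 for unreachable pairs);
    an edgeless graph has no finite-distance pair and returns inf.
    """
    e_glob, _, _ = efficiencies(a)
    if e_glob == 0:
        warnings.warn("graph has no finite-distance pairs; Lp is infinite",
                      stacklevel=2)
        return np.inf
    return 1.0 / e_glob


def nodal_degree_betweenness(a: AdjacencyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Row-sum degrees and unnormalized Brandes betweenness (endpoints excluded)."""
    degree = a.entries.sum(axis=1).astype(np.float64)
    graph = nx.from_numpy_array(a.entries)
    bc = nx.betweenness_centrality(graph, normalized=False)
    betweenness = np.array([bc[i] for i in range(a.n_nodes)])
    return degree, betweenness


@njit(cache=True)
def _rng_init(seed):
    """SplitMix64 scramble of the seed into a nonzero xorshift64 state."""
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    if z == 0:
        z = np.uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True)
def _rng_next(state):
    """xorshift64 step; returns the new state (also the random value)."""
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True)
def _double_edge_swaps(adj, edges_u, edges_v, target_swaps, max_attempts, seed):
    state = _rng_init(seed)
    n_edges = np.uint64(edges_u.shape[0])
    swaps = 0
    attempts = 0
    while swaps < target_swaps and attempts < max_attempts:
        attempts += 1
        state = _rng_next(state)
        e1 = int(state % n_edges)
        state = _rng_next(state)
        e2 = int(state % n_edges)
        if e1 == e2:
            continue
        a, b = edges_u[e1], edges_v[e1]
        c, d = edges_u[e2], edges_v[e2]
        state = _rng_next(state)
        if state & np.uint64(1):
            c, d = d, c
        # propose a-d, c-b replacing a-b, c-d
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges_v[e1] = d
        edges_u[e2] = c
        edges_v[e2] = b
        swaps += 1
    return swaps


def random_null_ensemble(
    a: AdjacencyMatrix, m: int = DEFAULT_NULL_ENSEMBLE_SIZE, seed: int = 0
) -> list[AdjacencyMatrix]:
    """Degree-preserving rewired surrogates (Maslov-Sneppen double-edge swaps).

    Each surrogate applies ``10 * |edges|`` successful swaps (capped at
    ``100 * |edges|`` attempts).  Graphs admitting no swap (e.g., stars)
    come back as copies with a warning.
    """
    if m < 1:
        raise ValueError("ensemble size must be >= 1")
    if a.n_edges < 2:
        raise ValueError("graph needs at least 2 edges to rewire")
    iu = np.triu_indices(a.n_nodes, 1)
    present = a.entries[iu] > 0
    base_u = iu[0][present].astype(np.int64)
    base_v = iu[1][present].astype(np.int64)
    target = _SWAPS_PER_EDGE * a.n_edges
    max_attempts = _MAX_ATTEMPT_FACTOR * a.n_edges
    seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31 - 1)
    ensemble: list[AdjacencyMatrix] = []
    no_swap = 0
    for i in range(m):
        adj = a.entries.astype(np.bool_)
        swaps = _double_edge_swaps(
            adj, base_u.copy(), base_v.copy(), target, max_attempts, int(seeds[i])
        )
        if swaps == 0:
            no_swap += 1
        ensemble.append(
            AdjacencyMatrix(entries=adj.astype(np.int8), sparsity=a.sparsity)
        )
    if no_swap:
        warnings.warn(
            f"{no_swap}/{m} null graphs admitted no double-edge swap; "
            "returned copies of the input",
            stacklevel=2,
        )
    return ensemble


def _cp_lp(entries: np.ndarray) -> tuple[float, float]:
    """Fast (Cp, Lp-harmonic) used for null ensembles."""
    cp, e_glob = _cp_eglob_jit(np.ascontiguousarray(entries != 0))
    l_p = np.inf if e_glob == 0 else 1.0 / e_glob
    return float(cp), float(l_p)


@njit(cache=True)
def _popcount64(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> np.uint64(2)) & np.uint64(0x3333333333333333)
    )
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(cache=True)
def _bit_test(bits, i, j):
    return (bits[i, j >> 6] >> np.uint64(j & 63)) & np.uint64(1) != 0


@njit(cache=True)
def _bit_flip(bits, i, j, on):
    if on:
        bits[i, j >> 6] |= np.uint64(1) << np.uint64(j & 63)
    else:
        bits[i, j >> 6] &= ~(np.uint64(1) << np.uint64(j & 63))


@njit(cache=True)
def _double_edge_swaps_bits(bits, edges_u, edges_v, target, max_attempts, seed):
    """Same proposal sequence as :func:`_double_edge_swaps`, on bitset rows."""
    state = _rng_init(seed)
    n_edges = np.uint64(edges_u.shape[0])
    swaps = 0
    attempts = 0
    while swaps < target and attempts < max_attempts:
        attempts += 1
        state = _rng_next(state)
        e1 = int(state % n_edges)
        state = _rng_next(state)
        e2 = int(state % n_edges)
        if e1 == e2:
            continue
        a, b = edges_u[e1], edges_v[e1]
        c, d = edges_u[e2], edges_v[e2]
        state = _rng_next(state)
        if state & np.uint64(1):
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if _bit_test(bits, a, d) or _bit_test(bits, c, b):
            continue
        _bit_flip(bits, a, b, False)
        _bit_flip(bits, b, a, False)
        _bit_flip(bits, c, d, False)
        _bit_flip(bits, d, c, False)
        _bit_flip(bits, a, d, True)
        _bit_flip(bits, d, a, True)
        _bit_flip(bits, c, b, True)
        _bit_flip(bits, b, c, True)
        edges_v[e1] = d
        edges_u[e2] = c
        edges_v[e2] = b
        swaps += 1
    return swaps


@njit(cache=True)
def _cp_eglob_bits(bits, n):
    """(mean clustering, global efficiency) from bitset adjacency rows."""
    n_words = bits.shape[1]
    cp_sum = 0.0
    for i in range(n):
        k = 0
        for w in range(n_words):
            k += int(_popcount64(bits[i, w]))
        if k >= 2:
            links2 = 0
            for w in range(n_words):
                word = bits[i, w]
                while word != 0:
                    j = (w << 6) + int(np.log2(word & (~word + np.uint64(1))))
                    t = 0
                    for w2 in range(n_words):
                        t += int(_popcount64(bits[i, w2] & bits[j, w2]))
                    links2 += t
                    word &= word - np.uint64(1)
            cp_sum += links2 / (k * (k - 1))
    inv_sum = 0.0
    frontier = np.empty(n_words, np.uint64)
    visited = np.empty(n_words, np.uint64)
    nxt = np.empty(n_words, np.uint64)
    for s in range(n):
        for w in range(n_words):
            frontier[w] = np.uint64(0)
            visited[w] = np.uint64(0)
        frontier[s >> 6] = np.uint64(1) << np.uint64(s & 63)
        visited[s >> 6] = frontier[s >> 6]
        depth = 1
        while True:
            reached = 0
            for w in range(n_words):
                nxt[w] = np.uint64(0)
            for w in range(n_words):
                word = frontier[w]
                while word != 0:
                    u = (w << 6) + int(np.log2(word & (~word + np.uint64(1))))
                    for w2 in range(n_words):
                        nxt[w2] |= bits[u, w2]
                    word &= word - np.uint64(1)
            for w in range(n_words):
                nxt[w] &= ~visited[w]
                reached += int(_popcount64(nxt[w]))
            if reached == 0:
                break
            inv_sum += reached / depth
            for w in range(n_words):
                visited[w] |= nxt[w]
                frontier[w] = nxt[w]
            depth += 1
    return cp_sum / n, inv_sum / (n * (n - 1))


@njit(cache=True)
def _rewired_null_stats(bits_base, n, edges_u, edges_v, target, max_attempts, seeds):
    """(Cp, Eglob) of each rewired surrogate; fused bitset loop for speed."""
    m = seeds.shape[0]
    out = np.empty((m, 2))
    for i in range(m):
        bits = bits_base.copy()
        u = edges_u.copy()
        v = edges_v.copy()
        _double_edge_swaps_bits(bits, u, v, target, max_attempts, seeds[i])
        cp, eg = _cp_eglob_bits(bits, n)
        out[i, 0] = cp
        out[i, 1] = eg
    return out


def _to_bits(entries: np.ndarray) -> np.ndarray:
    n = entries.shape[0]
    n_words = (n + 63) // 64
    bits = np.zeros((n, n_words), dtype=np.uint64)
    rows, cols = np.nonzero(entries)
    for i, j in zip(rows, cols):
        bits[i, j >> 6] |= np.uint64(1) << np.uint64(j & 63)
    return bits


def null_cp_lp_means(
    a: AdjacencyMatrix, m: int, seed: int
) -> tuple[float, float]:
    """Ensemble means of (Cp, Lp-harmonic) over m rewired surrogates.

    Numerically identical to running :func:`random_null_ensemble` and
    averaging, but without materializing the graphs.
    """
    if a.n_edges < 2:
        raise ValueError("graph needs at least 2 edges to rewire")
    iu = np.triu_indices(a.n_nodes, 1)
    present = a.entries[iu] > 0
    base_u = iu[0][present].astype(np.int64)
    base_v = iu[1][present].astype(np.int64)
    seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31 - 1)
    stats = _rewired_null_stats(
        _to_bits(a.entries),
        a.n_nodes,
        base_u,
        base_v,
        _SWAPS_PER_EDGE * a.n_edges,
        _MAX_ATTEMPT_FACTOR * a.n_edges,
        seeds.astype(np.int64),
    )
    cps = stats[:, 0]
    lps = np.where(stats[:, 1] > 0, 1.0 / stats[:, 1], np.inf)
    return float(cps.mean()), float(lps.mean())


def _normalize_small_world(
    c_p: float, l_p: float, mean_cp_null: float, mean_lp_null: float
) -> tuple[float, float, float]:
    if mean_cp_null == 0:
        warnings.warn("null ensemble has zero mean clustering; gamma is infinite",
                      stacklevel=2)
        gamma = np.inf
    else:
        gamma = c_p / mean_cp_null
    lambda_ = l_p / mean_lp_null
    sigma = gamma / lambda_
    return float(gamma), float(lambda_), float(sigma)


def small_world_indices(
    a: AdjacencyMatrix, nulls: list[AdjacencyMatrix]
) -> tuple[float, float, float]:
    """gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null>, sigma = gamma/lambda."""
    if not nulls:
        raise ValueError("null ensemble must be non-empty")
    c_p, _ = clustering_coefficient(a)
    l_p = characteristic_path_length_harmonic(a)
    null_stats = np.array([_cp_lp(n.entries) for n in nulls])
    return _normalize_small_world(
        c_p, l_p, null_stats[:, 0].mean(), null_stats[:, 1].mean()
    )


def auc_over_grid(values, grid: SparsityGrid) -> float:
    """Trapezoidal integral of a metric curve over the sparsity grid."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(grid):
        raise ValueError("need exactly one value per grid point")
    if len(grid) < 2:
        raise ValueError("grid must have at least 2 points for an AUC")
    if not np.all(np.isfinite(values)):
        warnings.warn("non-finite metric values; AUC is infinite", stacklevel=2)
        return np.inf
    return float(np.trapezoid(values, grid.values))


def compute_metric_curves(
    pc: PartialCorrMatrix,
    grid: SparsityGrid,
    null_ensemble_size: int = DEFAULT_NULL_ENSEMBLE_SIZE,
    seed: int = 0,
) -> ThresholdedMetricCurves:
    """Binarize at every grid sparsity and evaluate all metrics.

    Null ensembles for gamma/lambda/sigma are seeded per threshold from
    ``seed`` so curves are reproducible in isolation.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(len(grid)) % (2**31 - 1)
    globals_: list[GlobalMetrics] = []
    nodals: list[NodalMetrics] = []
    for i, s in enumerate(grid):
        adj = binarize_at_sparsity(pc, float(s))
        c_p, _ = clustering_coefficient(adj)
        e_glob, e_loc, nodal_eff = efficiencies(adj)
        l_p = np.inf if e_glob == 0 else 1.0 / e_glob
        degree, betweenness = nodal_degree_betweenness(adj)
        mean_cp_null, mean_lp_null = null_cp_lp_means(
            adj, null_ensemble_size, int(child_seeds[i])
        )
        gamma, lambda_, sigma = _normalize_small_world(
            c_p, l_p, mean_cp_null, mean_lp_null
        )
        globals_.append(
            GlobalMetrics(c_p=c_p, l_p=l_p, gamma=gamma, lambda_=lambda_,
                          sigma=sigma, e_loc=e_loc, e_glob=e_glob)
        )
        nodals.append(
            NodalMetrics(degree=degree, betweenness=betweenness,
                         efficiency=nodal_eff)
        )
    return ThresholdedMetricCurves(
        grid=grid,
        global_metrics=globals_,
        nodal_metrics=nodals,
        null_ensemble_size=null_ensemble_size,
        seed=seed,
        region_labels=list(pc.region_labels),
    )
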