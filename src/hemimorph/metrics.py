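"""Graph metrics of binary hemispheric networks.

Global metrics: characteristic path length Lp (harmonic mean of shortest path
lengths, hence finite on disconnected graphs), clustering coefficient Cp,
global efficiency (mean inverse distance; note Lp * E_global = 1 identically
with the harmonic-mean definition), local efficiency (mean over nodes of the
global efficiency of each node's neighbour subgraph), and the small-world
indices lambda = Lp/L_ran, gamma = Cp/C_ran, sigma = gamma/lambda obtained by
normalising against degree-preserving (Maslov–Sneppen) rewired surrogates.
Local metrics: degree centrality and nodal efficiency (mean inverse distance
from a node to all others).

Unreachable pairs contribute 0 to every inverse-distance sum.  Shortest paths
are computed by breadth-first expansion expressed as boolean matrix products,
which is exact for unweighted graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RandomizationConfig",
    "GlobalMetrics",
    "all_pairs_distances",
    "characteristic_path_length",
    "clustering_coefficient",
    "global_efficiency",
    "local_efficiency",
    "degree_centrality",
    "nodal_efficiency",
    "rewire_random",
    "normalize_and_sigma",
    "compute_global_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RandomizationConfig:
    """Degree-preserving rewiring used for L_ran / C_ran normalisation."""

    n_random: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass(frozen=True)
class GlobalMetrics:
    lp: float
    cp: float
    e_global: float
    e_local: float
    l_ran: float | None = None
    c_ran: float | None = None
    lam: float | None = None      # Lp / L_ran
    gamma: float | None = None    # Cp / C_ran
    sigma: float | None = None    # gamma / lambda


def _check_binary(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("adjacency must be binary")
    return a.astype(np.uint8)


def all_pairs_distances(a: np.ndarray, validate: bool = True) -> np.ndarray:
    """Unweighted all-pairs shortest path lengths; unreachable pairs are inf."""
    if validate:
        a = _check_binary(a)
    n = a.shape[0]
    reach = a.astype(bool) | np.eye(n, dtype=bool)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[a.astype(bool)] = 1.0
    step = 1
    frontier = reach.astype(np.float32)
    adj = a.astype(np.float32)
    while True:
        new_reach = (frontier @ adj) > 0
        newly = new_reach & ~reach
        if not newly.any():
            break
        step += 1
        dist[newly] = step
        reach |= newly
        frontier = reach.astype(np.float32)
    return dist


def characteristic_path_length(dist: np.ndarray) -> float:
    """Harmonic-mean path length: [mean of 1/L_ij over ordered pairs]^-1."""
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    inv = _inverse_offdiag(dist)
    s = inv.sum()
    if s == 0:
        return float("inf")
    return n * (n - 1) / float(s)


def _inverse_offdiag(dist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0   # diagonal zeros and unreachable pairs
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(dist: np.ndarray) -> float:
    """Mean inverse shortest path length over ordered pairs."""
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return float(_inverse_offdiag(dist).sum() / (n * (n - 1)))


def nodal_efficiency(dist: np.ndarray) -> np.ndarray:
    """Per node: mean of 1/L_ij over the other N-1 nodes."""
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return _inverse_offdiag(dist).sum(axis=1) / (n - 1)


def degree_centrality(a: np.ndarray) -> np.ndarray:
    a = _check_binary(a)
    return a.sum(axis=1).astype(np.int64)


def clustering_coefficient(a: np.ndarray) -> float:
    """Mean over nodes of 2*E_i / (k_i (k_i - 1)); k_i < 2 contributes 0."""
    a = _check_binary(a)
    af = a.astype(np.float32)
    k = a.sum(axis=1).astype(np.float64)
    triangles = np.einsum("ii->i", af @ af @ af).astype(np.float64)  # 2*E_i per node
    denom = k * (k - 1)
    ci = np.where(denom > 0, triangles / np.maximum(denom, 1), 0.0)
    return float(ci.mean())


def _local_efficiency_numpy(a: np.ndarray) -> float:
    n = a.shape[0]
    abool = a.astype(bool)
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(abool[i])
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = all_pairs_distances(sub, validate=False)
        total += global_efficiency(d)
    return total / n


def local_efficiency(a: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbour subgraph."""
    a = _check_binary(a)
    if _HAVE_NUMBA:
        return float(_local_eff_bitset(a))
    return _local_efficiency_numpy(a)


# ---------------------------------------------------------------------------
# degree-preserving randomization
# ---------------------------------------------------------------------------

def _swap_kernel_python(a, edges, n_attempts, seed):
    rng = np.random.default_rng(seed)
    n_success = 0
    E = edges.shape[0]
    r_edges = rng.integers(0, E, size=(n_attempts, 2))
    r_flip = rng.integers(0, 2, size=n_attempts)
    for t in range(n_attempts):
        e1, e2 = r_edges[t]
        x, y = edges[e1]
        u, v = edges[e2]
        if r_flip[t]:
            u, v = v, u
        if x == u or x == v or y == u or y == v:
            continue
        if a[x, v] or a[u, y]:
            continue
        a[x, y] = a[y, x] = 0
        a[u, v] = a[v, u] = 0
        a[x, v] = a[v, x] = 1
        a[u, y] = a[y, u] = 1
        edges[e1, 0] = x
        edges[e1, 1] = v
        edges[e2, 0] = u
        edges[e2, 1] = y
        n_success += 1
    return n_success


#: de Bruijn index table for a branch-free count-trailing-zeros on uint64.
_CTZ_TABLE = np.array([
    0, 1, 48, 2, 57, 49, 28, 3, 61, 58, 50, 42, 38, 29, 17, 4,
    62, 55, 59, 36, 53, 51, 43, 22, 45, 39, 33, 30, 24, 18, 12, 5,
    63, 47, 56, 27, 60, 41, 37, 16, 54, 35, 52, 21, 44, 32, 23, 11,
    46, 26, 40, 15, 34, 20, 31, 10, 25, 14, 19, 9, 13, 8, 7, 6,
], dtype=np.int64)
_DEBRUIJN = np.uint64(0x03F79D71B4CB0A89)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=False)
    def _swap_kernel_numba(a, edges, n_attempts, seed):  # pragma: no cover
        np.random.seed(seed)
        n_success = 0
        E = edges.shape[0]
        for _ in range(n_attempts):
            e1 = np.random.randint(0, E)
            e2 = np.random.randint(0, E)
            x, y = edges[e1, 0], edges[e1, 1]
            u, v = edges[e2, 0], edges[e2, 1]
            if np.random.randint(0, 2) == 1:
                u, v = v, u
            if x == u or x == v or y == u or y == v:
                continue
            if a[x, v] or a[u, y]:
                continue
            a[x, y] = 0
            a[y, x] = 0
            a[u, v] = 0
            a[v, u] = 0
            a[x, v] = 1
            a[v, x] = 1
            a[u, y] = 1
            a[y, u] = 1
            edges[e1, 0] = x
            edges[e1, 1] = v
            edges[e2, 0] = u
            edges[e2, 1] = y
            n_success += 1
        return n_success

    @njit(cache=False)
    def _local_eff_bitset(a):  # pragma: no cover - numba-compiled
        """Exact local efficiency via per-node bitset breadth-first search.

        For every node the induced neighbour subgraph is packed into uint64
        bitset rows; BFS frontiers are expanded word-wise, counting newly
        reached vertices per distance ring, which yields the subgraph's mean
        inverse distance without materialising a distance matrix.
        """
        n = a.shape[0]
        one = np.uint64(1)
        words_max = (n + 63) >> 6
        nbrs = np.empty(n, np.int64)
        rows = np.zeros((n, words_max), np.uint64)
        visited = np.zeros(words_max, np.uint64)
        frontier = np.zeros(words_max, np.uint64)
        nxt = np.zeros(words_max, np.uint64)
        total = 0.0
        for i in range(n):
            k = 0
            for j in range(n):
                if a[i, j]:
                    nbrs[k] = j
                    k += 1
            if k < 2:
                continue
            kw = (k + 63) >> 6
            for p in range(k):
                for w in range(kw):
                    rows[p, w] = 0
            for p in range(k):
                ap = nbrs[p]
                for q in range(p + 1, k):
                    if a[ap, nbrs[q]]:
                        rows[p, q >> 6] |= one << np.uint64(q & 63)
                        rows[q, p >> 6] |= one << np.uint64(p & 63)
            inv_sum = 0.0
            for s in range(k):
                for w in range(kw):
                    visited[w] = 0
                    frontier[w] = 0
                visited[s >> 6] = one << np.uint64(s & 63)
                frontier[s >> 6] = visited[s >> 6]
                d = 0
                while True:
                    for w in range(kw):
                        nxt[w] = 0
                    for w in range(kw):
                        fw = frontier[w]
                        base = w << 6
                        while fw != 0:
                            low = fw & (~fw + one)
                            u = base + _CTZ_TABLE[(low * _DEBRUIJN) >> np.uint64(58)]
                            fw ^= low
                            for w2 in range(kw):
                                nxt[w2] |= rows[u, w2]
                    d += 1
                    newcnt = 0
                    for w in range(kw):
                        nw = nxt[w] & ~visited[w]
                        visited[w] |= nw
                        frontier[w] = nw
                        while nw != 0:
                            nw &= nw - one
                            newcnt += 1
                    if newcnt == 0:
                        break
                    inv_sum += newcnt / d
            total += inv_sum / (k * (k - 1.0))
        return total / n

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def rewire_random(
    a: np.ndarray, config: RandomizationConfig
) -> list[np.ndarray]:
    """Degree-preserving random surrogates via repeated double-edge swaps.

    Each surrogate attempts ``swaps_per_edge * E`` swaps; the degree sequence
    of every output equals the input's exactly.  Surrogates are seeded from
    ``config.seed`` and reproducible.
    """
    config.validate()
    a = _check_binary(a)
    ii, jj = np.nonzero(np.triu(a, k=1))
    if len(ii) < 2:
        raise ValueError("need at least 2 edges to rewire")
    n_attempts = int(config.swaps_per_edge * len(ii))
    out = []
    ss = np.random.SeedSequence([int(config.seed) % (2**31), 0x5A])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_random)]
    for seed in child_seeds:
        mat = a.copy()
        edges = np.stack([ii, jj], axis=1).astype(np.int64)
        if _HAVE_NUMBA:
            n_success = _swap_kernel_numba(mat, edges, n_attempts, seed)
        else:
            n_success = _swap_kernel_python(mat, edges, n_attempts, seed)
        if n_success == 0:
            logger.warning("rewiring made no successful swap (returning input copy)")
        out.append(mat)
    return out


def normalize_and_sigma(
    lp: float, cp: float, randoms: list[np.ndarray]
) -> tuple[float, float, float, float, float]:
    """(lambda, gamma, sigma, L_ran, C_ran) from rewired surrogates."""
    if not randoms:
        raise ValueError("need at least one random network")
    l_ran = float(np.mean([
        characteristic_path_length(all_pairs_distances(r, validate=False))
        for r in randoms
    ]))
    c_ran = float(np.mean([clustering_coefficient(r) for r in randoms]))
    lam = lp / l_ran
    if c_ran == 0:
        logger.warning("C_ran is zero; gamma/sigma undefined")
        return lam, float("nan"), float("nan"), l_ran, c_ran
    gamma = cp / c_ran
    return lam, gamma, gamma / lam, l_ran, c_ran


def compute_global_metrics(
    a: np.ndarray,
    randomization: RandomizationConfig | None = None,
    randoms: list[np.ndarray] | None = None,
) -> GlobalMetrics:
    """All global metrics of one binary network, optionally normalised.

    Pass either a :class:`RandomizationConfig` (surrogates are generated
    here) or a precomputed list of surrogates.
    """
    a = _check_binary(a)
    dist = all_pairs_distances(a, validate=False)
    lp = characteristic_path_length(dist)
    cp = clustering_coefficient(a)
    eg = global_efficiency(dist)
    el = local_efficiency(a)
    if randoms is None and randomization is not None:
        randoms = rewire_random(a, randomization)
    if randoms:
        lam, gamma, sigma, l_ran, c_ran = normalize_and_sigma(lp, cp, randoms)
        return GlobalMetrics(lp, cp, eg, el, l_ran, c_ran, lam, gamma, sigma)
    return GlobalMetrics(lp, cp, eg, el)
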