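"""Hemispheric morphological networks: JSD/JSS edges and sparsity binarization.

The edge weight between two subregions is the Jensen–Shannon similarity

    JSS(p, q) = exp(-JSD(p, q)),
    JSD(p, q) = 1/2 sum p log(p/m) + 1/2 sum q log(q/m),  m = (p + q)/2,

computed with natural logarithms over the shared 27-point mesh, so
JSD in [0, ln 2] and JSS in [exp(-ln 2), 1] = [0.5, 1].  Each weight matrix is
binarized at a grid of sparsity levels (default 0.10 to 0.36 in steps of
0.02) by retaining the floor(K * N(N-1)/2) strongest edges; because one fixed
edge ordering serves every level, the binary edge sets are nested in K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import RegionDensity

__all__ = [
    "SparsityGrid",
    "HemisphericNetwork",
    "jsd",
    "jss",
    "jsd_matrix",
    "build_weight_matrix",
    "binarize",
]

LN2 = float(np.log(2.0))


def _default_levels() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.10, 0.3601, 0.02), 10))


@dataclass(frozen=True)
class SparsityGrid:
    """The set R of sparsity levels used for binarization and integration."""

    values: tuple[float, ...] = field(default_factory=_default_levels)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) == 0 or np.any(np.diff(v) <= 0):
            raise ValueError("sparsity levels must be strictly increasing")
        if np.any((v <= 0) | (v >= 1)):
            raise ValueError("sparsity levels must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class HemisphericNetwork:
    """Per-subject, per-hemisphere weight matrix and its binary stack."""

    subject_id: str
    hemisphere: str
    labels: list[int]                      # subregion ids, matrix order
    weights: np.ndarray                    # (N, N) JSS, zero diagonal
    binaries: dict[float, np.ndarray]      # sparsity -> (N, N) uint8

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _check_shared_grid(p: RegionDensity, q: RegionDensity) -> None:
    if not np.array_equal(p.grid, q.grid):
        raise ValueError("densities do not share a grid")


def _entropy(mass: np.ndarray, axis=-1) -> np.ndarray:
    return -(mass * np.log(mass)).sum(axis=axis)


def jsd(p: RegionDensity, q: RegionDensity) -> float:
    """Jensen–Shannon divergence (nats) between two mesh distributions."""
    _check_shared_grid(p, q)
    m = 0.5 * (p.mass + q.mass)
    val = 0.5 * np.sum(p.mass * np.log(p.mass / m)) \
        + 0.5 * np.sum(q.mass * np.log(q.mass / m))
    return float(max(val, 0.0))


def jss(p: RegionDensity, q: RegionDensity) -> float:
    """Jensen–Shannon similarity exp(-JSD); 1 iff p == q on the grid."""
    return float(np.exp(-jsd(p, q)))


def jsd_matrix(masses: np.ndarray) -> np.ndarray:
    """All-pairs JSD for rows of ``masses`` ((N, n_mesh), rows sum to 1).

    Uses JSD(p, q) = H(m) - (H(p) + H(q))/2 with the entropies computed on
    the shared mesh; clipped at 0 to absorb roundoff.
    """
    P = np.asarray(masses, dtype=float)
    h = _entropy(P)
    m = 0.5 * (P[:, None, :] + P[None, :, :])
    hm = _entropy(m)
    out = hm - 0.5 * (h[:, None] + h[None, :])
    np.maximum(out, 0.0, out=out)
    np.fill_diagonal(out, 0.0)
    return out


def build_weight_matrix(densities: list[RegionDensity]) -> np.ndarray:
    """Pairwise JSS matrix over one hemisphere's densities (zero diagonal)."""
    if len(densities) < 2:
        raise ValueError("need at least 2 densities to build a network")
    grid = densities[0].grid
    for d in densities[1:]:
        if not np.array_equal(d.grid, grid):
            raise ValueError("densities do not share a grid")
    masses = np.stack([d.mass for d in densities])
    w = np.exp(-jsd_matrix(masses))
    np.fill_diagonal(w, 0.0)
    return w


def _edge_order(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight, ties by (i, j)."""
    n = weights.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    w = weights[ii, jj]
    order = np.lexsort((jj, ii, -w))
    return ii[order], jj[order]


def binarize(
    weights: np.ndarray, grid: SparsityGrid = SparsityGrid()
) -> dict[float, np.ndarray]:
    """Binary adjacency at each sparsity level K (edge count floor(K*M)).

    The same descending-weight edge ordering serves all levels, so the edge
    set at a lower K is a subset of that at any higher K.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[1] != n:
        raise ValueError("weights must be square")
    if np.abs(w - w.T).max() > 1e-10:
        raise ValueError("weights must be symmetric")
    m_total = n * (n - 1) // 2
    ei, ej = _edge_order(w)
    out: dict[float, np.ndarray] = {}
    for k in grid.values:
        n_edges = int(np.floor(k * m_total))
        if n_edges < 1:
            raise ValueError(f"sparsity {k} yields zero edges for N={n}")
        a = np.zeros((n, n), dtype=np.uint8)
        a[ei[:n_edges], ej[:n_edges]] = 1
        a |= a.T
        out[float(k)] = a
    return out


def build_network(
    subject_id: str,
    hemisphere: str,
    densities: list[RegionDensity],
    grid: SparsityGrid = SparsityGrid(),
) -> HemisphericNetwork:
    """Weight matrix plus its nested binary stack for one hemisphere."""
    w = build_weight_matrix(densities)
    return HemisphericNetwork(
        subject_id=subject_id,
        hemisphere=hemisphere,
        labels=[d.subregion_id for d in densities],
        weights=w,
        binaries=binarize(w, grid),
    )
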