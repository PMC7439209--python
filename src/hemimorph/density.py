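"""Regional cortical-thickness distributions on a fixed 27-point mesh.

Every subregion's thickness sample is turned into a discrete probability
distribution by Gaussian kernel density estimation evaluated on a mesh shared
by all subregions of a subject (the divergence between two distributions is a
pointwise functional of both, so they must live on a common support).  The
mesh spans the subject's pooled thickness range padded by three bandwidths;
masses are floored at a tiny epsilon before renormalisation so logarithms in
the divergence stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DensityConfig",
    "RegionDensity",
    "silverman_bandwidth",
    "make_grid",
    "estimate_density",
    "subject_densities",
]


class DegenerateSampleError(ValueError):
    """Raised when a thickness sample cannot support a density estimate."""


@dataclass(frozen=True)
class DensityConfig:
    n_mesh: int = 27
    bandwidth: float | None = None   # None => pooled Silverman rule
    pad_bandwidths: float = 3.0
    floor_eps: float = 1e-12

    def validate(self) -> None:
        if self.n_mesh < 3:
            raise ValueError("need at least 3 mesh points")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not (0 < self.floor_eps < 1e-3):
            raise ValueError("floor_eps out of range")


@dataclass(frozen=True)
class RegionDensity:
    """Discrete thickness distribution of one subregion on the subject mesh."""

    subregion_id: int
    grid: np.ndarray   # (n_mesh,) strictly increasing, mm
    mass: np.ndarray   # (n_mesh,) probabilities summing to 1

    def __post_init__(self):
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")


def silverman_bandwidth(values: np.ndarray, n_effective: int | None = None) -> float:
    """Silverman rule-of-thumb bandwidth.

    ``values`` sets the scale (pooled subject thickness); ``n_effective`` sets
    the sample-size factor and should be the typical per-subregion sample size
    (the densities are estimated per subregion, not on the pool).
    """
    values = np.asarray(values, dtype=float)
    n = int(n_effective) if n_effective is not None else len(values)
    if n < 2:
        raise DegenerateSampleError("need at least 2 values for a bandwidth")
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        raise DegenerateSampleError("constant thickness sample")
    return 0.9 * spread * n ** (-1 / 5)


def make_grid(values: np.ndarray, bandwidth: float, n_mesh: int = 27) -> np.ndarray:
    """Equally spaced mesh over [min - 3h, max + 3h] of the pooled values."""
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if not (hi > lo):
        raise DegenerateSampleError("degenerate (constant) thickness values")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return np.linspace(lo - 3.0 * bandwidth, hi + 3.0 * bandwidth, n_mesh)


def estimate_density(
    values: np.ndarray,
    grid: np.ndarray,
    bandwidth: float,
    floor_eps: float = 1e-12,
    subregion_id: int = -1,
) -> RegionDensity:
    """Gaussian-kernel density of ``values`` on ``grid``, as a discrete
    distribution (floored at ``floor_eps`` and renormalised to sum 1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateSampleError("empty thickness sample")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    z = (np.asarray(grid)[:, None] - values[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    dens = np.maximum(dens, 0.0) + floor_eps
    mass = dens / dens.sum()
    return RegionDensity(subregion_id=subregion_id, grid=np.asarray(grid, float),
                         mass=mass)


def subject_densities(
    vertex_table: pd.DataFrame,
    parcellation,
    config: DensityConfig = DensityConfig(),
) -> dict[str, list[RegionDensity]]:
    """Estimate all subregion densities of one subject on a shared mesh.

    Returns {hemisphere: [RegionDensity, ...]} with subregions in
    subregion_id order; both hemispheres share one grid and bandwidth.
    The bandwidth (when not fixed in ``config``) follows the Silverman rule
    with the subject's pooled thickness scale and the median subregion sample
    size, and is identical for every subregion of the subject.
    """
    config.validate()
    thickness = vertex_table["thickness"].to_numpy(dtype=float)
    if np.any(thickness <= 0):
        raise ValueError("thickness values must be positive")

    sub_of_vertex = parcellation.vertex_subregion.loc[
        vertex_table["vertex_id"]
    ].to_numpy()
    sizes = parcellation.subregions["n_vertices"].to_numpy()
    h = config.bandwidth
    if h is None:
        h = silverman_bandwidth(thickness, n_effective=int(np.median(sizes)))
    grid = make_grid(thickness, h, config.n_mesh)

    order = np.argsort(sub_of_vertex, kind="stable")
    sorted_subs = sub_of_vertex[order]
    sorted_thick = thickness[order]
    bounds = np.searchsorted(sorted_subs, parcellation.subregions["subregion_id"])
    bounds = np.append(bounds, len(sorted_subs))

    out: dict[str, list[RegionDensity]] = {"L": [], "R": []}
    for i, row in enumerate(parcellation.subregions.itertuples(index=False)):
        vals = sorted_thick[bounds[i]:bounds[i + 1]]
        dens = estimate_density(vals, grid, h, config.floor_eps,
                                subregion_id=int(row.subregion_id))
        out[row.hemisphere].append(dens)
    return out
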