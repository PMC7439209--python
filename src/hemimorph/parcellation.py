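"""Upsampling of the 78-region anatomical parcellation into 512 subregions.

Each anatomical region is split independently by k-means on the vertices'
unit-sphere coordinates, so subregion boundaries never cross anatomical
(gyral/sulcal) boundaries and subregion sizes are approximately equal.  The
number of clusters per region is proportional to its vertex count, adjusted by
the largest-remainder rule so that each hemisphere ends up with exactly the
target number of subregions (default 256, i.e. 512 brain-wide).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "DEFAULT_SIZE_FLOOR",
    "TARGET_PER_HEMISPHERE",
    "Parcellation",
    "allocate_cluster_counts",
    "upsample",
]

#: Minimum admissible mean subregion size (vertices); keeps the downstream
#: 27-point density estimates sane.
DEFAULT_SIZE_FLOOR = 30

#: Default number of subregions (network nodes) per hemisphere.
TARGET_PER_HEMISPHERE = 256


class AllocationError(ValueError):
    """A region cannot host its subregion allocation at the size floor."""


@dataclass(frozen=True)
class Parcellation:
    """Vertex-to-subregion assignment nested in the anatomical parcellation.

    ``vertex_subregion`` maps vertex_id -> subregion_id; ``subregions`` has one
    row per subregion (subregion_id, region, hemisphere, n_vertices), ordered
    by subregion_id: hemisphere-major (all L first), then region, then cluster.
    """

    vertex_subregion: pd.Series
    subregions: pd.DataFrame

    @property
    def n_subregions(self) -> int:
        return len(self.subregions)

    def per_hemisphere(self, hemisphere: str) -> pd.DataFrame:
        return self.subregions[self.subregions["hemisphere"] == hemisphere]

    def validate(self, template: pd.DataFrame) -> None:
        sub = self.subregions
        if not sub["subregion_id"].is_monotonic_increasing:
            raise ValueError("subregion ids must be sorted")
        # partition: every vertex assigned exactly once
        if set(self.vertex_subregion.index) != set(template["vertex_id"]):
            raise ValueError("parcellation does not cover the vertex table")
        # nesting: each subregion lives in one (region, hemisphere)
        merged = template.set_index("vertex_id").join(
            self.vertex_subregion.rename("subregion_id")
        )
        grp = merged.groupby("subregion_id")[["region", "hemisphere"]].nunique()
        if (grp > 1).any().any():
            raise ValueError("a subregion crosses an anatomical boundary")


def allocate_cluster_counts(
    region_sizes: "pd.Series[int]",
    target: int,
    size_floor: int = DEFAULT_SIZE_FLOOR,
) -> "pd.Series[int]":
    """Number of subregions per anatomical region for one hemisphere.

    Each region receives ``max(1, round(size / s))`` clusters where ``s`` is
    the hemisphere-wide target mean subregion size, then counts are nudged by
    the largest-remainder rule until they sum exactly to ``target``.
    """
    if target < len(region_sizes):
        raise AllocationError(
            f"target {target} below the number of regions {len(region_sizes)}"
        )
    sizes = region_sizes.astype(float)
    avg = sizes.sum() / target
    ideal = sizes / avg
    counts = np.maximum(1, np.floor(ideal + 0.5)).astype(int)
    remainder = ideal - counts  # in (-0.5, 0.5]; larger => deserves one more

    order = sorted(
        range(len(sizes)), key=lambda i: (-remainder.iloc[i], str(sizes.index[i]))
    )
    diff = target - int(counts.sum())
    idx = 0
    while diff > 0:  # grant extras to the largest remainders first
        counts.iloc[order[idx % len(order)]] += 1
        diff -= 1
        idx += 1
    idx = len(order) - 1
    while diff < 0:  # take from the smallest remainders, never below 1
        i = order[idx % len(order)]
        if counts.iloc[i] > 1:
            counts.iloc[i] -= 1
            diff += 1
        idx -= 1

    out = counts.astype(int)
    mean_sizes = sizes / out
    bad = mean_sizes[mean_sizes < size_floor]
    if len(bad):
        raise AllocationError(
            f"regions too small for their allocation at floor {size_floor}: "
            f"{list(bad.index)}"
        )
    return out


def _farthest_point_init(coords: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    start = int(rng.integers(len(coords)))
    chosen = [start]
    d = np.linalg.norm(coords - coords[start], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))  # argmax ties break to lowest index
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return coords[chosen]


def upsample(
    template: pd.DataFrame,
    counts: dict[str, "pd.Series[int]"] | None = None,
    seed: int = 0,
    target_per_hemisphere: int = TARGET_PER_HEMISPHERE,
    size_floor: int = DEFAULT_SIZE_FLOOR,
) -> Parcellation:
    """Split every anatomical region into its allocated subregions by k-means.

    ``counts`` maps hemisphere -> per-region cluster counts; when omitted it is
    computed by :func:`allocate_cluster_counts` for each hemisphere.  k-means
    runs on the unit-sphere coordinates with deterministic farthest-point
    seeding (100-iteration cap), so results are reproducible given ``seed``.
    """
    assignments = pd.Series(
        np.full(len(template), -1, dtype=int),
        index=pd.Index(template["vertex_id"], name="vertex_id"),
    )
    rows = []
    next_id = 0
    for hemisphere in ("L", "R"):
        hemi = template[template["hemisphere"] == hemisphere]
        if hemi.empty:
            raise ValueError(f"template has no vertices for hemisphere {hemisphere}")
        sizes = hemi.groupby("region", sort=True).size()
        hemi_counts = (
            counts[hemisphere]
            if counts is not None
            else allocate_cluster_counts(sizes, target_per_hemisphere, size_floor)
        )
        for region in sizes.index:
            part = hemi[hemi["region"] == region]
            k = int(hemi_counts.loc[region])
            coords = part[["x", "y", "z"]].to_numpy()
            if k == 1:
                labels = np.zeros(len(part), dtype=int)
            else:
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 0 if hemisphere == "L" else 1,
                                            zlib.crc32(region.encode())])
                )
                init = _farthest_point_init(coords, k, rng)
                km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=100,
                            random_state=0)
                labels = km.fit_predict(coords)
            for c in range(k):
                sel = part.loc[labels == c, "vertex_id"]
                if len(sel) == 0:
                    raise RuntimeError(
                        f"empty cluster in region {region} ({hemisphere})"
                    )
                assignments.loc[sel] = next_id
                rows.append({
                    "subregion_id": next_id,
                    "region": region,
                    "hemisphere": hemisphere,
                    "n_vertices": len(sel),
                })
                next_id += 1
    parc = Parcellation(
        vertex_subregion=assignments,
        subregions=pd.DataFrame(rows),
    )
    parc.validate(template)
    return parc
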