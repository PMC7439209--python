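"""Sparsity integration of graph metrics and hemispheric asymmetry indexes.

A metric computed on the binary network at each sparsity level is summarised
by its arithmetic mean over the sparsity grid (the "integrated" metric);
local metrics are first averaged over the subregions of each anatomical
region at every level.  The asymmetry index of a metric M is

    AI(M) = 100 * 2 * (M_L - M_R) / (M_L + M_R),

positive for leftward, negative for rightward asymmetry; homologous region
pairs are the left/right instances of the same anatomical label.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .network import SparsityGrid

__all__ = [
    "integrate_global",
    "integrate_local",
    "asymmetry_index",
    "ai_table",
]

logger = logging.getLogger(__name__)


def integrate_global(
    values: Mapping[float, float], grid: SparsityGrid
) -> float:
    """Mean of a global metric over the sparsity grid (one value per level)."""
    missing = [k for k in grid.values if float(k) not in {float(v) for v in values}]
    if missing:
        raise ValueError(f"missing sparsity levels: {missing}")
    return float(np.mean([values[float(k)] for k in grid.values]))


def integrate_local(
    values: pd.DataFrame,
    parcellation,
    grid: SparsityGrid,
    value_col: str = "value",
) -> pd.Series:
    """Integrated local metric per anatomical region for one hemisphere.

    ``values`` must have columns (subregion_id, sparsity, ``value_col``) with
    one row per subregion and level.  At each level the metric is averaged
    over the region's subregions, then averaged over levels; the result is a
    Series indexed by (hemisphere, region).
    """
    sub = parcellation.subregions[["subregion_id", "region", "hemisphere"]]
    values = values.drop(columns=[c for c in ("region", "hemisphere")
                                  if c in values.columns])
    merged = values.merge(sub, on="subregion_id", how="left")
    if merged["region"].isna().any():
        raise ValueError("values reference subregions absent from the parcellation")
    expected = {float(k) for k in grid.values}
    got = set(np.round(merged["sparsity"].unique().astype(float), 10))
    if not expected <= got:
        raise ValueError(f"missing sparsity levels: {sorted(expected - got)}")
    merged = merged[merged["sparsity"].round(10).isin(np.round(list(expected), 10))]

    counts = sub.groupby(["hemisphere", "region"]).size()
    if (counts == 0).any():
        raise ValueError("a region has no subregions")

    per_level = (
        merged.groupby(["hemisphere", "region", "sparsity"])[value_col].mean()
    )
    return per_level.groupby(["hemisphere", "region"]).mean()


def asymmetry_index(m_left: float, m_right: float) -> float:
    """AI = 100 * 2 * (M_L - M_R)/(M_L + M_R); nan when the sum is zero."""
    s = m_left + m_right
    if s == 0:
        logger.warning("asymmetry index undefined: M_L + M_R == 0")
        return float("nan")
    return 100.0 * 2.0 * (m_left - m_right) / s


def ai_table(
    integrated_global: pd.DataFrame,
    integrated_local: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-subject AI rows from integrated metric tables.

    ``integrated_global``: columns (subject_id, hemisphere, metric, value).
    ``integrated_local``: columns (subject_id, hemisphere, region, metric,
    value); pass None to skip local AIs.  Output columns: subject_id, scope
    ('global' | 'region'), metric, region ('' for global), ai.
    """
    rows = []
    piv = integrated_global.pivot_table(
        index=["subject_id", "metric"], columns="hemisphere", values="value"
    )
    for (sid, metric), r in piv.iterrows():
        rows.append({
            "subject_id": sid, "scope": "global", "metric": metric,
            "region": "", "ai": asymmetry_index(r["L"], r["R"]),
        })
    if integrated_local is not None:
        pivl = integrated_local.pivot_table(
            index=["subject_id", "metric", "region"], columns="hemisphere",
            values="value",
        )
        if pivl[["L", "R"]].isna().any().any():
            raise ValueError("homologous pairing incomplete: unmatched region")
        for (sid, metric, region), r in pivl.iterrows():
            rows.append({
                "subject_id": sid, "scope": "region", "metric": metric,
                "region": region, "ai": asymmetry_index(r["L"], r["R"]),
            })
    return pd.DataFrame(rows, columns=["subject_id", "scope", "metric",
                                       "region", "ai"])
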