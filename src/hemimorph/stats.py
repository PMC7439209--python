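"""Group statistics: repeated-measures ANOVA, AI t-tests, FDR control.

The two-way repeated-measures ANOVA (hemisphere within, gender between, age
as a linear covariate) exploits the two-level within factor to decompose
exactly into two between-subject ANCOVAs:

* the subject mean (L + R)/2 regressed on gender + age gives the gender
  main effect;
* the difference L - R regressed on gender + age gives the hemisphere main
  effect (intercept term, with gender effect-coded +/-1/2 and age centred)
  and the gender-by-hemisphere interaction (gender term).

With one-degree-of-freedom effects every F is the square of the
corresponding t statistic.  Sphericity is trivially satisfied with two
within levels, so no correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "TTestResult",
    "rm_anova",
    "one_sample_t",
    "two_sample_t",
    "fdr_bh",
]


@dataclass(frozen=True)
class AnovaResult:
    """F tests for gender, hemisphere and their interaction (df1 = 1 each)."""

    f_gender: float
    p_gender: float
    f_hemisphere: float
    p_hemisphere: float
    f_interaction: float
    p_interaction: float
    df1: int
    df2: int


@dataclass(frozen=True)
class TTestResult:
    scope: str            # 'global' or 'region'
    metric: str
    region: str           # '' for global
    group: str            # 'F', 'M' or 'FvM'
    t: float
    df: float
    p: float
    mean_ai: float


class SingularDesignError(ValueError):
    """Raised when the ANCOVA design matrix is rank-deficient."""


def _ancova_1df(y: np.ndarray, g: np.ndarray, a: np.ndarray):
    """OLS of y on [1, g, a]; returns per-coefficient (F, p) and df2.

    ``g`` is the effect-coded gender contrast, ``a`` the centred age.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), g, a])
    if np.linalg.matrix_rank(X) < 3:
        raise SingularDesignError("singular ANCOVA design (constant age or gender?)")
    df2 = n - 3
    if df2 < 1:
        raise SingularDesignError("too few subjects for the ANCOVA")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    mse = float(resid @ resid) / df2
    xtx_inv = np.linalg.inv(X.T @ X)
    out = []
    for j in range(3):
        if mse == 0:
            f = 0.0 if beta[j] == 0 else float("inf")
        else:
            f = float(beta[j] ** 2 / (mse * xtx_inv[j, j]))
        p = float(sps.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
        out.append((f, p))
    return out, df2


def rm_anova(data: pd.DataFrame) -> AnovaResult:
    """Two-way repeated-measures ANOVA with age covariate.

    ``data`` needs columns subject_id, gender ('F'/'M'), age, left, right —
    one row per subject with the metric value for each hemisphere.
    """
    req = {"subject_id", "gender", "age", "left", "right"}
    if not req <= set(data.columns):
        raise ValueError(f"missing columns: {sorted(req - set(data.columns))}")
    if data["subject_id"].duplicated().any():
        raise ValueError("one row per subject required")
    counts = data["gender"].value_counts()
    if counts.get("F", 0) < 2 or counts.get("M", 0) < 2:
        raise SingularDesignError("need at least 2 subjects per gender")

    g = np.where(data["gender"].to_numpy() == "F", 0.5, -0.5)
    a = data["age"].to_numpy(dtype=float)
    a = a - a.mean()
    left = data["left"].to_numpy(dtype=float)
    right = data["right"].to_numpy(dtype=float)

    between, df2 = _ancova_1df((left + right) / 2.0, g, a)
    within, _ = _ancova_1df(left - right, g, a)
    return AnovaResult(
        f_gender=between[1][0], p_gender=between[1][1],
        f_hemisphere=within[0][0], p_hemisphere=within[0][1],
        f_interaction=within[1][0], p_interaction=within[1][1],
        df1=1, df2=df2,
    )


def one_sample_t(
    ais: np.ndarray, metric: str = "", region: str = "", group: str = "",
    scope: str = "global",
) -> TTestResult:
    """Two-sided one-sample t-test of the AIs against zero."""
    ais = np.asarray(ais, dtype=float)
    n = len(ais)
    if n < 2:
        raise ValueError("need at least 2 AI values")
    if np.std(ais, ddof=1) == 0:
        raise ValueError("zero-variance AI sample")
    res = sps.ttest_1samp(ais, 0.0)
    return TTestResult(scope, metric, region, group, float(res.statistic),
                       float(n - 1), float(res.pvalue), float(ais.mean()))


def two_sample_t(
    ais_female: np.ndarray, ais_male: np.ndarray,
    metric: str = "", region: str = "", scope: str = "global",
    welch: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test (pooled variance by default) F vs M."""
    f = np.asarray(ais_female, dtype=float)
    m = np.asarray(ais_male, dtype=float)
    if len(f) < 2 or len(m) < 2:
        raise ValueError("need at least 2 AI values per group")
    df = len(f) + len(m) - 2 if not welch else None
    if np.std(f, ddof=1) == 0 and np.std(m, ddof=1) == 0:
        if f.mean() == m.mean():
            return TTestResult(scope, metric, region, "FvM", 0.0,
                               float(df or 0), 1.0, float(f.mean() - m.mean()))
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(f, m, equal_var=not welch)
    dof = float(df) if df is not None else float(res.df)
    return TTestResult(scope, metric, region, "FvM", float(res.statistic),
                       dof, float(res.pvalue), float(f.mean() - m.mean()))


def fdr_bh(pvalues, q: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg step-up control over one family of p-values.

    Returns a DataFrame (p_raw, p_adjusted, rejected) aligned with the input
    order; adjusted p-values are the usual step-up monotone adjustment
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return pd.DataFrame(columns=["p_raw", "p_adjusted", "rejected"])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame({"p_raw": p, "p_adjusted": p_adj, "rejected": rejected})
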