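"""A posteriori statistical screen: Welch's t, four-group ANOVA,
Benjamini-Hochberg FDR, the 2x2 chi-square test, and the combined
feature-table screen over residualized regional measures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, InvalidInputError
from .preprocess import residualize_covariates

__all__ = [
    "StatResult",
    "welch_t_test",
    "fourgroup_anova",
    "benjamini_hochberg",
    "chi_square_2x2",
    "screen_features",
]


@dataclass(frozen=True)
class StatResult:
    """One hypothesis test outcome, optionally FDR-adjusted."""

    feature: str
    test: str
    statistic: float
    df: float | tuple[int, int]
    p_value: float
    q_value: float | None = None
    rejected: bool | None = None
    zero_variance: bool = False


def welch_t_test(x1: np.ndarray, x2: np.ndarray, feature: str = "") -> StatResult:
    """Two-sample t-test for unequal variances.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite df and
    a two-sided p from the t distribution.  Two zero-variance samples with
    equal means return t = 0, p = 1 at the df floor.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("both samples need at least 2 values")
    v1, v2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if np.mean(x1) == np.mean(x2):
            return StatResult(
                feature, "welch_t", 0.0, float(min(n1, n2) - 1), 1.0,
                zero_variance=True,
            )
        return StatResult(
            feature, "welch_t", np.inf, float(min(n1, n2) - 1), 0.0,
            zero_variance=True,
        )
    t = (np.mean(x1) - np.mean(x2)) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(feature, "welch_t", float(t), float(df), float(p))


def fourgroup_anova(
    values: np.ndarray,
    groups: np.ndarray,
    feature: str = "",
    method: str = "oneway",
    expected_cells: tuple | None = None,
) -> StatResult:
    """ANOVA across the four diagnosis-by-sex cells.

    Default is the ordinary one-way fixed-effects decomposition with
    df = (g - 1, n - g) (so F_(3, n-4) for four cells); ``method='welch'``
    selects the unequal-variance Welch ANOVA instead.  ``expected_cells``
    lets callers assert the design: any expected cell with no members raises
    an error naming it.
    """
    if method not in ("oneway", "welch"):
        raise ConfigurationError("method must be 'oneway' or 'welch'")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    cells = pd.unique(groups) if expected_cells is None else np.asarray(expected_cells)
    samples = [values[groups == g] for g in cells]
    empty = [str(g) for g, s in zip(cells, samples) if len(s) == 0]
    if empty:
        raise InvalidInputError(f"empty cells: {empty}")
    g = len(cells)
    n = len(values)
    df = (g - 1, n - g)
    if all(np.var(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return StatResult(feature, f"anova_{method}", 0.0, df, 1.0, zero_variance=True)
    if method == "welch":
        res = _welch_anova(samples)
        return StatResult(feature, "anova_welch", res[0], res[1], res[2])
    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ss_within == 0:
        return StatResult(feature, "anova_oneway", np.inf, df, 0.0, zero_variance=True)
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = sps.f.sf(f, *df)
    return StatResult(feature, "anova_oneway", float(f), df, float(p))


def _welch_anova(samples: list[np.ndarray]) -> tuple[float, tuple[float, float], float]:
    g = len(samples)
    w = np.array([len(s) / np.var(s, ddof=1) for s in samples])
    means = np.array([s.mean() for s in samples])
    mw = np.sum(w * means) / np.sum(w)
    num = np.sum(w * (means - mw) ** 2) / (g - 1)
    lam = np.array([(1 - wi / np.sum(w)) ** 2 / (len(s) - 1) for wi, s in zip(w, samples)])
    denom = 1 + 2 * (g - 2) / (g**2 - 1) * np.sum(lam)
    df2 = (g**2 - 1) / (3 * np.sum(lam))
    f = num / denom
    return float(f), (float(g - 1), float(df2)), float(sps.f.sf(f, g - 1, df2))


def benjamini_hochberg(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR control: q_(i) = min_{j>=i} m p_(j) / j, capped at 1.

    Returns (q values, boolean rejection mask at ``alpha``), both in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise InvalidInputError("p values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


def chi_square_2x2(
    counts: np.ndarray, feature: str = "", yates: bool = False
) -> StatResult:
    """Pearson chi-square on a 2x2 contingency table, df = 1.

    No continuity correction by default; pass ``yates=True`` to apply it.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise InvalidInputError("counts must be a non-negative 2x2 table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise InvalidInputError("all margins must be positive")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff**2 / expected))
    return StatResult(feature, "chi_square", chi2, 1.0, float(sps.chi2.sf(chi2, 1)))


def screen_features(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    residualize: bool = True,
    anova_method: str = "oneway",
) -> pd.DataFrame:
    """Per-feature Welch t (diagnosis) and four-group ANOVA screen with BH.

    Age and site are regressed out first unless the table is already
    residualized.  BH correction is applied within each test family across
    all features.  Returns a tidy frame sorted by region then measure.
    """
    if features.shape[1] == 0:
        return pd.DataFrame(
            columns=[
                "feature", "region", "measure", "t", "t_df", "t_p", "t_q",
                "t_rejected", "F", "F_df1", "F_df2", "F_p", "F_q", "F_rejected",
            ]
        )
    x = residualize_covariates(features, cohort) if residualize else features
    dx = cohort["diagnosis"].astype(str).to_numpy()
    four = (
        cohort["diagnosis"].astype(str) + "_" + cohort["sex"].astype(str)
    ).to_numpy()
    rows = []
    for col in x.columns:
        v = x[col].to_numpy(dtype=float)
        wt = welch_t_test(v[dx == "ASD"], v[dx == "TD"], feature=col)
        an = fourgroup_anova(v, four, feature=col, method=anova_method)
        region, measure = col.split("__") if "__" in col else (col, "")
        rows.append(
            {
                "feature": col, "region": region, "measure": measure,
                "t": wt.statistic, "t_df": wt.df, "t_p": wt.p_value,
                "F": an.statistic, "F_df1": an.df[0], "F_df2": an.df[1],
                "F_p": an.p_value,
            }
        )
    out = pd.DataFrame(rows)
    for stat in ("t", "F"):
        q, rej = benjamini_hochberg(out[f"{stat}_p"].to_numpy(), alpha)
        out[f"{stat}_q"] = q
        out[f"{stat}_rejected"] = rej
    return out.sort_values(["region", "measure"], kind="stable").reset_index(drop=True)
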