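"""Group-level statistics for the cohort comparison.

Covers the parametric toolkit used on the per-participant summary table:
Shapiro-Wilk normality screening (justifying the log transform of
thresholds), between-participants one-way ANOVA with generalised eta
squared (which reduces to SS_effect / (SS_effect + SS_error) in a purely
between-participants design), Tukey HSD post-hocs, Levene's homogeneity
test (median-centred), Pearson correlations with adjusted R^2, and the
ANCOVA with group as categorical factor and two covariates (log
anisochrony threshold and synchronisation vector length) including
group x covariate interactions, using Type-II sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from delaydetect.errors import (
    CollinearityError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "normality_screen",
    "oneway_anova_ges",
    "tukey_hsd",
    "homogeneity_test",
    "correlate",
    "ancova_two_covariates",
]


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise InvalidInputError("non-finite values in sample")
    return arr


def normality_screen(values) -> dict:
    """Shapiro-Wilk test: W statistic and p value."""
    arr = _clean(values)
    if arr.size < 3:
        raise InsufficientDataError(f"Shapiro-Wilk needs n >= 3, got {arr.size}")
    if np.ptp(arr) == 0:
        raise DegenerateInputError("constant sample")
    w, p = stats.shapiro(arr)
    return {"W": float(w), "p": float(p), "n": int(arr.size)}


def _check_groups(table: pd.DataFrame, response: str, factor: str,
                  min_per_group: int = 2) -> list[np.ndarray]:
    groups = [g[response].to_numpy(dtype=float)
              for _, g in table.groupby(factor, observed=True)]
    if len(groups) < 2:
        raise InvalidInputError("need >= 2 groups")
    if any(g.size < min_per_group for g in groups):
        raise InsufficientDataError(
            f"every group needs >= {min_per_group} observations")
    return groups


def oneway_anova_ges(table: pd.DataFrame, response: str, factor: str) -> dict:
    """Between-participants one-way ANOVA with generalised eta squared."""
    _check_groups(table, response, factor)
    model = smf.ols(f"{response} ~ C({factor})", data=table).fit()
    tab = anova_lm(model, typ=2)
    ss_effect = float(tab.loc[f"C({factor})", "sum_sq"])
    ss_error = float(tab.loc["Residual", "sum_sq"])
    return {
        "F": float(tab.loc[f"C({factor})", "F"]),
        "df_effect": int(tab.loc[f"C({factor})", "df"]),
        "df_error": int(tab.loc["Residual", "df"]),
        "p": float(tab.loc[f"C({factor})", "PR(>F)"]),
        "eta_G_squared": ss_effect / (ss_effect + ss_error),
        "ss_effect": ss_effect,
        "ss_error": ss_error,
    }


def tukey_hsd(table: pd.DataFrame, response: str, factor: str) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range adjusted p)."""
    _check_groups(table, response, factor)
    res = pairwise_tukeyhsd(table[response].to_numpy(dtype=float),
                            table[factor].to_numpy(), alpha=0.05)
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    frame = frame.rename(columns={"p-adj": "p_adj"})
    frame["p_adj"] = frame["p_adj"].astype(float)
    frame["meandiff"] = frame["meandiff"].astype(float)
    return frame[["group1", "group2", "meandiff", "p_adj", "reject"]]


def homogeneity_test(table: pd.DataFrame, response: str, factor: str) -> dict:
    """Levene's test with median centring (Brown-Forsythe variant)."""
    groups = _check_groups(table, response, factor)
    if all(np.ptp(g) == 0 for g in groups):
        raise DegenerateInputError("all groups constant")
    stat, p = stats.levene(*groups, center="median")
    return {"W": float(stat), "p": float(p),
            "df": (len(groups) - 1, sum(g.size for g in groups) - len(groups))}


def correlate(table: pd.DataFrame, x: str, y: str) -> dict:
    """Pearson correlation with df = n - 2 and adjusted R^2."""
    sub = table[[x, y]].dropna()
    n = len(sub)
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 complete pairs, got {n}")
    xs, ys = _clean(sub[x]), _clean(sub[y])
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateInputError("zero variance in a correlated variable")
    r, p = stats.pearsonr(xs, ys)
    r2 = r * r
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return {"r": float(r), "df": n - 2, "p": float(p),
            "adjusted_R2": float(adj), "n": n}


def ancova_two_covariates(
    table: pd.DataFrame,
    response: str = "log_delay_threshold",
    factor: str = "group",
    covariate1: str = "log_aniso_threshold",
    covariate2: str = "sync_vector_z",
) -> dict:
    """ANCOVA: categorical group, two covariates, group x covariate
    interactions; Type-II sums of squares.

    Reports the five term tests of interest: both interactions, both
    covariate main effects, and the group main effect.
    """
    cols = [response, factor, covariate1, covariate2]
    sub = table[cols].dropna()
    for c in (covariate1, covariate2):
        if np.ptp(sub[c].to_numpy(dtype=float)) == 0:
            raise CollinearityError([c], f"covariate {c!r} is constant")
    cov1, cov2 = sub[covariate1].to_numpy(float), sub[covariate2].to_numpy(float)
    r = np.corrcoef(cov1, cov2)[0, 1]
    if abs(r) > 1 - 1e-10:
        raise CollinearityError([covariate1, covariate2],
                                "covariates are perfectly collinear")
    formula = (f"{response} ~ C({factor}) + {covariate1} + {covariate2} "
               f"+ C({factor}):{covariate1} + C({factor}):{covariate2}")
    model = smf.ols(formula, data=sub).fit()
    if model.model.exog.shape[1] > np.linalg.matrix_rank(model.model.exog):
        raise CollinearityError(
            model.model.exog_names, "rank-deficient ANCOVA design matrix")
    tab = anova_lm(model, typ=2)
    out = {"n": len(sub), "terms": {}}
    for term in tab.index:
        if term == "Residual":
            continue
        out["terms"][term] = {
            "F": float(tab.loc[term, "F"]),
            "df": (int(tab.loc[term, "df"]), int(tab.loc["Residual", "df"])),
            "p": float(tab.loc[term, "PR(>F)"]),
            "sum_sq": float(tab.loc[term, "sum_sq"]),
        }
    out["ss_residual"] = float(tab.loc["Residual", "sum_sq"])
    out["df_residual"] = int(tab.loc["Residual", "df"])
    out["group_term"] = f"C({factor})"
    return out
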