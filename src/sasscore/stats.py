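"""Group comparison statistics for severity scores.

The central quantity is the covariate-adjusted group mean (LS-mean): a
linear model ``score ~ group + sex + age_group`` is fit with treatment
coding, and each group's adjusted mean is the model prediction averaged
over a covariate distribution. Two marginalization conventions are
supported:

* ``observed`` (default) — average over the observed cohort
  sex × age-group distribution (population-margins convention);
* ``balanced`` — average over a balanced grid giving every
  sex × age-group cell equal weight (the classical LSMEANS convention).

Confidence intervals come from the standard error of the corresponding
linear combination of coefficients, with t quantiles by default
(normal quantiles optional). Per-group p-values are contrasts against a
reference group — by default the group with the least severe (lowest)
raw mean score.

Also provided: one-way ANOVA across a factor, z-standardized adjusted
means for radar-style cross-category comparison, positional/size trend
slopes for null variants and chromosomal deletions, and the Bonferroni
threshold for the per-category comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import AnalysisError, IneligibilityError

__all__ = [
    "AGE_GROUP_LABELS",
    "assign_age_group",
    "build_analysis_table",
    "anova_by_factor",
    "adjusted_means",
    "standardized_adjusted_means",
    "significance_threshold",
    "trend_slope",
    "TrendResult",
]

#: The four analysis age groups (years, integer-age semantics).
AGE_GROUP_LABELS: tuple[str, ...] = ("3-5", "6-10", "11-17", ">=18")

_AGE_EDGES = (3.0, 6.0, 11.0, 18.0)


def assign_age_group(age_years: float) -> str:
    """Bin an eligible age into one of the four analysis age groups.

    Bins are [3, 6), [6, 11), [11, 18), [18, inf): ages 3-5 inclusive in
    the first bin by integer-age semantics, and so on.
    """
    if age_years < _AGE_EDGES[0]:
        raise IneligibilityError(f"age {age_years} below scoring age of 3 years")
    for label, lo, hi in zip(AGE_GROUP_LABELS, _AGE_EDGES, _AGE_EDGES[1:] + (np.inf,)):
        if lo <= age_years < hi:
            return label
    raise AssertionError("unreachable")


def build_analysis_table(scores: pd.DataFrame, annotations: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Merge a score table with a molecular annotation table into an analysis table.

    Adds the ``age_group`` column derived from ``age_years``. If
    ``annotations`` is given, joins on ``individual_id`` (left join on the
    scored cohort); unmatched scored individuals keep NA molecular columns.
    """
    table = scores.copy()
    table["age_group"] = [assign_age_group(a) for a in table["age_years"]]
    if annotations is not None:
        dup = annotations["individual_id"].duplicated()
        if dup.any():
            raise AnalysisError(
                f"duplicate individual_id in annotations: {sorted(annotations['individual_id'][dup])}"
            )
        table = table.merge(annotations, on="individual_id", how="left")
    return table


def anova_by_factor(table: pd.DataFrame, score_name: str, factor: str) -> dict:
    """One-way ANOVA of a composite score across the levels of a factor.

    Empty factor levels are dropped with a warning; fewer than two
    non-empty levels is an analysis error. Returns ``{"F", "p", "n",
    "levels"}``.
    """
    sub = table.dropna(subset=[factor, score_name])
    groups = [g[score_name].to_numpy(float) for _, g in sub.groupby(factor, observed=True)]
    n_dropped = table[factor].isna().sum() + (table[score_name].isna() & table[factor].notna()).sum()
    if n_dropped:
        warnings.warn(f"anova_by_factor: dropped {n_dropped} rows with missing {factor}/{score_name}")
    if len(groups) < 2:
        raise AnalysisError(f"factor {factor!r} has fewer than 2 non-empty levels")
    F, p = sps.f_oneway(*groups)
    return {"F": float(F), "p": float(p), "n": int(sub.shape[0]), "levels": len(groups)}


def _design(
    df: pd.DataFrame,
    grouping: str,
    reference_group: str,
    covariates: Sequence[str] = ("sex", "age_group"),
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Treatment-coded design matrix: intercept, group dummies, covariate dummies.

    Returns (X, column names, {covariate: dropped-to-kept level lists}).
    Zero-variance dummy columns are removed (a covariate with a single
    observed level contributes nothing to adjust for).
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    levels_kept: dict[str, list[str]] = {}

    group_levels = [g for g in pd.unique(df[grouping]) if g != reference_group]
    group_levels.sort()
    for g in group_levels:
        cols.append((df[grouping] == g).to_numpy(float))
        names.append(f"{grouping}[{g}]")

    for cov in covariates:
        lv = sorted(pd.unique(df[cov]))
        kept = []
        for level in lv[1:]:  # drop-first coding
            col = (df[cov] == level).to_numpy(float)
            cols.append(col)
            names.append(f"{cov}[{level}]")
            kept.append(level)
        levels_kept[cov] = kept

    X = np.column_stack(cols)
    return X, names, levels_kept


def _margin_weights(
    df: pd.DataFrame, names: list[str], levels_kept: dict[str, list[str]], margins: str
) -> dict[str, float]:
    """Value of each covariate dummy in the marginal-prediction vector."""
    w: dict[str, float] = {}
    for cov, kept in levels_kept.items():
        n_levels = len(kept) + 1
        for level in kept:
            if margins == "observed":
                w[f"{cov}[{level}]"] = float((df[cov] == level).mean())
            elif margins == "balanced":
                w[f"{cov}[{level}]"] = 1.0 / n_levels
            else:
                raise AnalysisError(f"unknown margins convention {margins!r}")
    return w


def adjusted_means(
    table: pd.DataFrame,
    score_name: str,
    grouping: str,
    reference_group: Optional[str] = None,
    margins: Literal["observed", "balanced"] = "observed",
    use_t: bool = True,
    alpha: float = 0.05,
    covariates: Sequence[str] = ("sex", "age_group"),
) -> pd.DataFrame:
    """Covariate-adjusted group means with 95% CIs from a linear model.

    Fits ``score ~ grouping + sex + age_group`` (treatment coding) and
    reports, per group, the model prediction averaged over the chosen
    covariate distribution, its confidence interval, and the p-value of
    the contrast against the reference group. If ``reference_group`` is
    None the group with the lowest raw mean (least severe) is used.

    Returns a tidy frame with columns ``score, grouping, group, n,
    estimate, ci_low, ci_high, p_vs_reference, diff_vs_reference,
    diff_ci_low, diff_ci_high, reference_group``; the ``diff_*`` columns
    are the treatment-coded contrast against the reference (identical to
    the difference of the adjusted means, whose margin terms cancel).
    """
    df = table.dropna(subset=[grouping, score_name]).reset_index(drop=True)
    if df.empty:
        raise AnalysisError(f"no rows with non-missing {grouping!r} and {score_name!r}")
    raw_means = df.groupby(grouping, observed=True)[score_name].mean()
    if reference_group is None:
        reference_group = raw_means.idxmin()
    elif reference_group not in raw_means.index:
        raise AnalysisError(f"reference group {reference_group!r} not present in {grouping!r}")

    X, names, levels_kept = _design(df, grouping, reference_group, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise AnalysisError(
            f"rank-deficient design for {score_name} ~ {grouping} + "
            + " + ".join(covariates)
            + ": some terms are confounded (columns: "
            + ", ".join(names)
            + ")"
        )
    y = df[score_name].to_numpy(float)
    fit = sm.OLS(y, X).fit()
    cov_beta = fit.cov_params()
    if use_t and fit.df_resid > 0:
        crit = sps.t.ppf(1 - alpha / 2, fit.df_resid)
    else:
        crit = sps.norm.ppf(1 - alpha / 2)

    weights = _margin_weights(df, names, levels_kept, margins)
    rows = []
    all_groups = sorted(pd.unique(df[grouping]))
    for g in all_groups:
        L = np.zeros(X.shape[1])
        L[0] = 1.0
        for j, name in enumerate(names):
            if name == f"{grouping}[{g}]":
                L[j] = 1.0
            elif name in weights:
                L[j] = weights[name]
        est = float(L @ fit.params)
        se = float(np.sqrt(L @ cov_beta @ L))
        if g == reference_group:
            p = diff = diff_lo = diff_hi = np.nan
        else:
            j = names.index(f"{grouping}[{g}]")
            p = float(fit.pvalues[j])
            diff = float(fit.params[j])
            dse = float(fit.bse[j])
            diff_lo, diff_hi = diff - crit * dse, diff + crit * dse
        rows.append(
            {
                "score": score_name,
                "grouping": grouping,
                "group": g,
                "n": int((df[grouping] == g).sum()),
                "estimate": est,
                "ci_low": est - crit * se,
                "ci_high": est + crit * se,
                "p_vs_reference": p,
                "diff_vs_reference": diff,
                "diff_ci_low": diff_lo,
                "diff_ci_high": diff_hi,
                "reference_group": reference_group,
            }
        )
    return pd.DataFrame(rows)


def standardized_adjusted_means(
    table: pd.DataFrame,
    score_names: Iterable[str],
    grouping: str,
    **kwargs,
) -> pd.DataFrame:
    """Adjusted means of z-standardized scores: the radar-chart matrix.

    Each score is standardized over the analyzed cohort (mean 0, SD 1
    with divisor n-1) before the adjusted-means model is fit, putting
    categories with different point ranges on a common scale. Returns a
    groups x scores matrix. Zero-variance scores are dropped with a
    warning.
    """
    df = table.dropna(subset=[grouping]).reset_index(drop=True)
    out: dict[str, pd.Series] = {}
    for score in score_names:
        sd = df[score].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"standardized_adjusted_means: dropping zero-variance score {score!r}")
            continue
        zdf = df.copy()
        zcol = f"__z_{score}"
        zdf[zcol] = (df[score] - df[score].mean()) / sd
        res = adjusted_means(zdf, zcol, grouping, **kwargs)
        out[score] = res.set_index("group")["estimate"]
    if not out:
        raise AnalysisError("all scores had zero variance")
    mat = pd.DataFrame(out)
    mat.index.name = "group"
    return mat


def significance_threshold(n_comparisons: int) -> float:
    """Bonferroni-adjusted alpha: 0.05 divided by the number of comparisons."""
    if n_comparisons < 1:
        raise AnalysisError("n_comparisons must be >= 1")
    return 0.05 / n_comparisons


@dataclass(frozen=True)
class TrendResult:
    """Slope of a severity score on a continuous molecular predictor."""

    score_name: str
    predictor: str
    slope: float
    slope_se: float
    slope_p: float
    n: int
    adjusted: bool


def trend_slope(
    table: pd.DataFrame,
    score_name: str,
    predictor: str,
    adjusted: bool = True,
    covariates: Sequence[str] = ("sex", "age_group"),
) -> TrendResult:
    """Linear trend of a score on codon position or deletion size.

    Fits ``score ~ predictor + sex + age_group`` (or the unadjusted
    simple regression) over the rows where the predictor is defined.
    The caller restricts the table to the intended molecular class
    (null coding variants for codon position, chromosomal deletions for
    deletion size).
    """
    df = table.dropna(subset=[predictor, score_name]).reset_index(drop=True)
    n = len(df)
    if n < 3:
        raise AnalysisError(f"trend on {predictor!r} needs >= 3 rows, got {n}")
    y = df[score_name].to_numpy(float)
    if np.ptp(y) == 0:
        return TrendResult(score_name, predictor, 0.0, 0.0, np.nan, n, adjusted)
    cols = [np.ones(n), df[predictor].to_numpy(float)]
    names = ["intercept", predictor]
    if adjusted:
        for cov in covariates:
            for level in sorted(pd.unique(df[cov]))[1:]:
                cols.append((df[cov] == level).to_numpy(float))
                names.append(f"{cov}[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AnalysisError(f"rank-deficient trend design on {predictor!r}")
    fit = sm.OLS(y, X).fit()
    return TrendResult(
        score_name=score_name,
        predictor=predictor,
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        slope_p=float(fit.pvalues[1]),
        n=n,
        adjusted=adjusted,
    )
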