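"""Lipid double-bond index and species-mean statistics.

Covers the composition and trait analyses run on species-site means: the
abundance-weighted double-bond index (DBI) per thylakoid lipid class, simple
OLS regressions (overall and per-site), thermal acclimation slopes, and
one-way ANOVA across sites with Tukey HSD post-hoc comparisons summarised
as a compact letter display.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    response: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    scope: str = "overall"


@dataclass
class AnovaResult:
    factor: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame
    letters: dict[str, str]


def compute_dbi(lipids: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted mean double-bond count per species, site and class.

    DBI = sum(abundance_i * double_bonds_i) / sum(abundance_i).  Classes with
    zero total abundance are undefined and flagged (NaN with a warning); the
    index is invariant under uniform rescaling of the abundances.
    """
    def _one(group: pd.DataFrame) -> float:
        total = group["abundance"].sum()
        if total <= 0:
            return float("nan")
        return float((group["abundance"] * group["double_bonds"]).sum() / total)

    out = (
        lipids.groupby(["species", "site", "lipid_class"], sort=True)
        .apply(_one, include_groups=False)
        .rename("dbi")
        .reset_index()
    )
    n_bad = int(out["dbi"].isna().sum())
    if n_bad:
        logger.warning("%d lipid class group(s) with zero total abundance (DBI undefined)", n_bad)
    return out


def ols_regress(
    data: pd.DataFrame, x: str, y: str, scope: str = "overall"
) -> RegressionResult | list[RegressionResult]:
    """Simple linear regression of ``y`` on ``x`` over species-site means.

    ``scope="overall"`` pools all rows; ``scope="per-site"`` returns one
    result per site.  Requires at least 3 paired finite values and non-zero
    predictor variance.
    """
    if scope == "per-site":
        return [
            _ols_one(sub, x, y, scope=f"site:{site}")
            for site, sub in data.groupby("site", sort=True)
        ]
    return _ols_one(data, x, y, scope="overall")


def _ols_one(data: pd.DataFrame, x: str, y: str, scope: str) -> RegressionResult:
    if x not in data.columns or y not in data.columns:
        raise KeyError(f"column not available: {x if x not in data.columns else y}")
    sub = data[[x, y]].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations for {y} ~ {x}, got {n}")
    xv = sub[x].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError(f"predictor {x} has zero variance")
    model = sm.OLS(sub[y].to_numpy(dtype=float), sm.add_constant(xv)).fit()
    return RegressionResult(
        response=y, predictor=x,
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared), p_value=float(model.pvalues[1]),
        n=n, scope=scope,
    )


def acclimation_slope(
    thresholds: pd.DataFrame,
    predictors: pd.DataFrame,
    predictor: str = "growth_temperature",
    kind: str = "T50",
) -> RegressionResult:
    """Pooled OLS slope of a tolerance threshold against a warming predictor.

    ``predictor`` is typically ``growth_temperature`` (from the trait table)
    or ``tleafmax``; the slope is in degC of threshold per degC of predictor
    (1.0 = full acclimation, 0 = none).
    """
    from .safety import _threshold_column

    thr = _threshold_column(thresholds, kind)
    join_keys = ["species", "site"] if "species" in predictors.columns else ["site"]
    merged = thr.merge(predictors, on=join_keys, how="inner")
    result = _ols_one(merged, predictor, "threshold", scope="overall")
    result.response = kind
    return result


def anova_oneway(
    data: pd.DataFrame, value: str, factor: str = "site", alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA on species means per site, with Tukey HSD letters.

    Levels with a single observation are excluded with a warning.  The
    compact letter display assigns shared letters to groups whose Tukey HSD
    comparison is not significant at ``alpha``; letters are ordered by
    descending group mean.
    """
    sub = data[[factor, value]].dropna()
    counts = sub.groupby(factor)[value].size()
    singles = counts[counts < 2].index.tolist()
    if singles:
        logger.warning("excluding %s level(s) with fewer than 2 values: %s", factor, singles)
        sub = sub[~sub[factor].isin(singles)]
    levels = sorted(sub[factor].unique())
    if len(levels) < 2:
        raise ValueError("one-way ANOVA needs at least 2 factor levels with >= 2 values")

    groups = [sub.loc[sub[factor] == lvl, value].to_numpy(dtype=float) for lvl in levels]
    df_between = len(levels) - 1
    df_within = sum(len(g) for g in groups) - len(levels)
    all_vals = sub[value].to_numpy(dtype=float)
    if np.ptp(all_vals) == 0:
        # degenerate: no variance anywhere, F = 0 and no pair differs
        tukey = pd.DataFrame(
            [
                {"group1": a, "group2": b, "meandiff": 0.0, "p-adj": 1.0,
                 "lower": 0.0, "upper": 0.0, "reject": False}
                for i, a in enumerate(levels) for b in levels[i + 1:]
            ]
        )
        letters = compact_letter_display(
            levels, {lvl: float(np.mean(g)) for lvl, g in zip(levels, groups)},
            {frozenset((a, b)) for i, a in enumerate(levels) for b in levels[i + 1:]},
        )
        return AnovaResult(factor, 0.0, df_between, df_within, 1.0, tukey, letters)

    f_stat, p = sps.f_oneway(*groups)
    tk = pairwise_tukeyhsd(all_vals, sub[factor].to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    means = {lvl: float(np.mean(g)) for lvl, g in zip(levels, groups)}
    nonsig = {
        frozenset((row["group1"], row["group2"]))
        for _, row in tukey.iterrows()
        if not bool(row["reject"])
    }
    letters = compact_letter_display(levels, means, nonsig)
    return AnovaResult(
        factor=factor, f_statistic=float(f_stat),
        df_between=df_between, df_within=df_within, p_value=float(p),
        tukey=tukey, letters=letters,
    )


def compact_letter_display(
    levels: list, means: dict, nonsignificant_pairs: set
) -> dict[str, str]:
    """Assign letters so two groups share a letter iff they are connected by
    a maximal clique of non-significant pairwise comparisons.

    Works by enumerating maximal cliques of the non-significance graph
    (each group is trivially non-different from itself); intended for the
    small numbers of levels typical of site comparisons.
    """
    if len(levels) > 15:
        raise ValueError("compact letter display supports at most 15 levels")
    lv = sorted(levels, key=lambda g: -means[g])

    def compatible(subset) -> bool:
        return all(
            frozenset((a, b)) in nonsignificant_pairs
            for a, b in itertools.combinations(subset, 2)
        )

    cliques: list[tuple] = []
    for r in range(len(lv), 0, -1):
        for subset in itertools.combinations(lv, r):
            if compatible(subset) and not any(set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    # keep deterministic letter order: cliques sorted by their best (highest) mean
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in lv}
    for letter, clique in zip("abcdefghijklmno", cliques):
        for g in clique:
            letters[g] += letter
    return letters


def site_summary(
    thresholds: pd.DataFrame,
    tsm: pd.DataFrame | None = None,
    tleafmax: pd.DataFrame | None = None,
    kinds: tuple[str, ...] = ("Tcrit", "T50", "T95"),
) -> pd.DataFrame:
    """Species-mean site summary of thresholds (and optionally Tleafmax/TSM).

    One row per site with the across-species mean and standard error of each
    threshold kind, mirroring the usual site-level reporting layout.
    """
    from .safety import _threshold_column

    out = None
    for kind in kinds:
        thr = _threshold_column(thresholds, kind)
        agg = thr.groupby("site", sort=True)["threshold"].agg(
            **{f"{kind}_mean": "mean",
               f"{kind}_se": lambda v: (
                   float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
               )}
        ).reset_index()
        out = agg if out is None else out.merge(agg, on="site")
    if tleafmax is not None:
        agg = tleafmax.groupby("site", sort=True)["tleafmax"].agg(
            tleafmax_mean="mean").reset_index()
        out = out.merge(agg, on="site", how="left")
    if tsm is not None:
        agg = tsm.groupby("site", sort=True)["tsm"].agg(tsm_mean="mean").reset_index()
        out = out.merge(agg, on="site", how="left")
    return out
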