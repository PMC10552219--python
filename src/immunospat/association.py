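"""Outcome association statistics.

Per-sample features are related to overall survival (OS) and radiological
complete response (rCR) with per-unit-increase estimates and
likelihood-ratio (LR) p-values:

* OS: Cox proportional-hazards fits (Efron tie handling); the hazard ratio
  is ``exp(beta)`` per unit of the variable, and the LR p-value comes from
  twice the log-partial-likelihood difference between nested models with
  and without the variable (chi-square, 1 df).
* rCR: maximum-likelihood logistic fits reporting odds ratios, LR p from
  the deviance difference.  (Odds ratios imply a logistic link even where a
  methods text says "linear regression"; see docs/methods.md.)

Supporting machinery: reverse Kaplan-Meier median follow-up,
Benjamini-Hochberg adjustment, tertile splits with KM curves and log-rank
tests, paired/unpaired primary-vs-metastasis contrasts, Spearman
correlation maps with average-linkage clustering, and a screen runner that
sweeps (variable x endpoint x subgroup x adjustment) cells and applies BH
across the whole family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

SUBGROUPS = {
    "all": lambda d: pd.Series(True, index=d.index),
    "ER+": lambda d: d["er_positive"] == 1,
    "ER-": lambda d: d["er_positive"] == 0,
    "rCR": lambda d: d["rcr"] == 1,
    "no-rCR": lambda d: d["rcr"] == 0,
    "primary": lambda d: d["sample_type"] == "primary",
    "metastasis": lambda d: d["sample_type"] == "metastasis",
}

# dot-plot shading tiers for raw LR p-values
TIER_EDGES = (0.05, 0.10)


def significance_tier(p: float) -> str:
    if math.isnan(p):
        return "na"
    if p < TIER_EDGES[0]:
        return "white"
    if p < TIER_EDGES[1]:
        return "light-gray"
    return "gray"


@dataclass
class AssociationResult:
    variable: str
    endpoint: str  # "OS" | "rCR"
    subgroup: str = "all"
    covariates: tuple = ()
    estimate: float = math.nan  # HR or OR per unit increase
    ci_low: float = math.nan
    ci_high: float = math.nan
    lr_p: float = math.nan
    bh_adjusted_p: float = math.nan
    n: int = 0
    n_events: int = 0
    estimable: bool = True
    reason: str | None = None

    @property
    def tier(self) -> str:
        return significance_tier(self.lr_p)


def _clean(records: pd.DataFrame, cols: list) -> pd.DataFrame:
    return records.dropna(subset=[c for c in cols if c in records.columns])


def cox_per_unit(
    records: pd.DataFrame,
    variable: str,
    covariates: tuple = (),
    time_col: str = "os_months",
    event_col: str = "death_event",
) -> AssociationResult:
    """Univariable or adjusted Cox fit with an LR test on ``variable``.

    Raises on zero events, on a constant variable, and on non-convergence;
    the screen runner catches these and flags the cell instead.
    """
    cols = [time_col, event_col, variable, *covariates]
    d = _clean(records, cols)[cols].astype(float)
    n, n_events = len(d), int(d[event_col].sum())
    if n_events == 0:
        raise ValueError("zero events")
    if d[variable].nunique() <= 1:
        raise ValueError(f"constant variable: {variable!r}")
    try:
        full = CoxPHFitter()
        full.fit(d, duration_col=time_col, event_col=event_col)
        ll_full = full.log_likelihood_
        if covariates:
            reduced = CoxPHFitter()
            reduced.fit(d[[time_col, event_col, *covariates]],
                        duration_col=time_col, event_col=event_col)
            ll_reduced = reduced.log_likelihood_
        else:
            # null (no-covariate) partial log-likelihood as stored by lifelines
            ll_reduced = full._ll_null_
    except Exception as e:  # lifelines raises ConvergenceError and others
        raise RuntimeError(f"Cox fit failed for {variable!r}: {e}") from e
    lr_stat = 2.0 * (ll_full - ll_reduced)
    lr_p = float(stats.chi2.sf(max(lr_stat, 0.0), df=1))
    beta = float(full.params_[variable])
    ci = full.confidence_intervals_.loc[variable]
    return AssociationResult(
        variable=variable, endpoint="OS", covariates=tuple(covariates),
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(ci.iloc[0])), ci_high=float(np.exp(ci.iloc[1])),
        lr_p=lr_p, n=n, n_events=n_events,
    )


def logistic_per_unit(
    records: pd.DataFrame,
    variable: str,
    covariates: tuple = (),
    outcome_col: str = "rcr",
) -> AssociationResult:
    """Logistic fit for a binary endpoint with an LR test on ``variable``."""
    cols = [outcome_col, variable, *covariates]
    d = _clean(records, cols)[cols].astype(float)
    y = d[outcome_col]
    if y.nunique() < 2:
        raise ValueError("single class")
    if d[variable].nunique() <= 1:
        raise ValueError(f"constant variable: {variable!r}")
    X_full = sm.add_constant(d[[variable, *covariates]])
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            full = sm.Logit(y, X_full).fit(disp=0)
            if covariates:
                reduced = sm.Logit(y, sm.add_constant(d[list(covariates)])).fit(disp=0)
                ll_reduced = reduced.llf
            else:
                ll_reduced = full.llnull
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as e:
            raise RuntimeError(f"complete separation for {variable!r}") from e
    lr_stat = 2.0 * (full.llf - ll_reduced)
    lr_p = float(stats.chi2.sf(max(lr_stat, 0.0), df=1))
    beta = float(full.params[variable])
    ci = full.conf_int().loc[variable]
    n_events = int(y.sum())
    return AssociationResult(
        variable=variable, endpoint="rCR", covariates=tuple(covariates),
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(ci.iloc[0])), ci_high=float(np.exp(ci.iloc[1])),
        lr_p=lr_p, n=len(d), n_events=n_events,
    )


def reverse_km_median(
    records: pd.DataFrame,
    time_col: str = "os_months",
    event_col: str = "death_event",
) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Censoring is treated as the event and deaths as censored; returns
    ``inf`` when the reversed survival curve never reaches 0.5
    ("not reached").
    """
    if len(records) == 0:
        raise ValueError("empty records")
    km = KaplanMeierFitter()
    km.fit(records[time_col], 1 - records[event_col])
    return float(km.median_survival_time_)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved.

    NaN entries (untestable cells) are passed through as NaN and do not
    count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def tertile_split(values) -> pd.Series:
    """Split into T1/T2/T3 at the empirical 1/3 and 2/3 quantiles.

    Ties at a cut go to the lower group; missing values yield missing
    labels.  Warns (and puts everything in T1) when all values coincide.
    """
    v = pd.Series(values, dtype=float)
    nonmiss = v.dropna()
    if len(nonmiss) < 3:
        raise ValueError("tertile split needs at least 3 non-missing values")
    q1, q2 = nonmiss.quantile([1 / 3, 2 / 3])
    if q1 == q2 and nonmiss.nunique() == 1:
        warnings.warn("all values identical; single tertile group", stacklevel=2)
    labels = pd.Series(pd.NA, index=v.index, dtype="string")
    labels[v <= q1] = "T1"
    labels[(v > q1) & (v <= q2)] = "T2"
    labels[v > q2] = "T3"
    return labels


def km_curves_by_group(
    records: pd.DataFrame,
    labels: pd.Series,
    time_col: str = "os_months",
    event_col: str = "death_event",
):
    """Product-limit curve per group plus a two-sided log-rank test.

    Returns ``(curves, logrank_p)`` where ``curves`` maps group label to a
    KM survival-function DataFrame; ``logrank_p`` is NaN for a single group.
    """
    labels = pd.Series(labels, index=records.index)
    keep = labels.notna()
    d, g = records[keep], labels[keep]
    groups = sorted(g.unique())
    if not groups:
        raise ValueError("no labelled subjects")
    curves = {}
    for grp in groups:
        sub = d[g == grp]
        km = KaplanMeierFitter()
        km.fit(sub[time_col], sub[event_col], label=str(grp))
        curves[grp] = km.survival_function_
    if len(groups) < 2:
        return curves, math.nan
    res = multivariate_logrank_test(d[time_col], g, d[event_col])
    return curves, float(res.p_value)


def primary_met_contrast(
    scores: pd.DataFrame,
    feature: str,
    paired: bool = False,
    sample_type_col: str = "sample_type",
    pair_col: str = "pair_id",
):
    """Mean difference (metastasis - primary) with a rank test.

    Unpaired: Mann-Whitney U across sample types.  Paired: Wilcoxon
    signed-rank (exact distribution) on within-pair differences.  Returns a
    dict with ``mean_difference``, ``p``, ``n_primary``/``n_metastasis`` or
    ``n_pairs``, and a ``reason`` when not computable.
    """
    d = scores
    prim = d.loc[d[sample_type_col] == "primary", [feature] + ([pair_col] if paired else [])]
    met = d.loc[d[sample_type_col] == "metastasis", [feature] + ([pair_col] if paired else [])]
    if len(prim) == 0 or len(met) == 0:
        raise ValueError("both sample types must be present")
    if paired:
        merged = prim.dropna(subset=[pair_col]).merge(
            met.dropna(subset=[pair_col]), on=pair_col, suffixes=("_p", "_m"))
        merged = merged.dropna(subset=[f"{feature}_p", f"{feature}_m"])
        if len(merged) == 0:
            raise ValueError("no complete pairs")
        diff = merged[f"{feature}_m"].to_numpy(float) - merged[f"{feature}_p"].to_numpy(float)
        if np.all(diff == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diff, method="exact").pvalue)
        return {"feature": feature, "mean_difference": float(diff.mean()), "p": p,
                "n_pairs": len(merged), "reason": None}
    pv, mv = prim[feature].dropna(), met[feature].dropna()
    if len(mv) == 0 or len(pv) == 0:
        side = "metastases" if len(mv) == 0 else "primaries"
        return {"feature": feature, "mean_difference": math.nan, "p": math.nan,
                "n_primary": len(pv), "n_metastasis": len(mv),
                "reason": f"feature missing in all {side}"}
    stat = stats.mannwhitneyu(mv, pv, alternative="two-sided")
    return {"feature": feature, "mean_difference": float(mv.mean() - pv.mean()),
            "p": float(stat.pvalue), "n_primary": len(pv), "n_metastasis": len(mv),
            "reason": None}


def correlation_cluster_map(scores: pd.DataFrame, min_obs: int = 3):
    """Pairwise-complete Spearman correlations with hierarchical ordering.

    Features with fewer than ``min_obs`` non-missing values are dropped
    with a warning.  Returns ``(rho, p, stars, leaf_order)``: correlation
    and p-value matrices, star tiers ("***" p<0.001, "**" p<0.01,
    "*" p<0.05, "" otherwise), and the average-linkage leaf order on
    distance 1 - rho.
    """
    num = scores.select_dtypes(include=[np.number])
    keep = [c for c in num.columns if num[c].notna().sum() >= min_obs]
    dropped = sorted(set(num.columns) - set(keep))
    if dropped:
        warnings.warn(f"dropping features with < {min_obs} observations: {dropped}",
                      stacklevel=2)
    if len(keep) < 2:
        raise ValueError("need at least 2 usable features")
    if len(num) < 3:
        raise ValueError("need at least 3 samples")
    cols = keep
    k = len(cols)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = num[[cols[i], cols[j]]].dropna()
            if len(pair) < min_obs:
                r, p = math.nan, math.nan
            else:
                r, p = stats.spearmanr(pair[cols[i]], pair[cols[j]])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pmat, index=cols, columns=cols)

    def star(p):
        if math.isnan(p):
            return ""
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

    stars = p_df.map(star)
    dist = 1.0 - np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # enforce exact symmetry for squareform
    order = leaves_list(average(squareform(dist, checks=False)))
    leaf_order = [cols[i] for i in order]
    return rho_df, p_df, stars, leaf_order


def group_comparisons(values, grouping):
    """Dispatch the right nonparametric test for a grouped comparison.

    Two groups: Mann-Whitney U.  More than two: Kruskal-Wallis H.  Returns
    ``(test_name, statistic, p)``.
    """
    v = pd.Series(values, dtype=float)
    g = pd.Series(grouping)
    keep = v.notna() & g.notna()
    v, g = v[keep], g[keep]
    groups = [v[g == lvl].to_numpy() for lvl in sorted(g.unique())]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(x) == 0 for x in groups):
        raise ValueError("empty group")
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return "mann-whitney", float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return "kruskal-wallis", float(res.statistic), float(res.pvalue)


@dataclass
class ScreenPlan:
    """What to sweep: variables x endpoints x subgroups x covariate sets."""

    variables: list
    endpoints: list = field(default_factory=lambda: ["OS", "rCR"])
    subgroups: list = field(default_factory=lambda: ["all"])
    covariate_sets: dict = field(default_factory=lambda: {"unadjusted": ()})


def run_association_screen(
    scores: pd.DataFrame,
    records: pd.DataFrame,
    plan: ScreenPlan,
) -> pd.DataFrame:
    """Execute every screen cell; BH adjustment spans the full family.

    ``scores`` (one row per sample, sample_id column) is joined to the
    clinical table on patient/sample id.  Cells that cannot be estimated
    (zero events in a subgroup, constant variable, separation) are flagged
    ``estimable = False`` with the reason, never silently dropped.
    """
    merged = records.merge(scores, left_on="patient_id", right_on="sample_id",
                           how="inner") if "sample_id" in scores.columns else records
    results: list[AssociationResult] = []
    for variable in plan.variables:
        for endpoint in plan.endpoints:
            for sub_name in plan.subgroups:
                mask = SUBGROUPS[sub_name](merged)
                sub = merged[mask]
                for cov_name, covs in plan.covariate_sets.items():
                    covs = tuple(c for c in covs
                                 if c != variable and _usable_covariate(sub, c, sub_name))
                    try:
                        if endpoint == "OS":
                            res = cox_per_unit(sub, variable, covs)
                        elif endpoint == "rCR":
                            res = logistic_per_unit(sub, variable, covs)
                        else:
                            raise ValueError(f"unknown endpoint {endpoint!r}")
                    except (ValueError, RuntimeError, KeyError) as e:
                        res = AssociationResult(
                            variable=variable, endpoint=endpoint,
                            covariates=covs, estimable=False, reason=str(e),
                            n=len(sub),
                        )
                    res.subgroup = sub_name
                    res.covariates = covs
                    results.append(res)
    table = pd.DataFrame([{
        "variable": r.variable, "endpoint": r.endpoint, "subgroup": r.subgroup,
        "covariates": "+".join(r.covariates) if r.covariates else "none",
        "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "lr_p": r.lr_p, "n": r.n, "n_events": r.n_events,
        "estimable": r.estimable, "reason": r.reason,
    } for r in results])
    table["bh_adjusted_p"] = bh_adjust(table["lr_p"])
    table["tier"] = table["lr_p"].map(significance_tier)
    return table


def _usable_covariate(d: pd.DataFrame, col: str, subgroup: str) -> bool:
    """Drop a covariate that is constant within the subgroup (e.g. rCR
    adjustment inside the rCR subgroup)."""
    return col in d.columns and d[col].nunique(dropna=True) > 1
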