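"""Clinicopathological statistics layer.

Conventions: per-ROI statistics are averaged over the three replicate
fields of each (case, stain, region, matter, adjacency) cell before any
testing; when regional stratification is dropped, region means are
averaged again to one value per case to avoid pseudoreplication.  Group
comparisons are normality-gated (Shapiro-Wilk at alpha = 0.05): normal
data get unpaired t-tests / ANOVA + Tukey, non-normal data get
Mann-Whitney U / pairwise Wilcoxon rank-sum with Holm-Sidak correction,
and no comparison is run if any group has n < 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.sandbox.stats.multicomp import MultiComparison
from statsmodels.stats.multitest import multipletests

import statsmodels.formula.api as smf

MIN_GROUP_N = 3
NORMALITY_ALPHA = 0.05

REGION_KEYS = ["case_id", "stain", "region", "matter", "adjacency"]


# ---------------------------------------------------------------------------
# triplicate averaging


def triplicate_average(
    per_roi: pd.DataFrame,
    value_cols: list,
    *,
    keys: list = REGION_KEYS,
    expected_replicates: int = 3,
) -> pd.DataFrame:
    """Average per-ROI statistics over replicate fields of a region cell.

    Returns one row per key combination with the arithmetic mean of each
    value column, the replicate count, and a ``complete`` flag (full
    triplicate).  Cells with zero replicates simply do not appear.
    """
    counts = per_roi.groupby(keys, observed=True).size()
    if (counts > expected_replicates).any():
        raise ValueError(f"more than {expected_replicates} replicates in a region cell")
    out = per_roi.groupby(keys, observed=True, as_index=False)[value_cols].mean()
    out["n_replicates"] = counts.to_numpy()
    out["complete"] = out["n_replicates"] == expected_replicates
    return out


def case_average(region_summary: pd.DataFrame, value_cols: list) -> pd.DataFrame:
    """Collapse region summaries to one value per (case, stain).

    The unstratified (boxplot) view: the mean over a case's region cells,
    so each case contributes a single observation.
    """
    return region_summary.groupby(["case_id", "stain"], observed=True, as_index=False)[
        value_cols
    ].mean()


# ---------------------------------------------------------------------------
# normality-gated group tests


@dataclass
class GroupTestResult:
    groups: dict  # name -> n
    tested: bool
    branch: str = ""  # parametric | nonparametric
    test: str = ""
    statistic: float = np.nan
    p_value: float = np.nan
    pairwise: pd.DataFrame | None = None
    normality_p: dict = field(default_factory=dict)
    reason: str = ""


def _is_normal(x: np.ndarray) -> tuple[bool, float]:
    if np.ptp(x) == 0:
        return False, 0.0  # degenerate sample: route to the rank branch
    p = float(stats.shapiro(x).pvalue)
    return p > NORMALITY_ALPHA, p


def choose_and_run_test(samples: dict, *, min_n: int = MIN_GROUP_N) -> GroupTestResult:
    """Normality-gated two- or three-group comparison.

    ``samples`` maps group name -> 1-d array.  Comparisons involving any
    group with n < ``min_n`` are refused (reported untested).  All groups
    normal by Shapiro-Wilk -> parametric branch (t-test, or ANOVA with
    Tukey pairwise); otherwise nonparametric (Mann-Whitney U, or pairwise
    Wilcoxon rank-sum with Holm-Sidak correction).
    """
    if len(samples) not in (2, 3):
        raise ValueError("choose_and_run_test supports 2 or 3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    ns = {k: len(v) for k, v in arrays.items()}
    small = [k for k, n in ns.items() if n < min_n]
    if small:
        return GroupTestResult(groups=ns, tested=False, reason=f"groups below n>={min_n}: {small}")
    normal, norm_p = {}, {}
    for k, v in arrays.items():
        normal[k], norm_p[k] = _is_normal(v)
    parametric = all(normal.values())
    values = list(arrays.values())
    names = list(arrays.keys())
    pairwise = None
    if len(arrays) == 2:
        if parametric:
            res = stats.ttest_ind(values[0], values[1], equal_var=True)
            test = "unpaired t-test"
        else:
            res = stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
            test = "Mann-Whitney U"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        if parametric:
            res = stats.f_oneway(*values)
            statistic, p = float(res.statistic), float(res.pvalue)
            test = "one-way ANOVA + Tukey"
            stacked = np.concatenate(values)
            labels = np.concatenate([[n] * len(v) for n, v in zip(names, values)])
            tk = MultiComparison(stacked, labels).tukeyhsd()
            pairwise = pd.DataFrame(
                data=tk.summary().data[1:], columns=tk.summary().data[0]
            )[["group1", "group2", "p-adj"]].rename(columns={"p-adj": "p_adj"})
        else:
            res = stats.kruskal(*values)
            statistic, p = float(res.statistic), float(res.pvalue)
            test = "pairwise Wilcoxon + Holm-Sidak"
            pairs, raw = [], []
            for a, b in itertools.combinations(names, 2):
                raw.append(
                    float(
                        stats.mannwhitneyu(
                            arrays[a], arrays[b], alternative="two-sided"
                        ).pvalue
                    )
                )
                pairs.append((a, b))
            adj = multipletests(raw, method="holm-sidak")[1]
            pairwise = pd.DataFrame(
                {
                    "group1": [p[0] for p in pairs],
                    "group2": [p[1] for p in pairs],
                    "p_raw": raw,
                    "p_adj": adj,
                }
            )
    return GroupTestResult(
        groups=ns,
        tested=True,
        branch="parametric" if parametric else "nonparametric",
        test=test,
        statistic=statistic,
        p_value=p,
        pairwise=pairwise,
        normality_p=norm_p,
    )


# ---------------------------------------------------------------------------
# Spearman correlation matrices


def spearman_pair(x, y) -> tuple[float, float]:
    """Spearman rho and p; NaN for constant input or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(
    summaries: pd.DataFrame,
    variables: list,
    *,
    group_col: str = "group",
) -> pd.DataFrame:
    """Pairwise Spearman correlations per group (tidy output).

    One row per (group, var_x, var_y) with rho, p and n; computed on the
    region-summary rows (post triplicate averaging) with pairwise-complete
    observations.
    """
    rows = []
    for group, sub in summaries.groupby(group_col, observed=True):
        for vx, vy in itertools.combinations(variables, 2):
            pair = sub[[vx, vy]].dropna()
            rho, p = spearman_pair(pair[vx], pair[vy])
            rows.append(
                {
                    "group": group,
                    "var_x": vx,
                    "var_y": vy,
                    "rho": rho,
                    "p_value": p,
                    "n": len(pair),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regression coefficient comparison


@dataclass
class RegressionComparison:
    reference: str
    per_group: pd.DataFrame  # group, intercept, slope, se's, n
    intercept_diff_p: dict  # group -> p (vs reference)
    slope_diff_p: dict  # group -> p (vs reference)
    model_summary: str = ""


def compare_regressions(
    x,
    y,
    groups,
    *,
    reference: str | None = None,
) -> RegressionComparison:
    """Fit y ~ x within groups and compare coefficients between groups.

    A single interaction model ``y ~ x * group`` supplies the tests: the
    group main effect tests the intercept difference and the x:group
    interaction tests the slope difference against the reference group.
    Per-group slopes/intercepts equal the separate least-squares fits.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float), "g": list(groups)})
    if df[["x", "y"]].isna().any().any():
        df = df.dropna()
    levels = sorted(df["g"].unique())
    for lev in levels:
        if (df["g"] == lev).sum() < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 points")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among groups {levels}")

    per_rows = []
    for lev in levels:
        sub = df[df["g"] == lev]
        fit = smf.ols("y ~ x", data=sub).fit()
        per_rows.append(
            {
                "group": lev,
                "n": len(sub),
                "intercept": float(fit.params["Intercept"]),
                "slope": float(fit.params["x"]),
                "intercept_se": float(fit.bse["Intercept"]),
                "slope_se": float(fit.bse["x"]),
            }
        )
    per_group = pd.DataFrame(per_rows)

    intercept_p: dict = {}
    slope_p: dict = {}
    summary = ""
    if len(levels) > 1:
        model = smf.ols(
            f"y ~ x * C(g, Treatment(reference={reference!r}))", data=df
        ).fit()
        summary = str(model.summary())
        for lev in levels:
            if lev == reference:
                continue
            main = f"C(g, Treatment(reference={reference!r}))[T.{lev}]"
            inter = f"x:{main}"
            intercept_p[lev] = float(model.pvalues[main])
            slope_p[lev] = float(model.pvalues[inter])
    return RegressionComparison(reference, per_group, intercept_p, slope_p, summary)


# ---------------------------------------------------------------------------
# grading concordance


def grade_concordance(digital, manual) -> tuple[float, float]:
    """Spearman concordance between digital scores and manual ordinal grades.

    Statistics are computed on the raw paired values (any display jitter
    belongs to plotting, never here).
    """
    digital = np.asarray(digital, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if len(digital) != len(manual):
        raise ValueError("paired observations required")
    if len(digital) < 3:
        raise ValueError("need >= 3 pairs for a concordance estimate")
    res = stats.spearmanr(digital, manual)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ddCt fold-change analysis


@dataclass
class QPCRResult:
    per_sample: pd.DataFrame  # sample, group, dct, ddct, fold_change
    excluded: list
    t_stat: float
    p_value: float
    levene_p: float
    mean_log2_fc_disease: float


def ddct_analysis(
    ct_table: pd.DataFrame,
    *,
    target_gene: str = "FUS",
    reference_gene: str = "18S",
    control_group: str = "control",
    triplicate_sd_cutoff: float = 0.5,
) -> QPCRResult:
    """ddCt relative-expression analysis of a triplicate Ct table.

    Per sample: dCt = mean Ct(target) - mean Ct(reference) over technical
    replicates; samples whose triplicate Ct sd exceeds the cutoff for
    either gene are excluded.  ddCt is taken relative to the mean control
    dCt and fold change = 2**-ddCt.  Groups are compared with an unpaired
    t-test after a Levene homogeneity check (flagged, not gating).
    """
    genes = set(ct_table["gene"].unique())
    for g in (target_gene, reference_gene):
        if g not in genes:
            raise ValueError(f"gene {g!r} missing from the Ct table")
    stats_tbl = (
        ct_table[ct_table["gene"].isin([target_gene, reference_gene])]
        .groupby(["sample_id", "group", "gene"], observed=True)["ct"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    wide_sd = stats_tbl.pivot(index=["sample_id", "group"], columns="gene", values="std")
    wide_mean = stats_tbl.pivot(index=["sample_id", "group"], columns="gene", values="mean")
    bad = wide_sd.fillna(0.0).max(axis=1) > triplicate_sd_cutoff
    excluded = [s for (s, _g), flag in bad.items() if flag]
    kept = wide_mean[~bad.to_numpy()]
    missing = kept[[target_gene, reference_gene]].isna().any(axis=1)
    if missing.any():
        raise ValueError("samples missing target or reference gene measurements")
    per = kept.reset_index()
    per["dct"] = per[target_gene] - per[reference_gene]
    control_dct = per.loc[per["group"] == control_group, "dct"]
    if control_dct.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    per["ddct"] = per["dct"] - control_dct.mean()
    per["fold_change"] = np.power(2.0, -per["ddct"])
    dis = per.loc[per["group"] != control_group, "ddct"].to_numpy()
    ctl = per.loc[per["group"] == control_group, "ddct"].to_numpy()
    if len(dis) >= 2 and len(ctl) >= 2:
        levene_p = float(stats.levene(ctl, dis).pvalue)
        t = stats.ttest_ind(dis, ctl, equal_var=True)
        t_stat, p = float(t.statistic), float(t.pvalue)
    else:
        levene_p, t_stat, p = np.nan, np.nan, np.nan
    return QPCRResult(
        per_sample=per[["sample_id", "group", "dct", "ddct", "fold_change"]],
        excluded=excluded,
        t_stat=t_stat,
        p_value=p,
        levene_p=levene_p,
        mean_log2_fc_disease=float(-dis.mean()) if len(dis) else np.nan,
    )
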