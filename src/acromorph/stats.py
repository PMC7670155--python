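"""Reliability metrics, three-group comparisons and reference-range reports.

CV% and ICC% quantify measurement reliability; one-way ANOVA (from raw
values or from per-group summaries), Welch/pooled pairwise tests and signed
percent differences compare the three cohorts; 95% reference ranges supply
risk thresholds from their upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatisticsError

GROUP_ORDER = ("control", "nii", "ii")

#: Published risk cutoffs: upper bounds of the impingement-injury group's 95%
#: reference ranges for the AALP widths and AP-diameter ratio.  These are
#: read-in reference constants, not quantities this package recomputes.
RISK_THRESHOLDS = {"a_mm": 16.8, "b_mm": 12.9, "ratio_percent": 33.5}


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def cv_percent(table: pd.DataFrame, value: str = "value",
               subject: str = "subject") -> float:
    """Within-subject coefficient of variation, percent.

    *table* holds one rater's replicate readings (>= 2 per subject for at
    least one subject).  CV% = 100 * sqrt(mean within-subject variance) /
    grand mean.
    """
    grand = table[value].mean()
    if abs(grand) < 1e-12:
        raise StatisticsError("grand mean is zero; CV% undefined")
    per_subject = table.groupby(subject)[value].agg(["var", "count"])
    per_subject = per_subject[per_subject["count"] >= 2]
    if per_subject.empty:
        raise StatisticsError("need at least one subject with >= 2 replicates")
    return float(100.0 * np.sqrt(per_subject["var"].mean()) / grand)


def icc_percent(table: pd.DataFrame, value: str = "value",
                subject: str = "subject", rater: str = "rater") -> float:
    """Two-way random-effects, absolute-agreement, single-measures ICC, x100.

    Requires a complete subjects x raters grid with one reading per cell.
    """
    wide = table.pivot_table(index=subject, columns=rater, values=value)
    if wide.isna().any().any():
        raise StatisticsError("ICC requires a complete subject x rater table")
    n, k = wide.shape
    if n < 5 or k < 2:
        raise StatisticsError("ICC needs >= 5 subjects and >= 2 raters")
    x = wide.to_numpy()
    grand = x.mean()
    if np.allclose(x, grand):
        raise StatisticsError("zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(100.0 * icc)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    flags: tuple = ()


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Classic fixed-effects one-way ANOVA on raw values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise StatisticsError("ANOVA needs >= 2 groups with n >= 2 each")
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    dfb, dfw = len(groups) - 1, int(ns.sum()) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, dfb, dfw)
        return AnovaResult(float("inf"), 0.0, dfb, dfw, flags=("zero_within_variance",))
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), p, dfb, dfw)


def anova_from_summary(ns, means, sds) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, SD) summaries.

    Algebraically identical to :func:`anova_oneway` on the raw data the
    summaries came from.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if len(ns) < 2 or np.any(ns < 2):
        raise StatisticsError("summary ANOVA needs >= 2 groups with n >= 2 each")
    grand = (ns * means).sum() / ns.sum()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    dfb, dfw = len(ns) - 1, int(ns.sum()) - len(ns)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, dfb, dfw)
        return AnovaResult(float("inf"), 0.0, dfb, dfw, flags=("zero_within_variance",))
    f = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(f), float(sps.f.sf(f, dfb, dfw)), dfb, dfw)


def percent_difference(reference: float, comparison: float,
                       decimals: int | None = 1) -> float:
    """Signed percent change of *comparison* relative to *reference*.

    Reported to one decimal by default; pass ``decimals=None`` for the exact
    value (which satisfies (1 + pd(a,b)/100)(1 + pd(b,a)/100) = 1).
    """
    if reference == 0:
        raise StatisticsError("reference mean is zero; percent difference undefined")
    value = 100.0 * (comparison - reference) / reference
    return value if decimals is None else round(value, decimals)


def pairwise_tests(groups: dict[str, np.ndarray], method: str = "welch",
                   bonferroni: bool = False) -> dict[tuple[str, str], float]:
    """Two-sample t-test p-values for every group pair.

    ``method``: ``welch`` (unequal variances, default) or ``pooled``.
    With *bonferroni* the p-values are multiplied by the number of pairs
    and capped at 1.
    """
    if method not in ("welch", "pooled"):
        raise ValueError(f"unknown pairwise method {method!r}")
    names = list(groups)
    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i + 1, len(names))]
    out = {}
    for g1, g2 in pairs:
        x, y = np.asarray(groups[g1], float), np.asarray(groups[g2], float)
        if len(x) < 2 or len(y) < 2:
            raise StatisticsError(f"pair ({g1}, {g2}) needs n >= 2 in both groups")
        res = sps.ttest_ind(x, y, equal_var=(method == "pooled"))
        p = float(res.pvalue)
        if bonferroni:
            p = min(p * len(pairs), 1.0)
        out[(g1, g2)] = p
    return out


def reference_range_95(values, n_min_percentile: int = 20) -> dict:
    """Central 95% reference range by two methods.

    Returns ``{"percentile": (lo, hi) | None, "normal": (lo, hi), "flags"}``.
    The percentile method (linear interpolation) is refused below
    *n_min_percentile* observations; the normal method (mean +/- 1.96 SD) is
    then flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise StatisticsError("empty sample")
    flags = []
    mean, sd = float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0
    normal = (mean - 1.96 * sd, mean + 1.96 * sd)
    if x.size < n_min_percentile:
        flags.append("percentile_refused_small_n")
        percentile = None
    else:
        lo, hi = np.percentile(x, [2.5, 97.5])
        percentile = (float(lo), float(hi))
    return {"percentile": percentile, "normal": normal, "flags": tuple(flags)}


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise StatisticsError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise StatisticsError("constant sample; normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Everything the three-group comparison stage produces."""

    summaries: pd.DataFrame        # group x parameter n/mean/sd/CI columns
    anova: pd.DataFrame            # per-parameter F, dfs, p
    pairwise: pd.DataFrame         # per-parameter pairwise p + percent diff
    normality: pd.DataFrame        # per group x parameter W, p
    parameters: tuple
    flags: dict = field(default_factory=dict)

    def significant(self, pair: tuple[str, str], alpha: float = 0.05) -> dict:
        sel = self.pairwise[(self.pairwise["group_1"] == pair[0])
                            & (self.pairwise["group_2"] == pair[1])]
        return {row.parameter: row.p < alpha for row in sel.itertuples()}

    def to_csv(self, path) -> None:
        self.summaries.to_csv(path, index=False)

    def render_text(self) -> str:
        lines = ["parameter | " + " | ".join(
            f"{g}: mean+/-SD (n)" for g in GROUP_ORDER) + " | F | p"]
        for p in self.parameters:
            cells = []
            for g in GROUP_ORDER:
                row = self.summaries[(self.summaries["group"] == g)
                                     & (self.summaries["parameter"] == p)].iloc[0]
                cells.append(f"{g}: {row['mean']:.1f}+/-{row['sd']:.1f} ({int(row['n'])})")
            arow = self.anova[self.anova["parameter"] == p].iloc[0]
            lines.append(f"{p} | " + " | ".join(cells)
                         + f" | {arow['F']:.2f} | {arow['p']:.4f}")
        return "\n".join(lines)


def build_table3_report(cohort: pd.DataFrame, parameters=None,
                        pairwise_method: str = "welch",
                        bonferroni: bool = False) -> ComparisonReport:
    """Per-parameter group summaries, overall ANOVA, pairwise tests and
    percent differences for a cohort table with a ``group`` column."""
    from .measures import PARAMETERS

    parameters = tuple(parameters) if parameters is not None else PARAMETERS
    missing = [p for p in parameters if p not in cohort.columns]
    if missing:
        raise StatisticsError(f"cohort table is missing parameter columns: {missing}")
    groups_present = [g for g in GROUP_ORDER if g in set(cohort["group"])]
    if len(groups_present) < 2:
        raise StatisticsError("cohort table must contain at least two groups")

    summary_rows, anova_rows, pair_rows, norm_rows = [], [], [], []
    for p in parameters:
        by_group = {g: cohort.loc[cohort["group"] == g, p].to_numpy()
                    for g in groups_present}
        for g, x in by_group.items():
            rr = reference_range_95(x)
            row = {"group": g, "parameter": p, "n": len(x),
                   "mean": float(x.mean()), "sd": float(x.std(ddof=1))}
            if rr["percentile"] is not None:
                row["ci95_low_pct"], row["ci95_high_pct"] = rr["percentile"]
            row["ci95_low_norm"], row["ci95_high_norm"] = rr["normal"]
            summary_rows.append(row)
            try:
                w, pv = normality_test(x)
                norm_rows.append({"group": g, "parameter": p, "W": w, "p": pv,
                                  "normal_at_05": pv >= 0.05})
            except StatisticsError:
                norm_rows.append({"group": g, "parameter": p, "W": np.nan,
                                  "p": np.nan, "normal_at_05": False})
        res = anova_oneway(list(by_group.values()))
        anova_rows.append({"parameter": p, "F": res.F, "p": round(res.p, 4),
                           "df_between": res.df_between, "df_within": res.df_within})
        pvals = pairwise_tests(by_group, method=pairwise_method,
                               bonferroni=bonferroni)
        for (g1, g2), pv in pvals.items():
            pair_rows.append({
                "parameter": p, "group_1": g1, "group_2": g2,
                "percent_difference": percent_difference(
                    by_group[g1].mean(), by_group[g2].mean()),
                "p": round(pv, 4),
            })
    return ComparisonReport(
        summaries=pd.DataFrame(summary_rows),
        anova=pd.DataFrame(anova_rows),
        pairwise=pd.DataFrame(pair_rows),
        normality=pd.DataFrame(norm_rows),
        parameters=parameters,
        flags={"pairwise_method": pairwise_method, "bonferroni": bonferroni},
    )


def reliability_report(table: pd.DataFrame) -> pd.DataFrame:
    """CV% (first rater's replicates) and ICC% (rater means) per parameter.

    *table* is the long format of :func:`acromorph.synthetic.simulate_rater_table`.
    """
    rows = []
    first_rater = table["rater"].min()
    for p, sub in table.groupby("parameter"):
        one = sub[sub["rater"] == first_rater]
        cv = cv_percent(one)
        per_reading = sub.groupby(["subject", "rater"], as_index=False)["value"].mean()
        icc = icc_percent(per_reading)
        rows.append({"parameter": p, "cv_percent": cv, "icc_percent": icc,
                     "n_raters": sub["rater"].nunique(),
                     "n_replicates": sub["replicate"].nunique()})
    return pd.DataFrame(rows)
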