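"""Nonparametric comparison battery.

Summaries are median with the (Q3-Q1) interquartile range; independent
groups (controls vs tumors) are compared with the two-sided Mann-Whitney U
test and primary/recurrent tumor pairs with the two-sided Wilcoxon
signed-rank test, mirroring the small-cohort FFPE setting this pipeline
targets: heavily tied, skewed, far-from-normal percentages and scores.

Exact p-values (scipy's exact distributions, equivalent to full enumeration
of label assignments / sign patterns) are used for small tie-free samples;
otherwise a normal approximation with midranks, tie-corrected variance and a
0.5 continuity correction is applied.  No multiple-testing correction is
made by default (raw p per marker); Benjamini-Hochberg is optional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

#: sample-size cutoffs below which the exact null distribution is used
MWU_EXACT_MAX_N = 8
WILCOXON_EXACT_MAX_N = 12

QUANTILE_RULES = {
    "linear": "linear",    # interpolation between order statistics (type 7)
    "weibull": "weibull",  # SPSS-style weighted average (type 6)
}


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str            # "exact" or "approximate"
    degenerate: bool = False


@dataclass
class ComparisonResult:
    measure: str
    comparison: str
    test: str
    n1: int
    n2: int
    statistic: float
    p_value: float
    method: str
    degenerate: bool
    group1: GroupSummary
    group2: GroupSummary
    p_value_bh: float | None = None

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_value < 0.01


def median_iqr(values, group: str = "", rule: str = "linear") -> GroupSummary:
    """Median and quartiles; missing values are dropped first.

    ``rule='linear'`` interpolates between order statistics (the common
    default); ``rule='weibull'`` is the weighted-average definition used by
    some commercial packages — the two differ for small n.
    """
    if rule not in QUANTILE_RULES:
        raise ValidationError(f"unknown quantile rule {rule!r}")
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValidationError("no values left after dropping missing")
    method = QUANTILE_RULES[rule]
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=method)
    return GroupSummary(group=group, n=int(arr.size), median=float(med),
                        q1=float(q1), q3=float(q3))


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def _normal_two_sided_p(z_numerator: float, variance: float) -> float:
    """Continuity-corrected two-sided normal p from a centered statistic."""
    if variance <= 0:
        return 1.0
    shrunk = max(abs(z_numerator) - 0.5, 0.0)
    z = shrunk / math.sqrt(variance)
    return min(1.0, 2.0 * scipy.stats.norm.sf(z))


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    ``mode='exact'`` uses the exact null distribution (full enumeration of
    label assignments); ``mode='approximate'`` a normal approximation with
    tie-corrected variance and continuity correction; ``mode='auto'`` picks
    exact when both groups have <= 8 observations and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann-Whitney requires at least one value per group")
    if mode not in ("auto", "exact", "approximate"):
        raise ValidationError(f"unknown mode {mode!r}")
    combined = np.concatenate([x, y])
    ties = _has_ties(combined)
    if mode == "auto":
        mode = "exact" if (x.size <= MWU_EXACT_MAX_N and y.size <= MWU_EXACT_MAX_N
                           and not ties) else "approximate"

    ranks = scipy.stats.rankdata(combined)
    u1 = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    mean_u = x.size * y.size / 2.0

    if mode == "exact":
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          method="exact")
    if u1 == mean_u:
        return TestResult(statistic=u1, p_value=1.0, method="approximate")
    n = combined.size
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum())
    variance = (x.size * y.size / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    p = _normal_two_sided_p(u1 - mean_u, variance)
    degenerate = variance <= 0
    return TestResult(statistic=u1, p_value=p, method="approximate", degenerate=degenerate)


def wilcoxon_signed_rank(differences, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original rule); if all
    differences are zero the result is degenerate with p = 1.  The statistic
    is W = min(T+, T-) over signed midranks.  ``mode='exact'`` enumerates the
    2^n sign patterns; ``mode='auto'`` does so for n <= 12 without tied
    absolute differences, else applies the tie/continuity-corrected normal
    approximation.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValidationError("Wilcoxon requires at least one paired difference")
    if mode not in ("auto", "exact", "approximate"):
        raise ValidationError(f"unknown mode {mode!r}")
    d = d[d != 0.0]
    if d.size == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="degenerate", degenerate=True)

    absd = np.abs(d)
    ranks = scipy.stats.rankdata(absd)
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    w = min(t_plus, t_minus)
    ties = _has_ties(absd)
    if mode == "auto":
        mode = "exact" if (d.size <= WILCOXON_EXACT_MAX_N and not ties) else "approximate"

    if mode == "exact":
        res = scipy.stats.wilcoxon(d, alternative="two-sided", method="exact")
        return TestResult(statistic=w, p_value=float(res.pvalue), method="exact")
    n = d.size
    mean_t = n * (n + 1) / 4.0
    if t_plus == mean_t:
        return TestResult(statistic=w, p_value=1.0, method="approximate")
    _, counts = np.unique(absd, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum())
    variance = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    p = _normal_two_sided_p(t_plus - mean_t, variance)
    return TestResult(statistic=w, p_value=p, method="approximate",
                      degenerate=variance <= 0)


# ---------------------------------------------------------------------------
# Cohort comparison battery
# ---------------------------------------------------------------------------

def _pivot(measures: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "measure", "value"}
    missing = required - set(measures.columns)
    if missing:
        raise ValidationError(f"measure table lacks columns {sorted(missing)}")
    return measures


def compare_groups(
    measures: pd.DataFrame,
    design: pd.DataFrame,
    control_group: str = "auto",
    quantile_rule: str = "linear",
    mode: str = "auto",
    bh: bool = False,
) -> list[ComparisonResult]:
    """Run the full comparison plan for every measure.

    Plan per measure: control vs GBM1 and control vs GBM2 (unpaired
    Mann-Whitney), then GBM1 vs GBM2 (paired Wilcoxon on pair_id-matched
    values; pairs with either member missing are excluded and n reports the
    complete pairs).  ``control_group='auto'`` picks MC if any MC sample has
    a value for the measure, else HC.  With ``bh=True`` Benjamini-Hochberg
    adjusted p-values are attached across all comparisons (see
    :func:`results_to_frame`); raw p-values are reported either way.
    """
    measures = _pivot(measures)
    dmap = design.set_index("sample_id")
    unknown = sorted(set(measures["sample_id"]) - set(dmap.index))
    if unknown:
        raise ValidationError(f"measured sample(s) absent from design: {unknown}")

    results: list[ComparisonResult] = []
    for measure, block in measures.groupby("measure", sort=True):
        block = block.dropna(subset=["value"])
        values = block.set_index("sample_id")["value"]
        groups = dmap.loc[values.index, "group"]
        by_group = {g: values[groups == g] for g in groups.unique()}

        if control_group == "auto":
            ctrl = "MC" if len(by_group.get("MC", ())) else "HC"
        else:
            ctrl = control_group
        ctrl_vals = by_group.get(ctrl, pd.Series(dtype=float))

        for tumor in ("GBM1", "GBM2"):
            tumor_vals = by_group.get(tumor, pd.Series(dtype=float))
            if len(ctrl_vals) == 0 or len(tumor_vals) == 0:
                continue
            tr = mann_whitney_u(ctrl_vals, tumor_vals, mode=mode)
            results.append(ComparisonResult(
                measure=str(measure), comparison=f"{ctrl} vs {tumor}",
                test="Mann-Whitney U", n1=len(ctrl_vals), n2=len(tumor_vals),
                statistic=tr.statistic, p_value=tr.p_value, method=tr.method,
                degenerate=tr.degenerate,
                group1=median_iqr(ctrl_vals, ctrl, quantile_rule),
                group2=median_iqr(tumor_vals, tumor, quantile_rule),
            ))

        g1 = by_group.get("GBM1", pd.Series(dtype=float))
        g2 = by_group.get("GBM2", pd.Series(dtype=float))
        if len(g1) and len(g2):
            pair_ids = dmap["pair_id"]
            for sid in list(g1.index) + list(g2.index):
                pid = pair_ids.get(sid, "")
                if not pid:
                    raise ValidationError(
                        f"paired comparison: sample {sid!r} has no pair_id"
                    )
                partners = dmap.index[(pair_ids == pid) & (dmap.index != sid)]
                if len(partners) == 0:
                    raise ValidationError(
                        f"paired comparison: pair {pid!r} has no partner sample"
                    )
            p1 = g1.groupby(pair_ids.loc[g1.index]).first()
            p2 = g2.groupby(pair_ids.loc[g2.index]).first()
            common = p1.index.intersection(p2.index)
            if len(common):
                diffs = (p1.loc[common] - p2.loc[common]).to_numpy()
                tr = wilcoxon_signed_rank(diffs, mode=mode)
                results.append(ComparisonResult(
                    measure=str(measure), comparison="GBM1 vs GBM2",
                    test="Wilcoxon signed-rank", n1=len(common), n2=len(common),
                    statistic=tr.statistic, p_value=tr.p_value, method=tr.method,
                    degenerate=tr.degenerate,
                    group1=median_iqr(p1.loc[common], "GBM1", quantile_rule),
                    group2=median_iqr(p2.loc[common], "GBM2", quantile_rule),
                ))
    if bh and results:
        adjusted = scipy.stats.false_discovery_control(
            [r.p_value for r in results], method="bh"
        )
        for r, p_adj in zip(results, adjusted):
            r.p_value_bh = float(p_adj)
    return results


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into the report table."""
    rows = []
    for r in results:
        row = {
            "measure": r.measure, "comparison": r.comparison, "test": r.test,
            "n1": r.n1, "n2": r.n2, "statistic": r.statistic, "p_value": r.p_value,
            "method": r.method, "degenerate": r.degenerate,
            "significant_0.05": r.significant_05, "significant_0.01": r.significant_01,
        }
        for label, summ in (("group1", r.group1), ("group2", r.group2)):
            d = asdict(summ)
            row.update({f"{label}_{k}": v for k, v in d.items()})
        if r.p_value_bh is not None:
            row["p_value_bh"] = r.p_value_bh
        rows.append(row)
    return pd.DataFrame(rows)
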