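"""Paired cohort comparison and robustness-spread analysis.

The comparison protocol: for each metric, run Shapiro-Wilk on the paired
differences; if they look normal use a paired t-test, otherwise the
Wilcoxon signed-rank test (exact null for n <= 25 without rank ties,
normal approximation with continuity correction above).  Two-sided
throughout, alpha = 0.05, no multiple-testing correction (per-metric
reporting).  Identical pairs (zero-variance differences) are reported as
degenerate with p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class PairedTestResult:
    metric: str
    pair: str
    test_used: Literal["paired-t", "wilcoxon-signed-rank", "degenerate"]
    statistic: float
    p_value: float
    mean_difference: float
    significant: bool
    alpha: float = 0.05


def _wilcoxon(diffs: np.ndarray) -> tuple[float, float]:
    nonzero = diffs[diffs != 0]  # zero differences dropped (documented)
    if nonzero.size == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(nonzero))
    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    if nonzero.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(nonzero, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    del ranks
    return float(res.statistic), float(res.pvalue)


def paired_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "",
    pair: str = "",
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    test: Literal["auto", "t", "wilcoxon"] = "auto",
) -> PairedTestResult:
    """Compare two paired per-patient samples of one metric.

    ``test='auto'`` chooses paired-t vs Wilcoxon from Shapiro-Wilk on the
    differences at ``normality_alpha``; forcing either test is supported.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape} (samples must be paired)")
    if a.size < 5:
        raise ValueError("paired comparison needs at least 5 pairs")
    diffs = b - a
    mean_diff = float(diffs.mean())
    if np.all(diffs == diffs[0]) and diffs[0] == 0:
        return PairedTestResult(metric, pair, "degenerate", 0.0, 1.0, 0.0, False, alpha)
    if test == "auto":
        if np.ptp(diffs) == 0:
            use_t = True  # constant nonzero shift: trivially "normal"
        else:
            use_t = sps.shapiro(diffs).pvalue > normality_alpha
        test = "t" if use_t else "wilcoxon"
    if test == "t":
        res = sps.ttest_rel(b, a)
        stat, p = float(res.statistic), float(res.pvalue)
        used = "paired-t"
    else:
        stat, p = _wilcoxon(diffs)
        used = "wilcoxon-signed-rank"
    return PairedTestResult(metric, pair, used, stat, p, mean_diff, p < alpha, alpha)


def compare_strategies(
    table: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
    metrics: Sequence[str],
    alpha: float = 0.05,
    test: Literal["auto", "t", "wilcoxon"] = "auto",
) -> pd.DataFrame:
    """Run paired_compare per metric for each (strategy_a, strategy_b) pair.

    ``table`` holds one row per (patient_id, strategy); patients missing
    either arm of a pair are excluded pairwise.
    """
    rows = []
    for strat_a, strat_b in pairs:
        wide = table.pivot(index="patient_id", columns="strategy", values=list(metrics))
        for metric in metrics:
            sub = wide[metric][[strat_a, strat_b]].dropna()
            result = paired_compare(
                sub[strat_a], sub[strat_b],
                metric=metric, pair=f"{strat_b}_vs_{strat_a}", alpha=alpha, test=test,
            )
            rows.append(result.__dict__)
    return pd.DataFrame(rows)


def cohort_summary(table: pd.DataFrame, metrics: Sequence[str]) -> pd.DataFrame:
    """Mean +- sample standard deviation per (metric, strategy)."""
    if table["patient_id"].nunique() < 2:
        raise ValueError("cohort summary needs at least 2 patients")
    long = table.melt(
        id_vars=["patient_id", "strategy"], value_vars=list(metrics),
        var_name="metric", value_name="value",
    )
    out = (
        long.groupby(["metric", "strategy"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


def robustness_spread(
    summary: pd.DataFrame,
    methods: Dict[str, Dict[str, str]] = None,
) -> pd.DataFrame:
    """Spread (max - min of setting means) per metric and method.

    ``methods`` maps method name to {setting: strategy label}; the default
    compares the script and hybrid families across easy/moderate/hard.
    The method with the smaller spread per metric is flagged.
    """
    if methods is None:
        methods = {
            "script": {s: f"script_{s}" for s in ("easy", "moderate", "hard")},
            "hybrid": {s: f"hybrid_{s}" for s in ("easy", "moderate", "hard")},
        }
    rows = []
    for metric, group in summary.groupby("metric"):
        means = group.set_index("strategy")["mean"]
        per_method = {}
        for method, settings in methods.items():
            missing = [lab for lab in settings.values() if lab not in means.index]
            if missing:
                continue  # excluded metric/method with missing settings
            vals = {setting: float(means[label]) for setting, label in settings.items()}
            per_method[method] = vals
        if len(per_method) < len(methods):
            continue
        spreads = {m: max(v.values()) - min(v.values()) for m, v in per_method.items()}
        most_robust = min(spreads, key=spreads.get)
        for method, vals in per_method.items():
            row = {"metric": metric, "method": method, **{f"mean_{k}": v for k, v in vals.items()}}
            row["spread"] = spreads[method]
            row["most_robust"] = method == most_robust
            rows.append(row)
    return pd.DataFrame(rows)
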