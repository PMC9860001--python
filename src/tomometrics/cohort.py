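"""Cohort-level statistics over an extracted metric table.

Three analyses:

* :func:`correlation_map` — the pairwise metric-metric Spearman matrix with
  the conventional five-class grading of |rho| (very weak < 0.2 <= weak <
  0.4 <= moderate < 0.6 <= strong < 0.8 <= very strong) and a significance
  mask;
* :func:`select_metrics` — screening of the metrics against patient-specific
  QA passing rates: keep the metrics significantly correlated with the
  endpoint, then prune redundancy by dropping, within any (very) strongly
  inter-correlated pair, the metric less correlated with the endpoint;
* :func:`efficiency_split` — delivery-efficiency stratification: the plans
  below the 25th / above the 75th percentile of CFNS75 form the most / least
  efficient groups, compared metric-by-metric with a Student t-test, plus the
  pooled per-group average FLOT histograms.

Spearman p-values use the large-sample t approximation with average ranks
for ties (two-sided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .extraction import MetricTable
from .plan import PlanDocument

CLASS_BOUNDS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
    (math.inf, "very strong"),
)

DEFAULT_ALPHA = 0.05
DEFAULT_REDUNDANCY = 0.6  # |rho| >= 0.6: "(very) strongly correlated"
HISTOGRAM_BINS = 20


def classify_correlation(rho: float) -> str:
    """Five-class grading of a correlation magnitude."""
    if not np.isfinite(rho):
        return "not available"
    a = abs(rho)
    for bound, label in CLASS_BOUNDS:
        if a < bound:
            return label
    return "very strong"


def _frame(table: Union[MetricTable, pd.DataFrame]) -> pd.DataFrame:
    return table.frame if isinstance(table, MetricTable) else table


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Spearman rho and two-sided p over complete pairs (NaN-safe)."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return math.nan, math.nan
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass(frozen=True)
class CorrelationReport:
    rho: pd.DataFrame
    p: pd.DataFrame
    classes: pd.DataFrame  # five-class labels of |rho|
    significant: pd.DataFrame  # boolean mask: p < alpha
    alpha: float


def correlation_map(
    table: Union[MetricTable, pd.DataFrame], alpha: float = DEFAULT_ALPHA
) -> CorrelationReport:
    """Pairwise Spearman map over all metric columns (complete pairs only)."""
    frame = _frame(table)
    if len(frame) < 3:
        raise ParameterError("correlation map needs at least 3 plans")
    cols = list(frame.columns)
    k = len(cols)
    rho = np.eye(k)
    p = np.zeros((k, k))
    values = frame.to_numpy(dtype=float)
    for a in range(k):
        for b in range(a + 1, k):
            r, pv = spearman_with_p(values[:, a], values[:, b])
            rho[a, b] = rho[b, a] = r
            p[a, b] = p[b, a] = pv
    # a constant column has no rank ordering even against itself
    for a in range(k):
        col = values[:, a]
        finite = col[np.isfinite(col)]
        if finite.size < 3 or np.ptp(finite) == 0:
            rho[a, a] = math.nan
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    classes = rho_df.abs().map(classify_correlation)
    return CorrelationReport(
        rho=rho_df,
        p=p_df,
        classes=classes,
        significant=p_df < alpha,
        alpha=alpha,
    )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the PSQA metric screen.

    ``significant`` is the stage-1 list (endpoint-correlated metrics);
    ``selected`` the stage-2 list after redundancy pruning.  Both are sorted
    by |rho| descending, ties broken by name.
    """

    endpoint: str
    significant: List[Tuple[str, float]]
    selected: List[Tuple[str, float]]


def select_metrics(
    table: Union[MetricTable, pd.DataFrame],
    psqa: pd.DataFrame,
    endpoint: str,
    alpha: float = DEFAULT_ALPHA,
    redundancy_threshold: float = DEFAULT_REDUNDANCY,
) -> SelectionResult:
    """Screen metrics against a PSQA endpoint (gamma passing-rate column).

    Stage 1 keeps metrics whose Spearman correlation with the endpoint is
    significant at ``alpha``.  Stage 2 scans them by descending |rho| and
    drops any metric (very) strongly correlated (|rho| >=
    ``redundancy_threshold``) with an already-kept one.
    """
    frame = _frame(table)
    if endpoint not in psqa.columns:
        raise ParameterError(f"endpoint column {endpoint!r} not in PSQA table")
    merged = frame.join(psqa[[endpoint]], how="inner")
    if merged.empty:
        raise ParameterError("no plan_id overlap between metric table and PSQA table")
    y = merged[endpoint].to_numpy(dtype=float)

    significant: List[Tuple[str, float]] = []
    for name in frame.columns:
        rho, p = spearman_with_p(merged[name].to_numpy(dtype=float), y)
        if np.isfinite(rho) and p < alpha:
            significant.append((name, rho))
    significant.sort(key=lambda item: (-abs(item[1]), item[0]))

    selected: List[Tuple[str, float]] = []
    for name, rho in significant:
        redundant = False
        for kept, _ in selected:
            r_mm, _ = spearman_with_p(
                merged[name].to_numpy(dtype=float), merged[kept].to_numpy(dtype=float)
            )
            if np.isfinite(r_mm) and abs(r_mm) >= redundancy_threshold:
                redundant = True
                break
        if not redundant:
            selected.append((name, rho))
    return SelectionResult(endpoint=endpoint, significant=significant, selected=selected)


@dataclass(frozen=True)
class EfficiencySplit:
    efficient_ids: List[str]  # CFNS75 < 25th percentile (most efficient)
    inefficient_ids: List[str]  # CFNS75 > 75th percentile (least efficient)
    q25: float
    q75: float
    summary: pd.DataFrame  # per metric: group means/sds, t, p, significance flags
    histograms: Optional[pd.DataFrame]  # per-bin pooled average FLOT histograms


def _flot_histogram(plan: PlanDocument, bins: int) -> np.ndarray:
    flots = plan.sinogram.S[plan.sinogram.S > 0]
    counts, _ = np.histogram(flots, bins=bins, range=(0.0, 1.0))
    total = counts.sum()
    if total == 0:
        raise ParameterError(f"plan {plan.plan_id}: no open leaves, empty FLOT histogram")
    return counts / total


def _pooled_histogram(plans: Sequence[PlanDocument], bins: int) -> Dict[str, np.ndarray]:
    per_plan = np.vstack([_flot_histogram(p, bins) for p in plans])
    mean = per_plan.mean(axis=0)
    sd = per_plan.std(axis=0, ddof=1) if len(plans) > 1 else np.zeros(bins)
    half_ci = 1.96 * sd / math.sqrt(len(plans))  # 95% Gaussian CI
    return {"mean": mean, "ci95": half_ci}


def efficiency_split(
    table: Union[MetricTable, pd.DataFrame],
    plans: Optional[Sequence[PlanDocument]] = None,
    welch: bool = False,
    bins: int = HISTOGRAM_BINS,
) -> EfficiencySplit:
    """Stratify the cohort by delivery efficiency via CFNS75 quartiles.

    Plans strictly below the 25th percentile of CFNS75 are the most
    efficient, strictly above the 75th the least efficient; plans exactly at
    a percentile belong to neither group.  Percentiles use linear
    interpolation.  Group means are compared with a Student (equal-variance)
    t-test per metric (Welch via ``welch=True``), flagged at 0.05 and 0.01.
    """
    frame = _frame(table)
    if len(frame) < 8:
        raise ParameterError("efficiency split needs at least 8 plans")
    if "CFNS75" not in frame.columns:
        raise ParameterError("metric table has no CFNS75 column")
    cfns = frame["CFNS75"].to_numpy(dtype=float)
    q25, q75 = np.percentile(cfns[np.isfinite(cfns)], [25, 75])
    eff_mask = cfns < q25
    ineff_mask = cfns > q75
    if not eff_mask.any() or not ineff_mask.any():
        raise ParameterError(
            f"degenerate CFNS75 percentiles (q25={q25:.6g}, q75={q75:.6g}): "
            "a strict quartile group is empty"
        )
    rows = []
    for name in frame.columns:
        a = frame.loc[eff_mask, name].dropna().to_numpy(dtype=float)
        b = frame.loc[ineff_mask, name].dropna().to_numpy(dtype=float)
        if a.size > 1 and b.size > 1 and (np.ptp(a) > 0 or np.ptp(b) > 0):
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
        else:
            t, p = math.nan, math.nan
        rows.append(
            {
                "metric": name,
                "mean_efficient": a.mean() if a.size else math.nan,
                "sd_efficient": a.std(ddof=1) if a.size > 1 else math.nan,
                "mean_inefficient": b.mean() if b.size else math.nan,
                "sd_inefficient": b.std(ddof=1) if b.size > 1 else math.nan,
                "t": t,
                "p": p,
                "sig_0.05": bool(p < 0.05) if np.isfinite(p) else False,
                "sig_0.01": bool(p < 0.01) if np.isfinite(p) else False,
            }
        )
    summary = pd.DataFrame(rows).set_index("metric")

    histograms = None
    if plans is not None:
        by_id = {p.plan_id: p for p in plans}
        eff_ids = list(frame.index[eff_mask])
        ineff_ids = list(frame.index[ineff_mask])
        eff_plans = [by_id[i] for i in eff_ids if i in by_id]
        ineff_plans = [by_id[i] for i in ineff_ids if i in by_id]
        if eff_plans and ineff_plans:
            eff_h = _pooled_histogram(eff_plans, bins)
            ineff_h = _pooled_histogram(ineff_plans, bins)
            edges = np.linspace(0.0, 1.0, bins + 1)
            histograms = pd.DataFrame(
                {
                    "bin_low": edges[:-1],
                    "bin_high": edges[1:],
                    "efficient_mean": eff_h["mean"],
                    "efficient_ci95": eff_h["ci95"],
                    "inefficient_mean": ineff_h["mean"],
                    "inefficient_ci95": ineff_h["ci95"],
                }
            )
    return EfficiencySplit(
        efficient_ids=list(frame.index[eff_mask]),
        inefficient_ids=list(frame.index[ineff_mask]),
        q25=float(q25),
        q75=float(q75),
        summary=summary,
        histograms=histograms,
    )
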