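"""Leaf-open-time (LOT) distribution statistics.

All statistics are computed over the **nonzero** open times of the plan
(structurally closed leaves are described by the geometry metrics instead).
Two families:

* absolute LOT statistics, in ms (``LOT_ij = S_ij x PT``), including the
  cumulative LOT number scores ``CLNS_n`` (fraction of LOTs strictly below
  ``n`` ms) and ``CLNS_pt,n`` (fraction of LOTs within ``n`` ms of the
  projection time, i.e. ``LOT > PT - n``);
* relative (fractional) LOT statistics, dimensionless, with the cumulative
  FLOT number scores ``CFNS_{n x 100}`` (fraction of FLOTs strictly below
  ``n``, ``n`` in [0, 1]).

Relative statistics are the absolute ones divided by PT exactly, which makes
plans with very different projection times comparable.

Estimator conventions: standard deviation uses the sample (ddof=1) form;
skewness is the biased population estimator and kurtosis the non-excess
biased estimator (a normal distribution scores 3); the mode of the
continuous distribution is the midpoint of the fullest bin of a 100-bin
histogram over [min, max], ties resolved toward the lowest bin.  Zero-variance
distributions get NaN skewness/kurtosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError
from .plan import PlanDocument

DEFAULT_CLNS_THRESHOLDS_MS = (20.0, 30.0, 50.0, 100.0)
DEFAULT_CLNS_PT_MARGINS_MS = (20.0,)
DEFAULT_CFNS_THRESHOLDS = (0.05, 0.10, 0.50, 0.75, 0.90)

MODE_BINS = 100


@dataclass(frozen=True)
class LOTStatistics:
    mean: float
    sd: float
    median: float
    mode: float
    minimum: float
    maximum: float
    kurtosis: float  # non-excess (normal -> 3)
    skewness: float
    clns: Dict[float, float]  # threshold (ms) -> fraction strictly below
    clns_pt: Dict[float, float]  # margin (ms) -> fraction with LOT > PT - margin


@dataclass(frozen=True)
class FLOTStatistics:
    mean: float
    sd: float
    median: float
    mode: float
    minimum: float
    maximum: float
    cfns: Dict[float, float]  # threshold (dimensionless) -> fraction strictly below


def _nonzero(values: np.ndarray) -> np.ndarray:
    nz = values[values > 0]
    if nz.size == 0:
        raise UndefinedMetricError("LOT distribution undefined: all leaves closed")
    return nz


def _histogram_mode(x: np.ndarray) -> float:
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(x, bins=MODE_BINS, range=(lo, hi))
    k = int(np.argmax(counts))  # argmax takes the first (lowest) maximal bin
    return float((edges[k] + edges[k + 1]) / 2.0)


def _moments(x: np.ndarray):
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if sd > 0:
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        skew = float(stats.skew(x, bias=True))
    else:
        kurt = math.nan
        skew = math.nan
    return mean, sd, kurt, skew


def absolute_lot_stats(
    plan: PlanDocument,
    clns_thresholds: Sequence[float] = DEFAULT_CLNS_THRESHOLDS_MS,
    clns_pt_margins: Sequence[float] = DEFAULT_CLNS_PT_MARGINS_MS,
) -> LOTStatistics:
    """Statistics of the nonzero absolute LOTs (ms)."""
    lots = _nonzero(plan.sinogram.S.ravel()) * plan.pt_ms
    mean, sd, kurt, skew = _moments(lots)
    pt = plan.pt_ms
    return LOTStatistics(
        mean=mean,
        sd=sd,
        median=float(np.median(lots)),
        mode=_histogram_mode(lots),
        minimum=float(lots.min()),
        maximum=float(lots.max()),
        kurtosis=kurt,
        skewness=skew,
        clns={float(n): float(np.mean(lots < n)) for n in clns_thresholds},
        clns_pt={float(n): float(np.mean(lots > pt - n)) for n in clns_pt_margins},
    )


def relative_lot_stats(
    plan: PlanDocument,
    cfns_thresholds: Sequence[float] = DEFAULT_CFNS_THRESHOLDS,
) -> FLOTStatistics:
    """Statistics of the nonzero fractional LOTs (dimensionless)."""
    flots = _nonzero(plan.sinogram.S.ravel())
    mean, sd, _, _ = _moments(flots)
    return FLOTStatistics(
        mean=mean,
        sd=sd,
        median=float(np.median(flots)),
        mode=_histogram_mode(flots),
        minimum=float(flots.min()),
        maximum=float(flots.max()),
        cfns={float(n): float(np.mean(flots < n)) for n in cfns_thresholds},
    )
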