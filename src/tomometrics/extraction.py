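"""Batch extraction of the default 65-metric registry.

The registry lists 65 metrics in five subcategories — Delivery (12),
Absolute LOT (13), Relative LOT (11), Geometry (13), Modulation (16) — split
into 29 previously published ("old") metrics and 36 newly introduced ("new")
ones.  Default parameter choices: CLNS thresholds {20, 30, 50, 100} ms plus
CLNS_pt,20; CFNS thresholds {5, 10, 50, 75, 90} (x100); ELOTV projection
steps 1..5; EPSTV step pairs (1,1), (1,0), (0,1).

Extraction is fault-isolated per cell: a metric that cannot be computed for
a plan yields NaN in the table plus a logged reason, and never aborts the
batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .delivery import DeliveryMetrics, compute_delivery
from .errors import TomometricsError
from .geometry import GeometryMetrics, geometry_metrics, leaf_mask, projection_geometry
from .lot_stats import (
    DEFAULT_CFNS_THRESHOLDS,
    DEFAULT_CLNS_PT_MARGINS_MS,
    DEFAULT_CLNS_THRESHOLDS_MS,
    FLOTStatistics,
    LOTStatistics,
    absolute_lot_stats,
    relative_lot_stats,
)
from .modulation import elotv, epstv, lotv, lps_metrics, modulation_index, noc, pstv
from .plan import PlanDocument, leaf_position_array

logger = logging.getLogger(__name__)

CATEGORIES = ("Delivery", "AbsoluteLOT", "RelativeLOT", "Geometry", "Modulation")


@dataclass(frozen=True)
class RegistryConfig:
    """User-tunable extraction parameters (defaults reproduce the registry)."""

    eps: float = 0.0  # open/closed mask threshold: leaf open iff S > eps
    clns_thresholds_ms: Sequence[float] = DEFAULT_CLNS_THRESHOLDS_MS
    clns_pt_margins_ms: Sequence[float] = DEFAULT_CLNS_PT_MARGINS_MS
    cfns_thresholds: Sequence[float] = DEFAULT_CFNS_THRESHOLDS
    elotv_steps: Sequence[int] = (1, 2, 3, 4, 5)
    epstv_steps: Sequence[tuple] = ((1, 1), (1, 0), (0, 1))
    mi_function: Callable[[PlanDocument], float] = modulation_index


class MetricContext:
    """Per-plan cache of the intermediate products shared between metrics."""

    def __init__(self, plan: PlanDocument, config: RegistryConfig):
        self.plan = plan
        self.config = config

    @cached_property
    def delivery(self) -> DeliveryMetrics:
        return compute_delivery(self.plan, strict_mf=False)

    @cached_property
    def lot(self) -> LOTStatistics:
        return absolute_lot_stats(
            self.plan, self.config.clns_thresholds_ms, self.config.clns_pt_margins_ms
        )

    @cached_property
    def flot(self) -> FLOTStatistics:
        return relative_lot_stats(self.plan, self.config.cfns_thresholds)

    @cached_property
    def geometry(self) -> GeometryMetrics:
        mask = leaf_mask(self.plan, self.config.eps)
        return geometry_metrics(self.plan, projection_geometry(mask))

    @cached_property
    def lps(self):
        return lps_metrics(self.plan, leaf_position_array(self.plan.n_leaves))


@dataclass(frozen=True)
class MetricDescriptor:
    name: str
    category: str
    group: str  # "old" | "new"
    fn: Callable[[MetricContext], float]


@dataclass(frozen=True)
class MetricRegistry:
    metrics: Sequence[MetricDescriptor]
    config: RegistryConfig = field(default_factory=RegistryConfig)

    def __post_init__(self) -> None:
        names = [m.name for m in self.metrics]
        if len(set(names)) != len(names):
            raise ValueError("metric names must be unique")

    @property
    def names(self) -> List[str]:
        return [m.name for m in self.metrics]

    def filter(self, group: Optional[str] = None, category: Optional[str] = None) -> "MetricRegistry":
        kept = [
            m
            for m in self.metrics
            if (group is None or m.group == group)
            and (category is None or m.category == category)
        ]
        return MetricRegistry(kept, self.config)


def default_registry(config: Optional[RegistryConfig] = None) -> MetricRegistry:
    """The default 65-metric registry (29 old + 36 new)."""
    cfg = config or RegistryConfig()
    m: List[MetricDescriptor] = []

    def add(name, category, group, fn):
        m.append(MetricDescriptor(name, category, group, fn))

    # --- Delivery (12, all old) ---------------------------------------
    for name, attr in [
        ("pitch", "pitch"), ("FW", "fw"), ("PT", "pt"), ("GP", "gp"),
        ("TT", "tt"), ("TL", "tl"), ("CS", "cs"), ("CT", "ct"),
        ("Nproj", "n_proj"), ("Nrot", "n_rot"), ("MF", "mf"), ("TTDF", "ttdf"),
    ]:
        add(name, "Delivery", "old", lambda c, a=attr: getattr(c.delivery, a))

    # --- Absolute LOT (10 old + 3 new) --------------------------------
    for name, attr, group in [
        ("mLOT", "mean", "old"), ("sdLOT", "sd", "old"), ("mdLOT", "median", "old"),
        ("moLOT", "mode", "old"), ("minLOT", "minimum", "old"), ("maxLOT", "maximum", "old"),
        ("kLOT", "kurtosis", "new"), ("sLOT", "skewness", "new"),
    ]:
        add(name, "AbsoluteLOT", group, lambda c, a=attr: getattr(c.lot, a))
    # CLNS_20 is the one threshold first used with the extended set
    for n_ms in cfg.clns_thresholds_ms:
        group = "old" if float(n_ms) in (30.0, 50.0, 100.0) else "new"
        add(f"CLNS{n_ms:g}", "AbsoluteLOT", group, lambda c, t=float(n_ms): c.lot.clns[t])
    for n_ms in cfg.clns_pt_margins_ms:
        group = "old" if float(n_ms) == 20.0 else "new"
        add(f"CLNSpt{n_ms:g}", "AbsoluteLOT", group, lambda c, t=float(n_ms): c.lot.clns_pt[t])

    # --- Relative LOT (11, all new) -----------------------------------
    for name, attr in [
        ("mFLOT", "mean"), ("sdFLOT", "sd"), ("mdFLOT", "median"),
        ("moFLOT", "mode"), ("minFLOT", "minimum"), ("maxFLOT", "maximum"),
    ]:
        add(name, "RelativeLOT", "new", lambda c, a=attr: getattr(c.flot, a))
    for t in cfg.cfns_thresholds:
        add(f"CFNS{t * 100:g}", "RelativeLOT", "new", lambda c, x=float(t): c.flot.cfns[x])

    # --- Geometry (4 old + 9 new) -------------------------------------
    for name, attr, group in [
        ("TA", "ta", "new"), ("centroid", "centroid", "new"), ("nCC", "ncc", "new"),
        ("lengthCC", "length_cc", "new"), ("fDISC", "f_disc", "new"),
        ("CLS", "cls", "old"), ("CLSin", "cls_in", "old"),
        ("CLSin_area", "cls_in_area", "new"), ("CLSin_disc", "cls_in_disc", "new"),
        ("CLSin_area_disc", "cls_in_area_disc", "new"),
        ("L0NS", "l0ns", "old"), ("L1NS", "l1ns", "old"), ("L2NS", "l2ns", "new"),
    ]:
        add(name, "Geometry", group, lambda c, a=attr: getattr(c.geometry, a))

    # --- Modulation (3 old + 13 new) ----------------------------------
    for dp in cfg.elotv_steps:
        add(f"ELOTV{dp}", "Modulation", "new", lambda c, d=dp: elotv(c.plan, d))
    add("LOTV", "Modulation", "old", lambda c: lotv(c.plan))
    for dp, dl in cfg.epstv_steps:
        add(f"EPSTV{dp}{dl}", "Modulation", "new", lambda c, p=dp, q=dl: epstv(c.plan, p, q))
    add("PSTV", "Modulation", "old", lambda c: pstv(c.plan))
    add("nOC", "Modulation", "new", lambda c: noc(c.plan))
    add("MSA", "Modulation", "new", lambda c: c.lps[1])
    add("mSI", "Modulation", "new", lambda c: c.lps[2])
    add("mdSI", "Modulation", "new", lambda c: c.lps[3])
    add("sdSI", "Modulation", "new", lambda c: c.lps[4])
    add("MI", "Modulation", "old", lambda c: cfg.mi_function(c.plan))

    return MetricRegistry(m, cfg)


@dataclass(frozen=True)
class MetricTable:
    """Plan-by-metric result table plus extraction provenance."""

    frame: pd.DataFrame  # index: plan_id; columns: registry metric names
    provenance: Dict[str, str]

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the table with '#'-prefixed provenance header lines."""
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in self.provenance.items():
                fh.write(f"# {key}: {value}\n")
            self.frame.to_csv(fh, index_label="plan_id")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "MetricTable":
        provenance = {}
        with open(path, "r", encoding="utf-8") as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition(":")
                    provenance[key.strip()] = value.strip()
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            frame = pd.read_csv(fh, index_col="plan_id")
        return cls(frame=frame, provenance=provenance)


def extract(
    plans: Sequence[PlanDocument], registry: Optional[MetricRegistry] = None
) -> MetricTable:
    """Evaluate every registry metric on every plan.

    Failures are isolated per cell: the cell gets NaN and the reason is
    logged; the batch always completes.
    """
    registry = registry or default_registry()
    rows = []
    ids = []
    for plan in plans:
        ctx = MetricContext(plan, registry.config)
        row = {}
        for desc in registry.metrics:
            try:
                row[desc.name] = float(desc.fn(ctx))
            except TomometricsError as exc:
                logger.warning("plan %s metric %s: %s", plan.plan_id, desc.name, exc)
                row[desc.name] = np.nan
        rows.append(row)
        ids.append(plan.plan_id)
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="plan_id"), columns=registry.names)
    cfg = registry.config
    provenance = {
        "generator": f"tomometrics {_pkg_version}",
        "registry": f"default-65 ({len(registry.metrics)} metrics)",
        "eps": repr(cfg.eps),
        "clns_thresholds_ms": repr(list(cfg.clns_thresholds_ms)),
        "clns_pt_margins_ms": repr(list(cfg.clns_pt_margins_ms)),
        "cfns_thresholds": repr(list(cfg.cfns_thresholds)),
        "conventions": "nonzero-LOT statistics; sample sd; non-excess kurtosis; "
        "strict < thresholds; TT=N*PT; MI=spectral(f_max=2)",
    }
    return MetricTable(frame=frame, provenance=provenance)
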