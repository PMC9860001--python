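"""Delivery-subcategory metrics (TPS parameters).

These are the twelve parameters a planner or optimizer controls directly:
pitch, field width (FW), projection time (PT), gantry period (GP), treatment
time (TT), target length (TL), couch speed (CS), couch translation (CT),
number of projections / rotations, modulation factor (MF), and treatment
time per unit fraction dose (TTDF).

Conventions (documented so cross-center comparisons can adjust):

* ``TT = N_proj x PT`` — ramp-up / dead time is not modeled;
* ``MF`` is the *actual* modulation factor, max over mean of the **nonzero**
  leaf open times (zeros excluded: including structurally closed leaves
  would make MF diverge with field size);
* when stored GP and sinogram-derived ``PT x projections_per_rotation``
  disagree by more than 1e-3 relative, the sinogram-derived value wins and a
  warning is logged;
* missing metadata yields NaN (an explicit not-available marker), never a
  silent zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError
from .plan import PlanDocument

logger = logging.getLogger(__name__)

_GP_CONFLICT_RTOL = 1e-3


@dataclass(frozen=True)
class DeliveryMetrics:
    pitch: float  # dimensionless
    fw: float  # cm
    pt: float  # ms
    gp: float  # s
    tt: float  # s
    tl: float  # cm
    cs: float  # cm/s
    ct: float  # cm
    n_proj: float  # count
    n_rot: float  # count (fractional allowed)
    mf: float  # dimensionless, >= 1
    ttdf: float  # s/Gy


def modulation_factor(plan: PlanDocument) -> float:
    """MF = max(LOT) / mean(nonzero LOT) = max(FLOT) / mean(nonzero FLOT)."""
    flots = plan.sinogram.S[plan.sinogram.S > 0]
    if flots.size == 0:
        raise UndefinedMetricError("MF undefined: all leaves closed")
    return float(flots.max() / flots.mean())


def compute_delivery(plan: PlanDocument, strict_mf: bool = True) -> DeliveryMetrics:
    """Compute the Delivery metrics; absent inputs propagate as NaN.

    An all-closed sinogram makes MF undefined: with ``strict_mf`` (default)
    that raises :class:`UndefinedMetricError`; otherwise MF alone becomes NaN
    so the metadata-driven metrics stay available.
    """
    nan = math.nan
    n = plan.n_projections
    pt_ms = plan.pt_ms
    ppr = plan.projections_per_rotation

    gp_derived = pt_ms * ppr / 1000.0
    gp = gp_derived
    if plan.gp_s is not None:
        if abs(plan.gp_s - gp_derived) > _GP_CONFLICT_RTOL * gp_derived:
            logger.warning(
                "plan %s: stored GP %.6g s conflicts with PT-derived %.6g s; "
                "using the sinogram-derived value",
                plan.plan_id, plan.gp_s, gp_derived,
            )
        else:
            gp = plan.gp_s

    tt = n * pt_ms / 1000.0  # s
    ct = plan.ct_cm if plan.ct_cm is not None else nan
    cs = ct / tt if not math.isnan(ct) else nan
    fw = plan.fw_cm if plan.fw_cm is not None else nan
    pitch = cs * gp / fw if not (math.isnan(cs) or math.isnan(fw)) else nan
    tl = plan.tl_cm if plan.tl_cm is not None else nan
    if plan.dose_per_fraction_gy is not None:
        ttdf = tt / plan.dose_per_fraction_gy
    else:
        ttdf = nan

    try:
        mf = modulation_factor(plan)
    except UndefinedMetricError:
        if strict_mf:
            raise
        logger.warning("plan %s: MF undefined (all leaves closed)", plan.plan_id)
        mf = nan

    return DeliveryMetrics(
        pitch=pitch,
        fw=fw,
        pt=pt_ms,
        gp=gp,
        tt=tt,
        tl=tl,
        cs=cs,
        ct=ct,
        n_proj=float(n),
        n_rot=n / ppr,
        mf=mf,
        ttdf=ttdf,
    )
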