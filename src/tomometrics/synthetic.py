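"""Synthetic HT plan generator.

Produces :class:`~tomometrics.plan.PlanDocument` objects with controlled
statistical structure so that every metric and the cohort analysis can be
exercised without clinical data.  The generator emulates the two delivery
regimes seen in clinical cohorts:

* *inefficient* plans — a bimodal FLOT distribution with one peak near 0.5
  and one near the maximum opening;
* *efficient* plans — a flat FLOT distribution with a marked peak in the
  last (near-fully-open) bin, and the modulation carried by field geometry
  (split, discontinuous openings).

It emulates per-projection open spans with controllable width, lateral
offset, and a Poisson number of internal closed gaps.  It does not emulate
optimizer output, dose realism, nor longitudinal (projection-correlated)
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ParameterError
from .plan import FLOTSinogram, PlanDocument

FLOT_SHAPES = ("constant", "uniform_flat", "bimodal", "flat_with_end_peak")

#: Largest FLOT generated when full openings are disallowed; keeps the exact
#: CLS = 1 - 0.5*nOC regime (no merged openings across projection boundaries).
MAX_PARTIAL_FLOT = 0.999


@dataclass(frozen=True)
class GeneratorProfile:
    """Parameters of one synthetic-plan family.

    Delivery metadata defaults are typical Radixact values: 250 ms projection
    time (12.75 s gantry period at 51 projections/rotation), 2.5 cm dynamic
    field width, pitch 0.287, 2 Gy per fraction.
    """

    n_projections: int = 400
    n_leaves: int = 64
    flot_shape: str = "uniform_flat"
    open_fraction: float = 0.4  # fraction of leaves in the open span
    discontinuity: float = 1.0  # expected closed gaps inside the span
    asymmetry_shift: float = 0.0  # lateral field-center offset, in leaves
    allow_full_open: bool = False
    constant_value: float = 0.5  # FLOT used by the 'constant' shape
    seed: int = 0
    pt_ms: float = 250.0
    fw_cm: float = 2.5
    pitch: float = 0.287
    dose_per_fraction_gy: float = 2.0

    def __post_init__(self) -> None:
        if self.flot_shape not in FLOT_SHAPES:
            raise ParameterError(f"unknown flot_shape {self.flot_shape!r}")
        if not (0 < self.open_fraction <= 1):
            raise ParameterError("open_fraction must be in (0, 1]")
        if self.open_fraction * self.n_leaves < 1:
            raise ParameterError("infeasible profile: open_fraction x n_leaves < 1")
        if self.discontinuity < 0:
            raise ParameterError("discontinuity must be >= 0")
        if not (0 < self.constant_value <= 1):
            raise ParameterError("constant_value must be in (0, 1]")


def _draw_flots(shape: str, n: int, rng: np.random.Generator, profile: GeneratorProfile) -> np.ndarray:
    top = 1.0 if profile.allow_full_open else MAX_PARTIAL_FLOT
    if shape == "constant":
        v = min(profile.constant_value, top)
        return np.full(n, v)
    if shape == "uniform_flat":
        return rng.uniform(0.05, min(0.95, top), size=n)
    if shape == "bimodal":
        # inefficient regime: dominant peak near 0.5, second near the maximum
        pick = rng.random(n) < 0.70
        low = rng.normal(0.5, 0.08, size=n)
        high = rng.normal(0.92, 0.04, size=n)
        return np.clip(np.where(pick, low, high), 0.02, min(0.98, top))
    if shape == "flat_with_end_peak":
        # efficient regime: flat body plus a marked last-bin peak
        pick = rng.random(n) < 0.45
        body = rng.uniform(0.05, 0.95, size=n)
        peak = np.clip(rng.normal(0.97, 0.02, size=n), 0.90, top)
        return np.where(pick, peak, body)
    raise ParameterError(f"unknown flot_shape {shape!r}")


def generate_plan(profile: GeneratorProfile) -> PlanDocument:
    """Generate one plan; identical profiles (incl. seed) give identical plans.

    Each projection carries an open span of ``round(open_fraction * L)``
    leaves centered at ``L/2 + asymmetry_shift``, with ``Poisson(discontinuity)``
    single-leaf closed gaps placed uniformly strictly inside the span (the
    span bounds stay open by construction).  Nonzero FLOTs are drawn i.i.d.
    from the profile's distribution; with ``allow_full_open=False`` they stay
    strictly below 1.
    """
    rng = np.random.default_rng(profile.seed)
    n, l = profile.n_projections, profile.n_leaves
    S = np.zeros((n, l))
    width = max(1, int(round(profile.open_fraction * l)))
    for i in range(n):
        center = l / 2.0 + profile.asymmetry_shift
        start = int(round(center - width / 2.0))
        start = min(max(start, 0), l - width)
        open_idx = np.arange(start, start + width)
        if width >= 3 and profile.discontinuity > 0:
            n_gaps = min(rng.poisson(profile.discontinuity), width - 2)
            if n_gaps > 0:
                interior = open_idx[1:-1]
                gaps = rng.choice(interior, size=n_gaps, replace=False)
                open_idx = np.setdiff1d(open_idx, gaps)
        S[i, open_idx] = _draw_flots(profile.flot_shape, open_idx.size, rng, profile)

    n_rot = n / 51.0
    ct_cm = profile.pitch * profile.fw_cm * n_rot
    gp_s = profile.pt_ms * 51.0 / 1000.0
    return PlanDocument(
        sinogram=FLOTSinogram(S, profile.pt_ms),
        plan_id=f"synth-{profile.flot_shape}-{profile.seed}",
        tps_dialect="native",
        fw_cm=profile.fw_cm,
        gp_s=gp_s,
        tl_cm=max(ct_cm - profile.fw_cm, 0.0) or None,
        ct_cm=ct_cm,
        dose_per_fraction_gy=profile.dose_per_fraction_gy,
        projections_per_rotation=51,
    )


def generate_cohort(
    n_plans: int,
    profile_mix: Sequence[Tuple[GeneratorProfile, float]],
    master_seed: int = 0,
) -> List[PlanDocument]:
    """Draw ``n_plans`` plans from a weighted mixture of profiles.

    Per-plan seeds are ``master_seed + 1 + index`` and the mixture component
    of each plan is chosen by a dedicated RNG seeded with ``master_seed``, so
    cohorts are reproducible element-wise.
    """
    if n_plans < 0:
        raise ParameterError("n_plans must be >= 0")
    if not profile_mix:
        raise ParameterError("profile_mix must not be empty")
    weights = np.array([w for _, w in profile_mix], dtype=float)
    if (weights <= 0).any():
        raise ParameterError("mixture weights must be positive")
    weights /= weights.sum()
    chooser = np.random.default_rng(master_seed)
    picks = chooser.choice(len(profile_mix), size=n_plans, p=weights)
    plans = []
    for idx, pick in enumerate(picks):
        base = profile_mix[pick][0]
        profile = replace(base, seed=master_seed + 1 + idx)
        plan = generate_plan(profile)
        plans.append(replace(plan, plan_id=f"{plan.plan_id}-c{idx:04d}"))
    return plans
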