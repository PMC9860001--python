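"""Temporal/spatial modulation metrics of the sinogram.

The extended leaf-open-time variability ELOTV_dp compares each leaf's FLOTs
at projections ``dp`` apart, normalized by the leaf's maximum opening, so it
lives in [0, 1] and is 0 for a constant delivery; the classical LOTV is its
complement at dp=1.  The extended plan sinogram time variation EPSTV_(dp,dl)
accumulates absolute FLOT changes along both the projection and leaf axes;
PSTV is its (1,1) special case.  nOC counts leaf opening/closing events under
the centered-opening timing model; MSA and the sinogram-intensity statistics
summarize the leaf-projected sinogram (LPS).  MI is a spectral modulation
index (see :func:`modulation_index`).
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from .errors import ParameterError, UndefinedMetricError
from .plan import PlanDocument, leaf_position_array


def elotv(plan: PlanDocument, dp: int) -> float:
    """Extended leaf open time variability at projection step ``dp``.

    Per leaf: ``sum_i |S_ij - S_{i+dp,j}| / ((N - dp) * max_i S_ij)``; leaves
    that never open contribute 0; the plan value averages over all L leaves.
    """
    S = plan.sinogram.S
    n, l = S.shape
    if not (1 <= dp <= n - 1):
        raise ParameterError(f"dp must be in [1, N-1] = [1, {n - 1}], got {dp}")
    diffs = np.abs(S[dp:] - S[:-dp]).sum(axis=0)  # per leaf
    peak = S.max(axis=0)
    terms = np.zeros(l)
    open_leaves = peak > 0
    terms[open_leaves] = diffs[open_leaves] / ((n - dp) * peak[open_leaves])
    return float(terms.mean())


def lotv(plan: PlanDocument) -> float:
    """Leaf open time variability: per-leaf ``1 - elotv`` term, averaged.

    Equals ``1 - elotv(plan, 1)`` identically (never-open leaves score 1,
    i.e. zero variability).
    """
    return 1.0 - elotv(plan, 1)


def epstv(plan: PlanDocument, dp: int, dl: int) -> float:
    """Extended plan sinogram time variation at steps (dp, dl).

    ``1/(N-dp) * sum_{i<=N-dp} sum_{j<=L-dl} (|S_{i+dp,j} - S_ij| +
    |S_{i,j+dl} - S_ij|)``; with dp=0 the normalization is 1/N and only the
    leaf-direction term remains (and symmetrically for dl=0).
    """
    S = plan.sinogram.S
    n, l = S.shape
    if dp == 0 and dl == 0:
        raise ParameterError("EPSTV(0, 0) is degenerate (identically 0)")
    if not (0 <= dp < n):
        raise ParameterError(f"dp must be in [0, N-1], got {dp}")
    if not (0 <= dl < l):
        raise ParameterError(f"dl must be in [0, L-1], got {dl}")
    ni, lj = n - dp, l - dl
    total = 0.0
    if dp > 0:
        total += np.abs(S[dp:, :lj] - S[:ni, :lj]).sum()
    if dl > 0:
        total += np.abs(S[:ni, dl:] - S[:ni, :lj]).sum()
    return float(total / ni)


def pstv(plan: PlanDocument) -> float:
    """Plan sinogram time variation: the (1, 1) case of EPSTV."""
    return epstv(plan, 1, 1)


def noc_events(plan: PlanDocument) -> int:
    """Total leaf opening+closing events under the centered-LOT model.

    Each fractional opening is centered within its projection interval, so a
    leaf stays open across a projection boundary only along runs of fully
    open cells: a maximal run of ``S = 1`` cells — together with at most one
    partial (0 < S < 1) cell at each end, the physical ramp-in/ramp-out —
    forms ONE continuous opening (2 events: one opening + one closure).
    Every other partial cell closes within its own projection and counts as
    its own pair.  A partial cell between two full runs attaches to the
    earlier run.
    """
    S = plan.sinogram.S
    n = S.shape[0]
    events = 0
    for col in S.T:
        i = 0
        while i < n:
            if col[i] == 0.0:
                i += 1
                continue
            events += 2  # one opening + one closing
            if col[i] < 1.0:
                i += 1
                if i < n and col[i] == 1.0:  # leading ramp into a full run
                    while i < n and col[i] == 1.0:
                        i += 1
                    if i < n and 0.0 < col[i] < 1.0:  # trailing ramp
                        i += 1
            else:
                while i < n and col[i] == 1.0:
                    i += 1
                if i < n and 0.0 < col[i] < 1.0:
                    i += 1
    return events


def noc(plan: PlanDocument) -> float:
    """Opening/closing events per leaf per projection: events / (L x N)."""
    return noc_events(plan) / (plan.n_leaves * plan.n_projections)


def leaf_projected_sinogram(plan: PlanDocument) -> np.ndarray:
    """LPS_j = mean over projections of S_ij (length-L profile)."""
    return plan.sinogram.S.mean(axis=0)


def lps_metrics(
    plan: PlanDocument, leaf_positions: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, float, float, float, float]:
    """Return (LPS, MSA, mSI, mdSI, sdSI).

    MSA is the LPS-weighted mean leaf position (signed, in leaves); the
    sinogram-intensity statistics are the mean/median/sample-sd of the LPS
    over all L leaves (closed leaves contribute 0).
    """
    lps = leaf_projected_sinogram(plan)
    l = lps.size
    if leaf_positions is None:
        leaf_positions = leaf_position_array(l)
    total = lps.sum()
    if total == 0:
        raise UndefinedMetricError("MSA undefined: all leaves closed")
    msa = float((leaf_positions * lps).sum() / total)
    sd = float(lps.std(ddof=1)) if l > 1 else 0.0
    return lps, msa, float(lps.mean()), float(np.median(lps)), sd


# --- modulation index -------------------------------------------------------
# The MI definition is pluggable: pass a different callable to the extraction
# registry to match another implementation.

MI_F_MAX = 2.0
MI_F_STEPS = 201


def modulation_index(plan: PlanDocument, f_max: float = MI_F_MAX, steps: int = MI_F_STEPS) -> float:
    """Spectral modulation index of the sinogram.

    ``MI = integral_0^f_max z(f) df`` where ``z(f)`` is the fraction of
    adjacent-cell FLOT changes (along both the projection and the leaf axis)
    whose magnitude exceeds ``f * sigma``, ``sigma`` being the standard
    deviation of the nonzero FLOTs.  A constant sinogram has no spread
    (``sigma = 0``) and scores the minimal value 0.
    """
    S = plan.sinogram.S
    nz = S[S > 0]
    if nz.size == 0:
        return 0.0
    sigma = float(nz.std(ddof=1)) if nz.size > 1 else 0.0
    if sigma == 0.0:
        return 0.0
    diffs = np.concatenate(
        [np.abs(np.diff(S, axis=0)).ravel(), np.abs(np.diff(S, axis=1)).ravel()]
    )
    diffs.sort()
    f = np.linspace(0.0, f_max, steps)
    # z(f) = fraction of changes strictly exceeding f * sigma
    z = 1.0 - np.searchsorted(diffs, f * sigma, side="right") / diffs.size
    return float(np.trapezoid(z, f))
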