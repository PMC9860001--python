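"""Field-geometry metrics of the binary-MLC openings.

Everything here reads the *mask sinogram* ``O`` (``O_ij = 1`` iff
``S_ij > eps``, default ``eps = 0``) and describes the per-projection
aperture: its span (treatment area TA), lateral centroid, the connected
components of open leaves (count nCC, mean length lengthCC, fraction of
discontinuous projections fDISC), the closed-leaf scores (CLS and the
in-field CLS_in family), and the open-neighbour scores L0NS/L1NS/L2NS.

Averaging conventions: projections with no open leaf have no span, so they
are excluded from the TA / centroid / nCC / lengthCC averages (the average
runs over the ``N_active`` projections with at least one open leaf) but they
do count in the denominators of fDISC, CLS and CLS_in.  The LnNS scores pool
open cells over the whole plan before normalizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import UndefinedMetricError
from .plan import PlanDocument, leaf_position_array


@dataclass(frozen=True)
class ProjectionGeometry:
    """Per-projection aperture bookkeeping derived from the leaf mask."""

    mask: np.ndarray  # (N, L) uint8
    left: np.ndarray  # (N,) leftmost open leaf index, -1 if projection empty
    right: np.ndarray  # (N,) rightmost open leaf index, -1 if empty
    n_open: np.ndarray  # (N,) open-leaf count
    ncc: np.ndarray  # (N,) connected-component count (0 if empty)
    components: List[List[Tuple[int, int]]]  # per projection: [(l_k, r_k), ...]

    @property
    def span(self) -> np.ndarray:
        """Per-projection treatment area TA_i = R_i - L_i + 1 (0 if empty)."""
        return np.where(self.left >= 0, self.right - self.left + 1, 0)


@dataclass(frozen=True)
class GeometryMetrics:
    ta: float  # leaves
    centroid: float  # leaves, signed
    ncc: float
    length_cc: float  # leaves
    f_disc: float
    cls: float
    cls_in: float
    cls_in_area: float
    cls_in_disc: float
    cls_in_area_disc: float
    l0ns: float
    l1ns: float
    l2ns: float
    has_discontinuous: bool  # False => the *_disc scores are 0 by convention


def leaf_mask(plan: PlanDocument, eps: float = 0.0) -> np.ndarray:
    """Binary open/closed matrix: 1 where ``S_ij > eps``."""
    return (plan.sinogram.S > eps).astype(np.uint8)


def _row_components(row: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of consecutive open leaves in one projection."""
    open_idx = np.flatnonzero(row)
    if open_idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(open_idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [open_idx.size - 1]])
    return [(int(open_idx[s]), int(open_idx[e])) for s, e in zip(starts, ends)]


def projection_geometry(mask: np.ndarray) -> ProjectionGeometry:
    """Identify per-projection spans and connected open-leaf components."""
    mask = np.asarray(mask)
    n = mask.shape[0]
    left = np.full(n, -1, dtype=int)
    right = np.full(n, -1, dtype=int)
    ncc = np.zeros(n, dtype=int)
    components: List[List[Tuple[int, int]]] = []
    for i in range(n):
        comps = _row_components(mask[i])
        components.append(comps)
        ncc[i] = len(comps)
        if comps:
            left[i] = comps[0][0]
            right[i] = comps[-1][1]
    return ProjectionGeometry(
        mask=mask,
        left=left,
        right=right,
        n_open=mask.sum(axis=1).astype(int),
        ncc=ncc,
        components=components,
    )


def _neighbour_scores(mask: np.ndarray) -> Tuple[float, float, float]:
    """LnNS: fraction of open cells with n open lateral neighbours (n=0,1,2).

    Out-of-range neighbours count as closed; counts pooled over the plan.
    """
    padded = np.pad(mask, ((0, 0), (1, 1)))
    neighbours = padded[:, :-2] + padded[:, 2:]
    open_cells = mask.astype(bool)
    total = int(open_cells.sum())
    counts = [int(((neighbours == k) & open_cells).sum()) for k in (0, 1, 2)]
    return tuple(c / total for c in counts)  # type: ignore[return-value]


def geometry_metrics(
    plan: PlanDocument,
    geom: Optional[ProjectionGeometry] = None,
    leaf_positions: Optional[np.ndarray] = None,
    eps: float = 0.0,
) -> GeometryMetrics:
    """Plan-level geometry metrics from the leaf mask."""
    if geom is None:
        geom = projection_geometry(leaf_mask(plan, eps))
    mask = geom.mask
    n, l = mask.shape
    if leaf_positions is None:
        leaf_positions = leaf_position_array(l)

    active = geom.ncc > 0
    n_active = int(active.sum())
    if n_active == 0:
        raise UndefinedMetricError("geometry metrics undefined: no open leaf in plan")

    span = geom.span
    ta = float(span[active].mean())

    weights = mask[active].astype(float)
    centroid = float((weights @ leaf_positions / weights.sum(axis=1)).mean())

    ncc_plan = float(geom.ncc[active].mean())
    total_cc = int(geom.ncc.sum())
    total_cc_len = sum(r - s + 1 for comps in geom.components for (s, r) in comps)
    length_cc = total_cc_len / total_cc

    disc = geom.ncc > 1
    n_disc = int(disc.sum())
    f_disc = n_disc / n

    in_field_closed = span - geom.n_open  # closed leaves inside the span
    cls = float(1.0 - mask.mean())  # mean closed fraction per projection
    cls_in = float(in_field_closed.sum() / (n * l))
    with np.errstate(invalid="ignore", divide="ignore"):
        area_ratio = np.where(span > 0, in_field_closed / np.maximum(span, 1), 0.0)
    cls_in_area = float(area_ratio.sum() / n)
    if n_disc > 0:
        cls_in_disc = float(in_field_closed[disc].sum() / (n_disc * l))
        cls_in_area_disc = float(area_ratio[disc].sum() / n_disc)
    else:
        cls_in_disc = 0.0
        cls_in_area_disc = 0.0

    l0, l1, l2 = _neighbour_scores(mask)
    return GeometryMetrics(
        ta=ta,
        centroid=centroid,
        ncc=ncc_plan,
        length_cc=length_cc,
        f_disc=f_disc,
        cls=cls,
        cls_in=cls_in,
        cls_in_area=cls_in_area,
        cls_in_disc=cls_in_disc,
        cls_in_area_disc=cls_in_area_disc,
        l0ns=l0,
        l1ns=l1,
        l2ns=l2,
        has_discontinuous=n_disc > 0,
    )
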