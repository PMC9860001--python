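"""Core plan containers.

A helical tomotherapy (HT) delivery is defined by its *sinogram*: an
N-projection x L-leaf matrix of leaf open times.  Internally every value is
stored as a *fractional* leaf open time (FLOT) ``S_ij`` in ``[0, 1]`` — the
fraction of the projection time during which binary-MLC leaf ``j`` is open at
projection ``i``.  Absolute leaf open times (LOT, in ms) are always derived as
``S_ij * PT`` so that a single canonical representation feeds every metric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import SinogramIntegrityError

logger = logging.getLogger(__name__)

#: Values exceeding 1 by at most this much are silently clipped to 1.0
#: (floating-point dust from TPS exports); anything larger is an error.
CLIP_TOLERANCE = 1e-9

#: Standard HT geometry: 51 angular projections per gantry rotation.
DEFAULT_PROJECTIONS_PER_ROTATION = 51


def validate_sinogram_matrix(S: np.ndarray) -> np.ndarray:
    """Validate and normalize a raw FLOT matrix.

    Returns a float64 copy with near-1 overshoot (<= ``CLIP_TOLERANCE``)
    clipped to exactly 1.0.  Raises :class:`SinogramIntegrityError` naming the
    offending cell for genuine range violations.
    """
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2:
        raise SinogramIntegrityError(f"sinogram must be 2-D, got shape {S.shape}")
    n, l = S.shape
    if n < 1 or l < 2:
        raise SinogramIntegrityError(
            f"sinogram needs >=1 projection and >=2 leaves, got {n}x{l}"
        )
    if not np.isfinite(S).all():
        i, j = np.argwhere(~np.isfinite(S))[0]
        raise SinogramIntegrityError(f"non-finite FLOT at projection {i}, leaf {j}")
    bad = (S < 0) | (S > 1 + CLIP_TOLERANCE)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SinogramIntegrityError(
            f"FLOT {S[i, j]!r} out of [0, 1] at projection {i}, leaf {j}"
        )
    S = S.copy()
    over = S > 1.0
    if over.any():
        logger.warning("clipped %d FLOT value(s) within %g above 1.0", over.sum(), CLIP_TOLERANCE)
        S[over] = 1.0
    return S


@dataclass(frozen=True)
class FLOTSinogram:
    """Fractional leaf-open-time matrix plus the projection time.

    Parameters
    ----------
    S : (N, L) array
        Fractional leaf open times, each in [0, 1].
    pt_ms : float
        Projection time in milliseconds; the absolute LOT of cell (i, j) is
        ``S[i, j] * pt_ms``.
    """

    S: np.ndarray
    pt_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", validate_sinogram_matrix(self.S))
        if not (self.pt_ms > 0):
            raise SinogramIntegrityError(f"projection time must be > 0, got {self.pt_ms}")
        self.S.setflags(write=False)

    @property
    def n_projections(self) -> int:
        return self.S.shape[0]

    @property
    def n_leaves(self) -> int:
        return self.S.shape[1]

    @property
    def lot_ms(self) -> np.ndarray:
        """Absolute leaf open times in ms (same shape as ``S``)."""
        return self.S * self.pt_ms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FLOTSinogram):
            return NotImplemented
        return self.pt_ms == other.pt_ms and np.array_equal(self.S, other.S)


def leaf_position_array(n_leaves: int) -> np.ndarray:
    """Leaf Position Array: dimensionless leaf indexes from the MLC center.

    For an even leaf count the center falls between the two central leaves and
    the array is ``(-L/2, ..., -1, +1, ..., +L/2)`` (no zero entry); for an odd
    count the central leaf sits at 0.  Antisymmetric by construction.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if n_leaves % 2 == 0:
        half = n_leaves // 2
        return np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)]).astype(float)
    half = (n_leaves - 1) // 2
    return np.arange(-half, half + 1, dtype=float)


@dataclass(frozen=True)
class PlanDocument:
    """A sinogram together with the delivery metadata the TPS attaches to it.

    Optional metadata fields are ``None`` when absent from the source file;
    metrics needing them report a not-available marker rather than guessing.
    """

    sinogram: FLOTSinogram
    plan_id: str = "plan"
    tps_dialect: str = "native"  # {"precision", "raystation", "native"}
    fw_cm: Optional[float] = None  # jaw-defined field width
    gp_s: Optional[float] = None  # gantry period
    tl_cm: Optional[float] = None  # target length (metadata pass-through)
    ct_cm: Optional[float] = None  # total couch translation
    dose_per_fraction_gy: Optional[float] = None
    projections_per_rotation: int = DEFAULT_PROJECTIONS_PER_ROTATION

    def __post_init__(self) -> None:
        if self.projections_per_rotation < 1:
            raise ValueError("projections_per_rotation must be >= 1")
        for name in ("fw_cm", "gp_s", "dose_per_fraction_gy"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be > 0 when present, got {v}")

    @property
    def n_projections(self) -> int:
        return self.sinogram.n_projections

    @property
    def n_leaves(self) -> int:
        return self.sinogram.n_leaves

    @property
    def pt_ms(self) -> float:
        return self.sinogram.pt_ms

    def with_sinogram(self, S: np.ndarray) -> "PlanDocument":
        """Copy of this plan with a replaced FLOT matrix (same metadata)."""
        return replace(self, sinogram=FLOTSinogram(S, self.sinogram.pt_ms))
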