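"""Reading and writing HT plans.

Two sources are supported:

* DICOM RT-Plan files exported by the Precision or RayStation TPS (the
  sinogram lives in the beam's control-point sequence; see ``_dicom``);
* a native JSON exchange format used for fixtures, archival and the
  synthetic-plan generator.

Native format (one JSON document per plan)::

    {
      "format": "ht-plan", "version": 1,
      "header": {"plan_id": ..., "PT_ms": ..., "L": ...,
                 "FW_cm": ..., "GP_s": ..., "TL_cm": ..., "CT_cm": ...,
                 "dose_per_fraction_Gy": ..., "projections_per_rotation": ...},
      "sinogram": [[...], ...]        # row-major, N rows of L FLOTs
    }

Optional header fields are ``null`` when unknown.  Floats are serialized with
``repr`` (shortest round-trip representation), so a write/read cycle
reproduces the matrix bit-exactly.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Union

import numpy as np

from .errors import PlanFormatError, SinogramIntegrityError
from .plan import DEFAULT_PROJECTIONS_PER_ROTATION, FLOTSinogram, PlanDocument

NATIVE_FORMAT = "ht-plan"
NATIVE_VERSION = 1

_OPTIONAL_HEADER = {
    "FW_cm": "fw_cm",
    "GP_s": "gp_s",
    "TL_cm": "tl_cm",
    "CT_cm": "ct_cm",
    "dose_per_fraction_Gy": "dose_per_fraction_gy",
}


def write_native_plan(plan: PlanDocument, path: Union[str, os.PathLike]) -> None:
    """Serialize ``plan`` to the native JSON format (deterministic bytes)."""
    header = {
        "plan_id": plan.plan_id,
        "PT_ms": float(plan.pt_ms),
        "L": plan.n_leaves,
        "projections_per_rotation": plan.projections_per_rotation,
    }
    for key, attr in _OPTIONAL_HEADER.items():
        v = getattr(plan, attr)
        header[key] = None if v is None else float(v)
    doc = {
        "format": NATIVE_FORMAT,
        "version": NATIVE_VERSION,
        "header": header,
        "sinogram": [[float(x) for x in row] for row in plan.sinogram.S],
    }
    text = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
        fh.write("\n")


def read_native_plan(path: Union[str, os.PathLike]) -> PlanDocument:
    """Parse a native-format plan; schema violations raise PlanFormatError."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise PlanFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != NATIVE_FORMAT:
        raise PlanFormatError(f"{path}: missing 'format': '{NATIVE_FORMAT}' marker")
    header = doc.get("header")
    if not isinstance(header, dict):
        raise PlanFormatError(f"{path}: missing header object")
    for required in ("plan_id", "PT_ms", "L"):
        if required not in header:
            raise PlanFormatError(f"{path}: header field '{required}' missing")
    matrix = doc.get("sinogram")
    if not isinstance(matrix, list) or not matrix:
        raise PlanFormatError(f"{path}: field 'sinogram' missing or empty")
    S = np.asarray(matrix, dtype=np.float64)
    if S.ndim != 2:
        raise PlanFormatError(f"{path}: field 'sinogram' rows have unequal lengths")
    if S.shape[1] != int(header["L"]):
        raise PlanFormatError(
            f"{path}: header L={header['L']} but sinogram has {S.shape[1]} columns"
        )
    kwargs = {}
    for key, attr in _OPTIONAL_HEADER.items():
        v = header.get(key)
        kwargs[attr] = None if v is None else float(v)
    return PlanDocument(
        sinogram=FLOTSinogram(S, float(header["PT_ms"])),
        plan_id=str(header["plan_id"]),
        tps_dialect="native",
        projections_per_rotation=int(
            header.get("projections_per_rotation", DEFAULT_PROJECTIONS_PER_ROTATION)
        ),
        **kwargs,
    )


def read_dicom_rtplan(
    path: Union[str, os.PathLike], dialect: str = "auto"
) -> PlanDocument:
    """Read an HT DICOM RT-Plan (``dialect`` in {'precision','raystation','auto'})."""
    from ._dicom import read_dicom_rtplan as _read

    return _read(path, dialect=dialect)


def read_plan(path: Union[str, os.PathLike], fmt: str = "auto") -> PlanDocument:
    """Dispatch on file content: native JSON vs DICOM RT-Plan."""
    if fmt == "native":
        return read_native_plan(path)
    if fmt == "dicom":
        return read_dicom_rtplan(path)
    if fmt != "auto":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "rb") as fh:
        head = fh.read(256)
    if head.lstrip()[:1] == b"{":
        return read_native_plan(path)
    return read_dicom_rtplan(path)
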