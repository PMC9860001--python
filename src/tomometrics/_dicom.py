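"""DICOM RT-Plan adapters for the two supported TPS dialects.

The sinogram of an HT plan is carried in the beam's control-point sequence:
one control point per projection, with the per-leaf values in the MLCX
``LeafJawPositions`` element.  The two dialects differ in how those values are
scaled and ordered:

``precision``
    per-leaf values are fractional open times in [0, 1], leaf 0 first;
``raystation``
    per-leaf values are absolute open times in ms and the leaf order is
    reversed; the reader rescales by the projection time and flips columns so
    that column ``j`` always maps to the same physical leaf.

Delivery metadata (projection time, field width, gantry period, target
length, couch translation, dose per fraction, projections per rotation) lives
in a named private block.  Vendor exports are not publicly documented; this
layout was fixed against generated sample files (see the test suite) and is
validated by round-trip and shape checks only, so real clinical exports may
need an adapter tweak.  ``build_rtplan_dataset`` exists to produce such
synthetic sample files; writing clinical DICOM is out of scope.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import PlanFormatError, UnsupportedPlanError
from .plan import DEFAULT_PROJECTIONS_PER_ROTATION, FLOTSinogram, PlanDocument

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"

PRIVATE_GROUP = 0x0041
PRIVATE_CREATOR = "TOMOMETRICS HT"
# element offsets inside the private block
_PT_MS, _FW_CM, _GP_S, _TL_CM, _CT_CM, _DOSE_GY, _PPR = range(0x01, 0x08)

_MANUFACTURER_HINTS = {
    "accuray": "precision",
    "raysearch": "raystation",
}


def _detect_dialect(ds: Dataset) -> str:
    manufacturer = str(getattr(ds, "Manufacturer", "")).lower()
    for hint, dialect in _MANUFACTURER_HINTS.items():
        if hint in manufacturer:
            return dialect
    raise UnsupportedPlanError(
        f"cannot infer TPS dialect from Manufacturer={manufacturer!r}; "
        "pass dialect='precision' or 'raystation'"
    )


def _private_float(ds: Dataset, offset: int) -> Optional[float]:
    try:
        block = ds.private_block(PRIVATE_GROUP, PRIVATE_CREATOR)
        elem = block[offset]
    except KeyError:
        return None
    return None if elem.value in (None, "") else float(elem.value)


def _leaf_rows(ds: Dataset) -> np.ndarray:
    try:
        beams = ds.BeamSequence
    except AttributeError:
        raise UnsupportedPlanError("RT-Plan carries no BeamSequence")
    rows = []
    for beam in beams:
        for cp in getattr(beam, "ControlPointSequence", []):
            for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                if getattr(dev, "RTBeamLimitingDeviceType", "") == "MLCX":
                    rows.append(np.asarray(dev.LeafJawPositions, dtype=np.float64))
    if not rows:
        raise UnsupportedPlanError("no MLCX control-point data: not an HT sinogram plan")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise PlanFormatError(f"inconsistent leaf counts across projections: {sorted(lengths)}")
    return np.vstack(rows)


def read_dicom_rtplan(path: Union[str, os.PathLike], dialect: str = "auto") -> PlanDocument:
    """Read an HT DICOM RT-Plan into a :class:`PlanDocument`."""
    if dialect not in ("auto", "precision", "raystation"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        ds = pydicom.dcmread(str(path))
    except (InvalidDicomError, ValueError) as exc:
        raise PlanFormatError(f"{path}: not a DICOM file ({exc})") from exc
    modality = getattr(ds, "Modality", None)
    sop = str(getattr(ds, "SOPClassUID", ""))
    if modality != "RTPLAN" and sop != RTPLAN_SOP_CLASS:
        raise PlanFormatError(f"{path}: not an RT-Plan (Modality={modality!r})")
    if dialect == "auto":
        dialect = _detect_dialect(ds)

    pt_ms = _private_float(ds, _PT_MS)
    if pt_ms is None:
        raise UnsupportedPlanError(f"{path}: projection time not stored in plan")
    raw = _leaf_rows(ds)
    if dialect == "raystation":
        raw = raw[:, ::-1] / pt_ms  # absolute ms, reversed leaf order
    sinogram = FLOTSinogram(raw, pt_ms)

    ppr = _private_float(ds, _PPR)
    return PlanDocument(
        sinogram=sinogram,
        plan_id=str(getattr(ds, "RTPlanLabel", None) or getattr(ds, "SOPInstanceUID", "plan")),
        tps_dialect=dialect,
        fw_cm=_private_float(ds, _FW_CM),
        gp_s=_private_float(ds, _GP_S),
        tl_cm=_private_float(ds, _TL_CM),
        ct_cm=_private_float(ds, _CT_CM),
        dose_per_fraction_gy=_private_float(ds, _DOSE_GY),
        projections_per_rotation=(
            int(ppr) if ppr is not None else DEFAULT_PROJECTIONS_PER_ROTATION
        ),
    )


def build_rtplan_dataset(plan: PlanDocument, dialect: str) -> pydicom.FileDataset:
    """Build a synthetic RT-Plan dataset in the given dialect's layout.

    Intended for generating sample/fixture files; not a clinical DICOM writer.
    """
    if dialect not in ("precision", "raystation"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.plan_id
    ds.Manufacturer = "Accuray" if dialect == "precision" else "RaySearch Laboratories"

    block = ds.private_block(PRIVATE_GROUP, PRIVATE_CREATOR, create=True)
    block.add_new(_PT_MS, "DS", str(float(plan.pt_ms)))
    for offset, value in (
        (_FW_CM, plan.fw_cm),
        (_GP_S, plan.gp_s),
        (_TL_CM, plan.tl_cm),
        (_CT_CM, plan.ct_cm),
        (_DOSE_GY, plan.dose_per_fraction_gy),
    ):
        if value is not None:
            block.add_new(offset, "DS", str(float(value)))
    block.add_new(_PPR, "IS", str(plan.projections_per_rotation))

    S = plan.sinogram.S
    if dialect == "raystation":
        S = (S * plan.pt_ms)[:, ::-1]
    beam = Dataset()
    beam.BeamNumber = 1
    beam.ControlPointSequence = []
    for i, row in enumerate(S):
        cp = Dataset()
        cp.ControlPointIndex = i
        dev = Dataset()
        dev.RTBeamLimitingDeviceType = "MLCX"
        dev.LeafJawPositions = [f"{x:.12g}" for x in row]
        cp.BeamLimitingDevicePositionSequence = [dev]
        beam.ControlPointSequence.append(cp)
    ds.BeamSequence = [beam]
    return ds
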