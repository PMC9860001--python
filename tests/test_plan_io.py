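"""Plan I/O: native round trips, DICOM dialect adapters, integrity checks."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tomometrics as tm
from tomometrics import FLOTSinogram, PlanDocument
from tomometrics.errors import PlanFormatError, SinogramIntegrityError, UnsupportedPlanError

from conftest import make_random_plan, write_dicom_fixture


class TestSinogramValidation:
    def test_overshoot_within_tolerance_is_clipped(self):
        S = np.full((3, 4), 0.5)
        S[1, 2] = 1.0 + 1e-12
        sg = FLOTSinogram(S, 200.0)
        assert sg.S[1, 2] == 1.0

    def test_large_overshoot_names_offending_cell(self):
        S = np.full((3, 4), 0.5)
        S[2, 1] = 1.2
        with pytest.raises(SinogramIntegrityError, match="projection 2, leaf 1"):
            FLOTSinogram(S, 200.0)

    def test_negative_value_rejected(self):
        S = np.full((2, 4), 0.5)
        S[0, 0] = -0.01
        with pytest.raises(SinogramIntegrityError):
            FLOTSinogram(S, 200.0)

    @pytest.mark.parametrize("shape", [(0, 4), (3, 1)])
    def test_degenerate_shapes_rejected(self, shape):
        with pytest.raises(SinogramIntegrityError):
            FLOTSinogram(np.zeros(shape), 200.0)


class TestNativeFormat:
    def test_round_trip_preserves_everything(self, rng, tmp_path):
        plan = make_random_plan(rng, gp_s=12.75, tl_cm=7.5, plan_id="rt-1")
        path = tmp_path / "p.json"
        tm.write_native_plan(plan, path)
        back = tm.read_native_plan(path)
        assert back.sinogram == plan.sinogram
        for attr in ("plan_id", "fw_cm", "gp_s", "tl_cm", "ct_cm",
                     "dose_per_fraction_gy", "projections_per_rotation"):
            assert getattr(back, attr) == getattr(plan, attr)

    def test_writes_are_byte_identical(self, rng, tmp_path):
        plan = make_random_plan(rng)
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        tm.write_native_plan(plan, a)
        tm.write_native_plan(plan, b)
        assert a.read_bytes() == b.read_bytes()

    def test_single_projection_plan(self, tmp_path):
        plan = PlanDocument(FLOTSinogram(np.array([[0.1, 0.9]]), 100.0))
        path = tmp_path / "one.json"
        tm.write_native_plan(plan, path)
        assert tm.read_native_plan(path).n_projections == 1

    def test_out_of_range_value_is_integrity_error(self, tmp_path):
        doc = {
            "format": "ht-plan", "version": 1,
            "header": {"plan_id": "bad", "PT_ms": 200.0, "L": 2},
            "sinogram": [[0.5, 1.2]],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SinogramIntegrityError):
            tm.read_native_plan(path)

    @pytest.mark.parametrize("mutate", [
        lambda d: d.pop("format"),
        lambda d: d.pop("header"),
        lambda d: d["header"].pop("PT_ms"),
        lambda d: d.pop("sinogram"),
    ])
    def test_schema_violations_are_format_errors(self, tmp_path, mutate):
        doc = {
            "format": "ht-plan", "version": 1,
            "header": {"plan_id": "x", "PT_ms": 200.0, "L": 2},
            "sinogram": [[0.5, 0.5]],
        }
        mutate(doc)
        path = tmp_path / "x.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(PlanFormatError):
            tm.read_native_plan(path)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_property(self, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        plan = make_random_plan(rng, n=int(rng.integers(1, 12)), l=int(rng.integers(2, 20)))
        path = tmp_path_factory.mktemp("rt") / "p.json"
        tm.write_native_plan(plan, path)
        assert tm.read_native_plan(path).sinogram == plan.sinogram


class TestDicom:
    def test_precision_fixture_round_trips(self, tmp_path):
        S = np.full((3, 64), 0.5)
        plan = PlanDocument(FLOTSinogram(S, 200.0), plan_id="dcm", fw_cm=2.5,
                            dose_per_fraction_gy=2.0)
        path = tmp_path / "p.dcm"
        write_dicom_fixture(plan, path, "precision")
        back = tm.read_dicom_rtplan(path)
        assert back.tps_dialect == "precision"
        assert back.n_projections == 3 and back.n_leaves == 64
        assert np.all(back.sinogram.S == 0.5)
        assert back.pt_ms == 200.0 and back.fw_cm == 2.5

    def test_leaf_order_is_dialect_invariant(self, rng, tmp_path):
        plan = make_random_plan(rng, n=5, l=8)
        pa, pb = tmp_path / "a.dcm", tmp_path / "b.dcm"
        write_dicom_fixture(plan, pa, "precision")
        write_dicom_fixture(plan, pb, "raystation")
        a = tm.read_dicom_rtplan(pa)
        b = tm.read_dicom_rtplan(pb)
        assert b.tps_dialect == "raystation"
        np.testing.assert_allclose(a.sinogram.S, b.sinogram.S, atol=1e-10)
        np.testing.assert_allclose(a.sinogram.S, plan.sinogram.S, atol=1e-10)

    def test_missing_dose_flags_ttdf_not_available(self, rng, tmp_path):
        plan = make_random_plan(rng, n=4, l=8, dose_per_fraction_gy=None)
        path = tmp_path / "nodose.dcm"
        write_dicom_fixture(plan, path, "precision")
        back = tm.read_dicom_rtplan(path)
        assert back.dose_per_fraction_gy is None
        assert np.isnan(tm.compute_delivery(back).ttdf)

    def test_non_dicom_is_format_error(self, tmp_path):
        path = tmp_path / "junk.dcm"
        path.write_bytes(b"this is not dicom at all" * 10)
        with pytest.raises(PlanFormatError):
            tm.read_dicom_rtplan(path)

    def test_rtplan_without_sinogram_is_unsupported(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid
        from tomometrics._dicom import RTPLAN_SOP_CLASS

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = RTPLAN_SOP_CLASS
        ds.Modality = "RTPLAN"
        ds.Manufacturer = "Accuray"
        path = tmp_path / "empty.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        with pytest.raises(UnsupportedPlanError):
            tm.read_dicom_rtplan(path)


def test_small_leaf_count_runs_full_extraction(rng, tmp_path):
    """An L=32 plan loads and every metric downstream uses L=32 consistently."""
    plan = make_random_plan(rng, n=20, l=32)
    path = tmp_path / "l32.json"
    tm.write_native_plan(plan, path)
    back = tm.read_native_plan(path)
    table = tm.extract([back])
    assert table.frame.shape == (1, 65)
    assert table.frame.loc[back.plan_id, "TA"] <= 32
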