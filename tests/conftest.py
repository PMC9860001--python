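"""Shared fixtures: random-plan factories and synthetic DICOM sample files."""

from __future__ import annotations

import numpy as np
import pytest

from tomometrics import FLOTSinogram, PlanDocument


def make_random_plan(
    rng: np.random.Generator,
    n: int = 30,
    l: int = 16,
    open_prob: float = 0.6,
    pt_ms: float = 250.0,
    allow_full_open: bool = False,
    **metadata,
) -> PlanDocument:
    """A plan with i.i.d. uniform FLOTs on a random open/closed pattern.

    At least one cell is forced open so every metric is defined.  Uniform
    draws are almost surely < 1, so the no-full-open regime holds unless
    ``allow_full_open`` injects exact ones.
    """
    S = rng.uniform(0.01, 0.99, size=(n, l)) * (rng.random((n, l)) < open_prob)
    if not S.any():
        S[n // 2, l // 2] = 0.5
    if allow_full_open:
        ones = rng.random((n, l)) < 0.1
        S[ones & (S > 0)] = 1.0
        if not (S == 1.0).any():
            S[np.unravel_index(np.argmax(S), S.shape)] = 1.0
    metadata.setdefault("fw_cm", 2.5)
    metadata.setdefault("ct_cm", 10.0)
    metadata.setdefault("tl_cm", 7.5)
    metadata.setdefault("dose_per_fraction_gy", 2.0)
    return PlanDocument(sinogram=FLOTSinogram(S, pt_ms), **metadata)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def random_plan(rng) -> PlanDocument:
    return make_random_plan(rng)


def write_dicom_fixture(plan: PlanDocument, path, dialect: str) -> None:
    """Write a synthetic DICOM RT-Plan sample file in the given dialect."""
    from tomometrics._dicom import build_rtplan_dataset

    build_rtplan_dataset(plan, dialect).save_as(str(path), enforce_file_format=True)
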