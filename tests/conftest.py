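"""Shared fixtures: small deterministic cohorts and hand-built ERP containers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from erptrack.components import MONTAGE
from erptrack.preprocess import TARGET_FS, EpochSet, SubjectERP, sample_range
from erptrack.synthetic import CohortConfig

EPOCH_FIRST, EPOCH_LAST = sample_range(-200.0, 1000.0, TARGET_FS)
N_EPOCH_SAMPLES = EPOCH_LAST - EPOCH_FIRST + 1


def epoch_times_ms() -> np.ndarray:
    return (EPOCH_FIRST + np.arange(N_EPOCH_SAMPLES)) * 1000.0 / TARGET_FS


@pytest.fixture
def times_ms():
    return epoch_times_ms()


def make_erp(wave_face, wave_house=None, channels=MONTAGE, family_included=None,
             n_trials=20) -> SubjectERP:
    """SubjectERP from channels×samples arrays (house defaults to zeros)."""
    wave_face = np.asarray(wave_face, dtype=float)
    if wave_house is None:
        wave_house = np.zeros_like(wave_face)
    n_ch = wave_face.shape[0]
    fams = family_included or {"P1": True, "N290/P400": True, "Nc": True}
    counts = {c: np.full(n_ch, n_trials) for c in ("face", "house")}
    return SubjectERP(
        "T001", 1, TARGET_FS, tuple(channels), EPOCH_FIRST,
        {"face": wave_face, "house": np.asarray(wave_house, dtype=float)},
        counts, np.zeros(n_ch, dtype=bool), fams,
    )


def make_epochs(data, conditions, channels, lookaway=None) -> EpochSet:
    """Baseline-corrected EpochSet straight from a trials×channels×samples array."""
    data = np.asarray(data, dtype=float)
    n_tr = data.shape[0]
    lookaway = np.zeros(n_tr, bool) if lookaway is None else np.asarray(lookaway, bool)
    return EpochSet(
        "T001", 1, TARGET_FS, tuple(channels), EPOCH_FIRST, data,
        np.asarray(conditions, dtype=object), np.ones(n_tr, int), lookaway,
        np.array(["included"] * n_tr, dtype=object),
    )


@pytest.fixture
def fast_config():
    """Small 512 Hz cohort for end-to-end tests."""
    return CohortConfig(
        n_subjects=3, n_trials_per_condition=12, n_blocks=2, sample_rate=512,
        lookaway_rate=0.1, artifact_rate=0.02, seed=123,
    )


@pytest.fixture
def clean_config():
    """Noise- and artifact-free 512 Hz config (noiseless recovery limit)."""
    return CohortConfig(
        n_subjects=2, n_trials_per_condition=12, n_blocks=2, sample_rate=512,
        noise_sd=0.0, artifact_rate=0.0, lookaway_rate=0.0, seed=7,
    )
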