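"""Shared fixtures.

The two session-scoped experiment fixtures run the full two-phase
pipeline on synthetic cohorts (several minutes each); every test that
needs end-to-end results shares them instead of re-running.
"""

from __future__ import annotations

import numpy as np
import pytest

from seizurestack.experiments import run_two_phase_pipeline
from seizurestack.synthetic import PatientSignature, SyntheticConfig
from seizurestack.types import Recording, SeizureInterval

PIPELINE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def plain_runs():
    """Three in-distribution leave-one-patient-out runs (~2000 windows each)."""
    return [run_two_phase_pipeline(seed=s) for s in PIPELINE_SEEDS]


@pytest.fixture(scope="session")
def shift_runs():
    """Three domain-shift runs: target ictal frequency +2 Hz off the cohort."""
    return [
        run_two_phase_pipeline(seed=s, duration_s=1204.0, target_shift_hz=2.0)
        for s in PIPELINE_SEEDS
    ]


@pytest.fixture()
def default_signature():
    return PatientSignature(patient_id="P01")


@pytest.fixture()
def small_config():
    return SyntheticConfig(n_patients=2, n_channels=2, duration_s=60.0, seed=7)


@pytest.fixture()
def toy_recording():
    """20 s, 2 channels at 10 Hz with one seizure interval [8, 16)."""
    rng = np.random.default_rng(0)
    return Recording(
        patient_id="T01",
        channel_labels=["a", "b"],
        data=rng.normal(size=(2, 200)),
        fs=10.0,
        annotations=[SeizureInterval(8.0, 16.0)],
    )
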