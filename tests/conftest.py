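"""Shared fixtures: one modest synthetic session reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from somnispike.config import AnalysisConfig, GeneratorConfig, StagingThresholds
from somnispike.spectral import epoch_psd, preprocess
from somnispike.staging import classify_epochs
from somnispike.synthetic import generate_recording


@pytest.fixture(scope="session")
def session_20min():
    """A 30-min default-condition session with spikes and a few artifacts.

    Seeded so all four behavioral states occur (a fixture validity
    requirement for the state-conditional tests).
    """
    cfg = GeneratorConfig(
        duration_s=1800.0,
        seed=1,
        iis_rate_per_hour={"AW": 0.0, "QW": 0.0, "NREM": 30.0, "REM": 90.0},
        artifact_rate_per_hour=6.0,
    )
    rec, vel, truth = generate_recording(cfg)
    return {"cfg": cfg, "rec": rec, "vel": vel, "truth": truth}


@pytest.fixture(scope="session")
def staged_20min(session_20min):
    """The same session preprocessed, epoched and rule-staged."""
    acfg = AnalysisConfig()
    thr = StagingThresholds()
    ds = preprocess(session_20min["rec"], acfg)
    spectra = epoch_psd(ds, acfg, channel_role="FC",
                        iis_times=[t for t, _ in session_20min["truth"].iis_times],
                        artifact_times=session_20min["truth"].artifact_times)
    hyp = classify_epochs(spectra, session_20min["vel"], thr)
    return {**session_20min, "acfg": acfg, "thr": thr, "ds": ds,
            "spectra": spectra, "hyp": hyp}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
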