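"""Shared fixtures: scaled-down synthetic patients.

Simulated patients used in tests run at reduced sampling rate, channel
count, record length and seizure spacing so the whole suite stays fast;
the generative model is the same as at clinical scale.
"""

from __future__ import annotations

import numpy as np
import pytest

import preictal as p


def quick_config(**kw) -> p.SimulationConfig:
    """A small single-channel patient: 64 Hz, short seizure spacing,
    preictal effect planted in the 13-30 Hz band."""
    defaults = dict(
        n_seizures=4,
        record_days=6.5 / 24.0,
        fs=64.0,
        channel_names=("Cz",),
        min_separation_h=80.0 / 60.0,
        true_preictal_min=40.0,
        effect_size=3.0,
        effect_bands=((13.0, 30.0),),
        circadian_amplitude=0.0,
        sleep_schedule=(),
        artifact_rate_per_h=0.5,
        seed=11,
        allow_fewer_seizures=True,
    )
    defaults.update(kw)
    return p.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_patient():
    """One 6.5 h patient with 4 seizures and a 13-30 Hz preictal ramp."""
    cfg = quick_config()
    rec, ann, truth = p.generate_patient(cfg)
    return cfg, rec, ann, truth


@pytest.fixture(scope="session")
def small_features(small_patient):
    cfg, rec, ann, truth = small_patient
    fm = p.extract_features(rec, bands=p.bands_for_fs(rec.fs),
                            annotations=ann, preictal_min=cfg.true_preictal_min)
    return fm


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(20260928)
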