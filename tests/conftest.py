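import numpy as np
import pytest

import mindmetrics as mm
from mindmetrics.recording import CHANNEL_GROUPS


@pytest.fixture(scope="session")
def frontal_channels():
    return list(CHANNEL_GROUPS["frontal"])


@pytest.fixture(scope="session")
def fatigue_recordings(frontal_channels):
    """Breath-count + 3-back pair with a strong frontal-gamma fatigue effect."""
    effects = {("fatigue", "gamma", "frontal"): 0.8,
               ("fatigue", "delta", "frontal"): -0.5}
    prof = mm.default_profile(7, effects=effects)
    recs = {}
    for task in ("breath_count", "nback3"):
        lat = mm.generate_latents(task, 300, prof)
        rec = mm.synthesize_eeg(lat, prof, fs=250.0, channels=frontal_channels)
        rec.meta["task"] = task
        recs[task] = rec
    return recs


@pytest.fixture(scope="session")
def fatigue_windows(fatigue_recordings):
    from mindmetrics import eeg_features as ef

    return (ef.training_windows(fatigue_recordings["breath_count"],
                                "fatigue", "breath_count")
            + ef.training_windows(fatigue_recordings["nback3"],
                                  "fatigue", "nback3"))


@pytest.fixture(scope="session")
def clean_session():
    """One preprocessed scaled breath-count session (EEG+EOG+ECG)."""
    prof = mm.default_profile(7000)
    raw = mm.make_session(prof, "breath_count", duration=300, fs=250.0,
                          n_channels=10)
    clean = mm.preprocess(raw, ica_seed=prof.seed)
    return raw, clean
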