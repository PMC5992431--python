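"""Pipeline configuration with study-default constants.

Every default matches the study protocol value where one exists (500 Hz
sampling, the EEG/HRV band tables, 10 s / 6 s windows at a 1 s test
stride, k = 10 folds for fatigue/stress and 3 for attention, 3000
permutation iterations, the -0.001 quality-index threshold, the 25% IC
floor, 1000/50-sample drift windows).  Constructing a config that deviates
from any of those values logs a warning naming the field.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

logger = logging.getLogger(__name__)

#: Protocol-stated constants; deviations are legal but warned about.
PAPER_DEFAULTS = {
    "fs": 500.0,
    "train_window": 10.0,
    "attention_window": 6.0,
    "test_stride": 1.0,
    "k_fatigue": 10,
    "k_stress": 10,
    "k_attention": 3,
    "n_permutations": 3000,
    "sqi_threshold": -0.001,
    "min_ic_keep_fraction": 0.25,
    "eeg_detrend_window": 1000,
    "ecg_detrend_window": 50,
    "trial_duration": 2.0,
    "breath_duration": 1800.0,
    "nback_duration": 1260.0,
}


@dataclass
class PipelineConfig:
    # acquisition / windows
    fs: float = 500.0
    train_window: float = 10.0
    attention_window: float = 6.0
    test_stride: float = 1.0
    # validation
    k_fatigue: int = 10
    k_stress: int = 10
    k_attention: int = 3
    n_permutations: int = 3000
    regression_tails: str = "greater"
    # preprocessing
    sqi_threshold: float = -0.001
    min_ic_keep_fraction: float = 0.25
    eeg_detrend_window: int = 1000
    ecg_detrend_window: int = 50
    run_ica: bool = True
    # features / modeling
    transform: str = "log"              # log10(power + eps) then z-score
    ridge: float = 1e-4
    hrv_context: float = 120.0
    feature_sets: tuple[str, ...] = ("Pf1", "Pf2", "Ps1", "Ps2", "Ps3", "Ps4",
                                     "Pa1", "Pa2", "Pa3")
    regression_sets: tuple[str, ...] = ("Pf2", "Ps4")
    include_nback1: bool = True
    # synthetic cohort
    seed: int = 0
    n_subjects: int = 3
    n_channels: int = 10
    breath_duration: float = 1800.0
    nback_duration: float = 1260.0
    threat_duration: float = 330.0
    n_trials: int = 100
    trial_duration: float = 2.0
    # io
    out_dir: str = "mindmetrics_out"

    def __post_init__(self) -> None:
        for name, ref in PAPER_DEFAULTS.items():
            val = getattr(self, name)
            if val != ref:
                logger.warning("config %s=%r deviates from protocol value %r",
                               name, val, ref)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in fields(cls)}
        clean = {k: v for k, v in d.items() if k in names}
        for k in ("feature_sets", "regression_sets"):
            if k in clean and isinstance(clean[k], list):
                clean[k] = tuple(clean[k])
        return cls(**clean)


def scaled_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Desk-scale synthetic study: 5 min tasks, 250 Hz, 10 channels.

    Scaled-down session durations are the default for synthetic runs and
    tests; full-length sessions remain available by config.
    """
    kw = dict(fs=250.0, breath_duration=300.0, nback_duration=300.0,
              threat_duration=330.0, seed=seed)
    kw.update(overrides)
    return PipelineConfig(**kw)
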