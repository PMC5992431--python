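"""Multichannel biosignal recordings and the electrode montage.

A :class:`Recording` is the in-memory unit of raw and preprocessed data:
a channels x samples array plus sampling rate, channel labels/roles and
timestamped event markers.  The bundled montage covers the 29 scalp
electrodes of a 32-channel 10-20 cap where three positions are repurposed
as ECG and bipolar EOG leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Scalp EEG labels (10-20 system), ordered so that truncating to the first
#: ``n`` channels keeps every scalp region represented as early as possible.
EEG_CHANNELS: tuple[str, ...] = (
    "Fz", "F3", "F4", "FC1", "FC2", "Cz", "C3", "C4", "CP1", "CP2",
    "Pz", "Fp1", "Fp2", "P3", "P4", "O1", "O2", "F7", "F8", "FC5",
    "FC6", "CP5", "CP6", "P7", "P8", "T7", "T8", "Oz", "PO4",
)

#: Scalp region for each electrode; used to express region-level effect
#: directions (e.g. "frontal gamma up with fatigue").
CHANNEL_GROUPS: dict[str, tuple[str, ...]] = {
    "pre-frontal": ("Fp1", "Fp2"),
    "frontal": ("F7", "F3", "Fz", "F4", "F8"),
    "fronto-central": ("FC5", "FC1", "FC2", "FC6"),
    "central": ("C3", "Cz", "C4"),
    "centro-parietal": ("CP5", "CP1", "CP2", "CP6"),
    "parietal": ("P7", "P3", "Pz", "P4", "P8"),
    "temporal": ("T7", "T8"),
    "occipital": ("O1", "Oz", "O2"),
    "parieto-occipital": ("PO4",),
}

GROUP_OF_CHANNEL: dict[str, str] = {
    ch: grp for grp, chans in CHANNEL_GROUPS.items() for ch in chans
}

ROLES = ("EEG", "ECG", "EOG", "AUX")


@dataclass
class Recording:
    """Multichannel time series with sampling rate, roles and events.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in arbitrary (microvolt-like) units.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    channel_roles : list of str
        One of ``EEG``, ``ECG``, ``EOG``, ``AUX`` per channel.
    events : list of (time_s, label)
        Timestamped markers (task boundaries, button presses, trial onsets).
    meta : dict
        Free-form sidecar: ground-truth latents, true beat times,
        injected-artifact locations, preprocessing reports.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_roles: list[str]
    events: list[tuple[float, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError("channel_roles length must match data rows")
        for role in self.channel_roles:
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        dur = self.duration
        for t, _ in self.events:
            if not (0.0 <= t <= dur + 1e-9):
                raise ValueError(f"event time {t} outside [0, {dur}]")

    # -- convenience -------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def indices(self, role: str) -> np.ndarray:
        """Channel indices with the given role."""
        return np.array(
            [i for i, r in enumerate(self.channel_roles) if r == role], dtype=int
        )

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def pick(self, role: str) -> "Recording":
        """Sub-recording containing only channels of one role."""
        idx = self.indices(role)
        return Recording(
            data=self.data[idx].copy(),
            fs=self.fs,
            channel_names=[self.channel_names[i] for i in idx],
            channel_roles=[self.channel_roles[i] for i in idx],
            events=list(self.events),
            meta=dict(self.meta),
        )

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            channel_roles=list(self.channel_roles),
            events=list(self.events),
            meta=dict(self.meta),
        )

    def event_times(self, label: str) -> list[float]:
        return [t for t, lab in self.events if lab == label]
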