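"""Frequency-band tables for EEG spectral power and HRV spectra."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi})")


@dataclass(frozen=True)
class BandTable:
    """Ordered list of named frequency bands, half-open [lo, hi) in Hz."""

    entries: tuple[Band, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.entries)

    def __getitem__(self, name: str) -> Band:
        for b in self.entries:
            if b.name == name:
                return b
        raise KeyError(name)

    def subset(self, names: tuple[str, ...]) -> "BandTable":
        return BandTable(tuple(self[n] for n in names))


#: Informative EEG bands: delta through high-gamma.
EEG_BANDS = BandTable((
    Band("delta", 1.0, 3.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 30.0, 50.0),
    Band("high_gamma", 50.0, 100.0),
))

#: Informative HRV bands of the RR-interval spectrum.
HRV_BANDS = BandTable((
    Band("VLF", 0.01, 0.04),
    Band("LF", 0.04, 0.15),
    Band("HF", 0.15, 0.40),
))
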