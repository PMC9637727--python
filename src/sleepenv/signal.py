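"""Core in-memory containers for uniformly sampled recordings and frequency bands.

A :class:`Recording` holds a multichannel, uniformly sampled signal; a
:class:`BandDefinition` names a frequency band.  Time is measured in seconds
from the recording start, sample ``i`` covers ``[i/rate, (i+1)/rate)``, and
all intervals throughout the package are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "BandDefinition",
    "CANONICAL_BANDS",
    "band_by_name",
]


@dataclass
class Recording:
    """A uniformly sampled multichannel signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal amplitude (microvolts or arbitrary units).  A 1-D array is
        promoted to a single channel.
    rate : float
        Sampling rate in Hz.
    labels : list of str, optional
        Channel names; defaults to ``ch0, ch1, ...``.
    start_offset : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    rate: float
    labels: list[str] = field(default_factory=list)
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.labels.index(label)]

    def slice_seconds(self, start: float, stop: float) -> np.ndarray:
        """Samples covering the half-open interval [start, stop) seconds."""
        i0 = int(round((start - self.start_offset) * self.rate))
        i1 = int(round((stop - self.start_offset) * self.rate))
        return self.samples[:, i0:i1]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-power edges in Hz."""

    name: str
    low_edge: float
    high_edge: float

    def __post_init__(self) -> None:
        if not 0 < self.low_edge < self.high_edge:
            raise ValueError(
                f"band edges must satisfy 0 < low < high, got "
                f"({self.low_edge}, {self.high_edge})"
            )

    @property
    def width(self) -> float:
        return self.high_edge - self.low_edge


#: The canonical eight-band decomposition used for sleep EEG envelope analysis.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("low_delta", 0.5, 2.0),
    BandDefinition("high_delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 7.0, 10.0),
    BandDefinition("low_sigma", 10.0, 12.5),
    BandDefinition("high_sigma", 12.5, 16.0),
    BandDefinition("beta", 16.0, 30.0),
    BandDefinition("gamma", 30.0, 49.0),
)


def band_by_name(name: str) -> BandDefinition:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in CANONICAL_BANDS]}")
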