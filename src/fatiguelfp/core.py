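"""Shared domain types, constants and error hierarchy.

The package analyses paired extracellular recordings from primary motor
cortex (M1) and hippocampal CA1: a low-frequency local field potential
(LFP) channel per site plus multi-unit spike trains.  Sessions are split
into a pre-exercise baseline epoch and five 2-minute post-exercise epochs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger("fatiguelfp")

#: Session phase labels, in temporal order: the pre-exercise baseline and
#: the five consecutive 2-min post-exercise slots (0-2 ... 8-10 min).
PHASES: tuple[str, ...] = (
    "pre",
    "post_0_2",
    "post_2_4",
    "post_4_6",
    "post_6_8",
    "post_8_10",
)

#: Default recorded sites, in channel order.
REGIONS: tuple[str, str] = ("M1", "CA1")

#: LFP analysis band edges in Hz (half-open [lo, hi) intervals).
DEFAULT_BAND_EDGES: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.5, 4.0),
    ("theta", 4.0, 10.0),
    ("alpha", 10.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 80.0),
)

#: LFP band-pass corners in Hz; also the gravity-frequency integration range.
LFP_BAND: tuple[float, float] = (1.3, 80.0)


class PipelineError(Exception):
    """Base class for package errors."""


class ConfigError(PipelineError, ValueError):
    """Invalid configuration: unknown field, inconsistent parameters."""


class FormatError(PipelineError, ValueError):
    """Malformed on-disk data."""


class ComputationError(PipelineError, ValueError):
    """A quantity is undefined for the given input (e.g. zero in-range power)."""


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent, reproducible random substream for a (seed, keys) pair.

    Keys are hashed with CRC32 so that streams for different phases,
    channels or units are statistically independent and stable across runs
    and platforms; changing one component of a session does not perturb the
    draws of any other.
    """
    hashed = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *hashed]))


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping named frequency bands (half-open, Hz)."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BAND_EDGES

    def __post_init__(self):
        prev_hi = 0.0
        for name, lo, hi in self.bands:
            if not (0 <= lo < hi):
                raise ConfigError(f"band {name!r}: need 0 <= lo < hi, got [{lo}, {hi})")
            if lo < prev_hi:
                raise ConfigError(f"band {name!r} overlaps the previous band")
            prev_hi = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)

    @property
    def span(self) -> tuple[float, float]:
        return self.bands[0][1], self.bands[-1][2]


@dataclass
class Recording:
    """Multi-channel voltage time series.

    samples is a (channels x time) array in microvolts; regions labels the
    channels in order.
    """

    regions: tuple[str, ...]
    samples: np.ndarray
    fs: float
    t_start: float = 0.0
    phase_label: str = ""

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.regions = tuple(self.regions)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.regions) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.regions)} region labels but {self.samples.shape[0]} channels"
            )
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_span(self) -> tuple[float, float]:
        return self.t_start, self.t_start + self.duration

    def channel(self, region: str) -> "Recording":
        """Single-channel view of one site."""
        try:
            i = self.regions.index(region)
        except ValueError:
            raise KeyError(f"no channel labelled {region!r}") from None
        return Recording((region,), self.samples[i : i + 1], self.fs, self.t_start, self.phase_label)


@dataclass
class SpikeTrain:
    """Sorted event times (seconds) of one unit within a recording span."""

    region: str
    unit_id: int
    times: np.ndarray
    t_span: tuple[float, float]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        lo, hi = self.t_span
        if self.times.size and (self.times[0] < lo or self.times[-1] >= hi):
            raise ValueError("spike times outside t_span")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def in_window(self, start: float, end: float) -> np.ndarray:
        """Spike times within the half-open window [start, end)."""
        i0, i1 = np.searchsorted(self.times, [start, end], side="left")
        return self.times[i0:i1]


@dataclass(frozen=True)
class EpochWindow:
    """Half-open analysis window [start, end) with a phase label."""

    label: str
    start: float
    end: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("epoch end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


__all__ = [
    "PHASES",
    "REGIONS",
    "DEFAULT_BAND_EDGES",
    "LFP_BAND",
    "PipelineError",
    "ConfigError",
    "FormatError",
    "ComputationError",
    "substream",
    "BandScheme",
    "Recording",
    "SpikeTrain",
    "EpochWindow",
    "replace",
    "field",
]
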