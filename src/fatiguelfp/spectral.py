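"""Welch spectra, normalized band powers, coherence, gravity frequency, PSE.

All estimators share one Welch configuration: Hann window, 50% overlap,
segment length round(fs / resolution) samples, density scaling.  The
default 0.39 Hz resolution gives 1282-sample segments at 500 Hz.

Gravity frequency (GF) is the PSD-weighted mean frequency over [f1, f2] --
the spectral centroid, which slides toward slow rhythms under fatigue.
Power spectral entropy (PSE) is the Shannon entropy of the in-range PSD
normalized to a probability vector, divided by log(bin count), giving a
base-independent value in [0, 1] (0 = a pure tone, 1 = flat spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import BandScheme, ComputationError, Recording

DEFAULT_RESOLUTION = 0.39   # Hz
GF_RANGE = (1.3, 80.0)      # Hz, gravity-frequency integration limits


@dataclass
class Spectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray      # Hz, ascending
    psd: np.ndarray        # uV^2/Hz, >= 0
    resolution: float      # Hz, grid spacing

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape:
            raise ValueError("freqs and psd must have the same shape")
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")
        if self.freqs.size > 1:
            dgrid = np.diff(self.freqs)
            if not np.allclose(dgrid, self.resolution, atol=1e-9, rtol=1e-6):
                raise ValueError("frequency grid spacing != resolution")

    def band_mask(self, lo: float, hi: float, half_open: bool = True) -> np.ndarray:
        """Bins whose centers lie in [lo, hi) (or [lo, hi] if not half_open)."""
        if half_open:
            return (self.freqs >= lo) & (self.freqs < hi)
        return (self.freqs >= lo) & (self.freqs <= hi)


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence per frequency bin, values in [0, 1]."""

    freqs: np.ndarray
    coh: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.coh = np.asarray(self.coh, dtype=float)
        if np.any((self.coh < 0) | (self.coh > 1)):
            raise ValueError("coherence values must lie in [0, 1]")

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.freqs >= lo) & (self.freqs < hi)


@dataclass
class BandPowerRow:
    """Normalized band powers of one channel in one epoch."""

    region: str
    epoch: str
    fractions: dict[str, float]
    total_power: float     # uV^2 over the union of the scheme's bands


def _nperseg(fs: float, resolution: float) -> int:
    n = int(round(fs / resolution))
    if n < 2:
        raise ValueError("resolution too coarse for this sampling rate")
    return n


def welch_psd(
    x: np.ndarray | Recording,
    fs: float | None = None,
    resolution: float = DEFAULT_RESOLUTION,
) -> Spectrum:
    """Welch-averaged PSD at the requested frequency resolution.

    Density scaling: the PSD integrates (sum x grid spacing) to the signal
    variance.  The segment must be at least one Welch window long.
    """
    if isinstance(x, Recording):
        if x.samples.shape[0] != 1:
            raise ValueError("welch_psd expects a single channel")
        fs = x.fs
        x = x.samples[0]
    if fs is None:
        raise ValueError("fs is required for array input")
    x = np.asarray(x, dtype=float)
    nper = _nperseg(fs, resolution)
    if x.size < nper:
        raise ValueError(
            f"segment of {x.size} samples shorter than one Welch window ({nper})"
        )
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2,
        detrend="constant", scaling="density",
    )
    return Spectrum(freqs, psd, freqs[1] - freqs[0])


def welch_segment_count(n_samples: int, fs: float,
                        resolution: float = DEFAULT_RESOLUTION) -> int:
    """Number of averaged 50%-overlap Welch segments (the K in MSC bias 1/K)."""
    nper = _nperseg(fs, resolution)
    step = nper - nper // 2
    return max(0, 1 + (n_samples - nper) // step)


def msc_coherence(
    a: np.ndarray,
    b: np.ndarray,
    fs: float,
    resolution: float = DEFAULT_RESOLUTION,
) -> CoherenceSpectrum:
    """Welch-averaged magnitude-squared coherence |csd|^2/(psd_a psd_b).

    Uses the same windowing as welch_psd in numerator and denominator.  A
    single averaged segment gives identically 1 and is rejected.  Values
    are clamped to [0, 1] against round-off.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signals must have equal length")
    if welch_segment_count(a.size, fs, resolution) < 2:
        raise ValueError("need at least two Welch segments for coherence")
    nper = _nperseg(fs, resolution)
    freqs, coh = signal.coherence(
        a, b, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2,
        detrend="constant",
    )
    return CoherenceSpectrum(freqs, np.clip(coh, 0.0, 1.0))


def band_powers(spectrum: Spectrum, scheme: BandScheme,
                region: str = "", epoch: str = "") -> BandPowerRow:
    """Per-band power normalized by the total over the scheme's bands.

    Band power sums psd x resolution over bins whose centers fall in the
    half-open band; normalizing over the union of bands makes the
    fractions sum to exactly 1.
    """
    f_max = spectrum.freqs[-1] if spectrum.freqs.size else 0.0
    powers = {}
    for name, lo, hi in scheme.bands:
        if lo > f_max:
            raise ValueError(f"band {name!r} lies outside the spectral range")
        mask = spectrum.band_mask(lo, hi)
        powers[name] = float(spectrum.psd[mask].sum() * spectrum.resolution)
    total = sum(powers.values())
    if total <= 0:
        raise ComputationError("zero power over the band scheme")
    return BandPowerRow(region, epoch, {b: p / total for b, p in powers.items()}, total)


def band_coherence(cspec: CoherenceSpectrum, scheme: BandScheme) -> dict[str, float]:
    """Unweighted mean coherence over the bins of each band."""
    out = {}
    for name, lo, hi in scheme.bands:
        mask = cspec.band_mask(lo, hi)
        if not mask.any():
            raise ValueError(f"band {name!r} contains no frequency bins")
        out[name] = float(cspec.coh[mask].mean())
    return out


def gravity_frequency(spectrum: Spectrum, f1: float = GF_RANGE[0],
                      f2: float = GF_RANGE[1]) -> float:
    """PSD-weighted mean frequency (spectral centroid) over [f1, f2]."""
    if not f1 < f2:
        raise ValueError("need f1 < f2")
    mask = spectrum.band_mask(f1, f2, half_open=False)
    total = spectrum.psd[mask].sum()
    if total <= 0:
        raise ComputationError("zero in-range power; gravity frequency undefined")
    return float((spectrum.psd[mask] * spectrum.freqs[mask]).sum() / total)


def spectral_entropy(spectrum: Spectrum, f1: float = GF_RANGE[0],
                     f2: float = GF_RANGE[1]) -> float:
    """Normalized Shannon entropy of the in-range PSD, in [0, 1]."""
    if not f1 < f2:
        raise ValueError("need f1 < f2")
    mask = spectrum.band_mask(f1, f2, half_open=False)
    p = spectrum.psd[mask]
    total = p.sum()
    if total <= 0:
        raise ComputationError("zero in-range power; spectral entropy undefined")
    n_bins = int(mask.sum())
    if n_bins == 1:
        return 0.0
    q = p / total
    q = q[q > 0]
    h = float(-(q * np.log(q)).sum())
    return h / np.log(n_bins)


__all__ = [
    "Spectrum",
    "CoherenceSpectrum",
    "BandPowerRow",
    "welch_psd",
    "welch_segment_count",
    "msc_coherence",
    "band_powers",
    "band_coherence",
    "gravity_frequency",
    "spectral_entropy",
    "DEFAULT_RESOLUTION",
    "GF_RANGE",
]
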