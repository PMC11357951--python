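"""Synthetic two-site session generator with planted ground truth.

Every quantity the analysis pipeline estimates has a generative counterpart
here: per-band LFP power fractions, inter-site band coherence, per-unit
firing rates, Poisson-surprise burst episodes, and a fixed CA1-after-M1
conduction lag.  Post-exercise "fatigue" is emulated by per-phase
multiplicative shifts of those parameters with monotone partial recovery
across the five post epochs.

Defaults are the pre-exercise values reported for freely moving mice:
unit rates 29.86 Hz (M1) and 25.84 Hz (CA1), lag 3.5 ms, ~72/78 spikes per
burst, burst spike fraction ~0.34, band coherences 0.44-0.72, and a planted
spectral centroid near 40 Hz over 1.3-80 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .core import (
    PHASES,
    REGIONS,
    BandScheme,
    ConfigError,
    Recording,
    SpikeTrain,
    log,
    substream,
)

# Metric keys accepted in phase_multipliers, besides the band names.
_MULT_METRICS = ("coherence", "rate", "lag", "burst_rate", "spikes_per_burst")

# Fatigue effect at post_0_2 and residual effect at post_8_10; intermediate
# epochs interpolate linearly (monotone partial recovery, never back to 1).
_EFFECT_START_END: dict[str, tuple[float, float]] = {
    "delta": (1.35, 1.10),
    "theta": (1.35, 1.10),
    "alpha": (1.20, 1.05),
    "beta": (0.75, 0.92),
    "gamma": (0.70, 0.90),
    "coherence": (0.70, 0.90),
    "rate": (0.70, 0.90),
    "lag": (1.60, 1.15),
    "burst_rate": (0.75, 0.92),
    "spikes_per_burst": (0.70, 0.90),
}


def default_phase_multipliers() -> dict[str, dict[str, float]]:
    """Per-phase multiplicative fatigue factors, 1.0 everywhere at pre."""
    mults: dict[str, dict[str, float]] = {"pre": {m: 1.0 for m in _EFFECT_START_END}}
    n_post = len(PHASES) - 1
    for k, phase in enumerate(PHASES[1:]):
        frac = k / (n_post - 1)
        mults[phase] = {
            m: s + (e - s) * frac for m, (s, e) in _EFFECT_START_END.items()
        }
    return mults


def fractions_from_exponent(scheme: BandScheme, alpha: float) -> dict[str, float]:
    """Band power fractions of a 1/f^alpha background over the scheme's bands.

    Each fraction is proportional to the integral of f^-alpha across the
    band.  alpha = 0.05 (the default background exponent) places the
    spectral centroid of the planted LFP at ~40 Hz over 1.3-80 Hz.
    """
    weights = {}
    for name, lo, hi in scheme.bands:
        if abs(alpha - 1.0) < 1e-12:
            weights[name] = math.log(hi / lo)
        else:
            weights[name] = (hi ** (1 - alpha) - lo ** (1 - alpha)) / (1 - alpha)
    total = sum(weights.values())
    return {name: w / total for name, w in weights.items()}


@dataclass
class SynthSpec:
    """Full parameterization of a synthetic two-site session.

    Rates and burst parameters are per-region maps; base_rate is the target
    *total* rate of each unit (background plus burst spikes), so realized
    rates calibrate to the planted values.
    """

    duration: float = 120.0          # seconds per phase segment
    fs_lfp: float = 500.0            # Hz
    fs_raw: float = 10_000.0         # Hz, broadband rendering rate
    band_scheme: BandScheme = field(default_factory=BandScheme)
    band_power_fractions: dict[str, dict[str, float]] | None = None
    band_coherence_targets: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 0.44, "theta": 0.58, "alpha": 0.65, "beta": 0.72, "gamma": 0.65,
        }
    )
    background_exponent: float = 0.05   # 1/f^alpha profile for default fractions
    lfp_scale: float = 100.0            # microvolt RMS of each LFP channel
    units_per_region: int = 3
    base_rate: dict[str, float] = field(
        default_factory=lambda: {"M1": 29.86, "CA1": 25.84}
    )
    shared_event_fraction: float = 0.10   # P(an M1 spike is relayed to CA1)
    planted_lag: float = 3.5              # ms, CA1 after M1
    lag_jitter_sd: float = 0.5            # ms
    burst_episode_rate: dict[str, float] = field(
        default_factory=lambda: {"M1": 8.5, "CA1": 6.75}   # episodes/min
    )
    intra_burst_rate: float = 300.0       # Hz within an episode
    spikes_per_burst_mean: dict[str, float] = field(
        default_factory=lambda: {"M1": 71.81, "CA1": 78.16}
    )
    template_amplitude: float = 80.0      # microvolt trough depth
    noise_sd: float = 5.0                 # microvolt broadband noise
    phase_multipliers: dict[str, dict[str, float]] = field(
        default_factory=default_phase_multipliers
    )
    regions: tuple[str, str] = REGIONS
    seed: int = 0

    def __post_init__(self):
        if self.band_power_fractions is None:
            frac = fractions_from_exponent(self.band_scheme, self.background_exponent)
            self.band_power_fractions = {r: dict(frac) for r in self.regions}
        self.validate()

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        ratio = self.fs_raw / self.fs_lfp
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError("fs_raw must be an integer multiple of fs_lfp")
        for region, fr in self.band_power_fractions.items():
            vals = np.array([fr[b] for b in self.band_scheme.names])
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"band_power_fractions[{region!r}] must be >=0 and sum to 1"
                )
        for band, c in self.band_coherence_targets.items():
            if not 0.0 <= c <= 1.0:
                raise ConfigError(f"coherence target for {band!r} not in [0,1]")
        for region, r in self.base_rate.items():
            if r <= 0:
                raise ConfigError(f"base_rate[{region!r}] must be positive")
        if not 0.0 <= self.shared_event_fraction <= 1.0:
            raise ConfigError("shared_event_fraction must be in [0,1]")
        if set(self.phase_multipliers) != set(PHASES):
            raise ConfigError(
                f"phase_multipliers must contain exactly the phases {PHASES}"
            )
        if self.intra_burst_rate <= max(self.base_rate.values()):
            raise ConfigError(
                "intra_burst_rate must exceed base_rate for planted bursts "
                "to be detectable"
            )

    def multiplier(self, phase: str, metric: str) -> float:
        return self.phase_multipliers[phase].get(metric, 1.0)

    def effective_fractions(self, region: str, phase: str) -> dict[str, float]:
        """Planted normalized band fractions for a phase (renormalized)."""
        raw = {
            b: self.band_power_fractions[region][b] * self.multiplier(phase, b)
            for b in self.band_scheme.names
        }
        total = sum(raw.values())
        return {b: v / total for b, v in raw.items()}

    def effective_coherence(self, band: str, phase: str) -> float:
        c = self.band_coherence_targets[band] * self.multiplier(phase, "coherence")
        return float(np.clip(c, 0.0, 1.0))

    def effective_rate(self, region: str, phase: str) -> float:
        return self.base_rate[region] * self.multiplier(phase, "rate")

    def planted_gravity_frequency(self, region: str, phase: str) -> float:
        """Centroid implied by the planted (flat-within-band) fractions."""
        fr = self.effective_fractions(region, phase)
        return sum(fr[b] * (lo + hi) / 2 for b, lo, hi in self.band_scheme.bands)


def default_spec(overrides: dict | None = None) -> SynthSpec:
    """A fully populated spec; overrides replace named fields.

    Unknown field names raise ConfigError.
    """
    overrides = dict(overrides or {})
    known = {f.name for f in fields(SynthSpec)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown SynthSpec field(s): {sorted(unknown)}")
    return SynthSpec(**overrides)


def _brickband_noise(rng: np.random.Generator, n: int, fs: float,
                     lo: float, hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise exactly confined to [lo, hi) Hz.

    White noise is shaped in the Fourier domain (bins outside the band
    zeroed) so planted band powers do not leak into neighbouring bands;
    the realization is rescaled to exactly unit sample variance.
    """
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    X[(f < lo) | (f >= hi)] = 0.0
    y = np.fft.irfft(X, n)
    sd = y.std()
    if sd == 0:
        raise ConfigError(f"band [{lo}, {hi}) Hz contains no Fourier bins at fs={fs}")
    return y / sd


def gen_lfp_pair(spec: SynthSpec, phase: str) -> Recording:
    """Two-channel LFP at fs_lfp with planted band powers and coherences.

    Each band is band-limited Gaussian noise; inter-site coherence c is
    planted by mixing a shared component with weight c**(1/4) and an
    independent component with weight sqrt(1 - sqrt(c)), which gives
    magnitude-squared coherence |S12|^2/(S11*S22) = c.  Band variances are
    the (phase-adjusted, renormalized) power fractions times lfp_scale^2.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if spec.duration <= 0:
        raise ValueError("non-positive duration")
    n = int(round(spec.duration * spec.fs_lfp))
    out = np.zeros((2, n))
    for name, lo, hi in spec.band_scheme.bands:
        c = spec.effective_coherence(name, phase)
        a = c ** 0.25
        b = math.sqrt(1.0 - math.sqrt(c))
        shared = _brickband_noise(
            substream(spec.seed, phase, "lfp", name, "shared"), n, spec.fs_lfp, lo, hi
        )
        for i, region in enumerate(spec.regions):
            indep = _brickband_noise(
                substream(spec.seed, phase, "lfp", name, region), n, spec.fs_lfp, lo, hi
            )
            sigma = spec.lfp_scale * math.sqrt(
                spec.effective_fractions(region, phase)[name]
            )
            out[i] += sigma * (a * shared + b * indep)
    return Recording(spec.regions, out, spec.fs_lfp, 0.0, phase)


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """Homogeneous Poisson event times on [0, duration), sorted."""
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def _burst_episode(rng: np.random.Generator, start: float, mean_spikes: float,
                   intra_rate: float, duration: float) -> np.ndarray:
    n = rng.poisson(mean_spikes)
    if n == 0:
        return np.empty(0)
    isis = rng.exponential(1.0 / intra_rate, n)
    t = start + np.concatenate(([0.0], np.cumsum(isis[:-1])))
    return t[t < duration]


def gen_spike_trains(
    spec: SynthSpec, phase: str, return_truth: bool = False
) -> list[SpikeTrain] | tuple[list[SpikeTrain], dict]:
    """Planted spike trains for both regions in one phase.

    M1 units: Poisson background plus burst episodes; the background rate
    is the phase-adjusted base rate minus the expected burst-spike rate, so
    the realized total rate calibrates to the planted value.  Each M1 spike
    is relayed to the paired CA1 unit with probability
    shared_event_fraction, delayed by planted_lag (phase-scaled) plus
    Gaussian jitter.  CA1 units add their own burst episodes and Poisson
    background so their total rate matches the planted CA1 rate.

    With return_truth=True also returns planted burst windows and the
    effective lag, for recovery tests.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    m1, ca1 = spec.regions
    dur = spec.duration
    lag_s = spec.planted_lag * spec.multiplier(phase, "lag") / 1000.0
    truth: dict = {"lag_s": lag_s, "burst_windows": {}, "burst_times": {}}
    trains: list[SpikeTrain] = []

    def burst_component(region: str, rng: np.random.Generator):
        ep_rate = (
            spec.burst_episode_rate[region] / 60.0 * spec.multiplier(phase, "burst_rate")
        )
        mean_spk = spec.spikes_per_burst_mean[region] * spec.multiplier(
            phase, "spikes_per_burst"
        )
        starts = _poisson_times(rng, ep_rate, dur)
        times, windows = [], []
        for s in starts:
            t = _burst_episode(rng, s, mean_spk, spec.intra_burst_rate, dur)
            if t.size >= 3:
                times.append(t)
                windows.append((t[0], t[-1]))
        all_t = np.concatenate(times) if times else np.empty(0)
        return all_t, windows, ep_rate * mean_spk

    ca1_shared: dict[int, np.ndarray] = {}
    for u in range(spec.units_per_region):
        rng = substream(spec.seed, phase, "spk", m1, u)
        burst_t, windows, burst_hz = burst_component(m1, rng)
        bg_rate = spec.effective_rate(m1, phase) - burst_hz
        if bg_rate <= 0:
            raise ConfigError(
                f"M1 burst spike rate {burst_hz:.2f} Hz exceeds the planted "
                f"unit rate in phase {phase!r}"
            )
        t = np.unique(np.concatenate([_poisson_times(rng, bg_rate, dur), burst_t]))
        t = t[(t >= 0) & (t < dur)]
        trains.append(SpikeTrain(m1, u, t, (0.0, dur)))
        truth["burst_windows"][(m1, u)] = windows
        truth["burst_times"][(m1, u)] = burst_t
        # relay to the paired CA1 unit
        rng_sh = substream(spec.seed, phase, "spk", "share", u)
        mask = rng_sh.random(t.size) < spec.shared_event_fraction
        jitter = rng_sh.normal(0.0, spec.lag_jitter_sd / 1000.0, int(mask.sum()))
        ca1_shared[u] = t[mask] + lag_s + jitter

    for u in range(spec.units_per_region):
        rng = substream(spec.seed, phase, "spk", ca1, u)
        burst_t, windows, burst_hz = burst_component(ca1, rng)
        shared_hz = spec.shared_event_fraction * spec.effective_rate(m1, phase)
        bg_rate = spec.effective_rate(ca1, phase) - shared_hz - burst_hz
        if bg_rate <= 0:
            raise ConfigError(
                f"CA1 shared+burst rate exceeds the planted unit rate in {phase!r}"
            )
        t = np.concatenate(
            [_poisson_times(rng, bg_rate, dur), burst_t, ca1_shared[u]]
        )
        t = np.unique(t[(t >= 0) & (t < dur)])
        trains.append(SpikeTrain(ca1, u, t, (0.0, dur)))
        truth["burst_windows"][(ca1, u)] = windows
        truth["burst_times"][(ca1, u)] = burst_t

    return (trains, truth) if return_truth else trains


def spike_template(fs: float, width_ms: float = 1.5, asym: float = 0.45,
                   neg_frac: float = 0.35) -> np.ndarray:
    """Biphasic (negative-then-positive) cosine-windowed spike shape.

    Unit trough depth; width_ms is the total support, neg_frac the fraction
    occupied by the negative lobe, asym the positive/negative amplitude
    ratio.  Distinct (width, asym) pairs per unit make PCA sorting
    exercisable.
    """
    n_neg = max(int(round(width_ms * neg_frac * fs / 1000.0)), 2)
    n_pos = max(int(round(width_ms * (1 - neg_frac) * fs / 1000.0)), 2)
    neg = -np.sin(np.linspace(0, np.pi, n_neg, endpoint=False)) ** 2
    pos = asym * np.sin(np.linspace(0, np.pi, n_pos, endpoint=False)) ** 2
    return np.concatenate([neg, pos])


def unit_template(fs: float, region: str, unit_id: int) -> np.ndarray:
    """Per-unit template: width and asymmetry vary with (region, unit)."""
    k = unit_id + (3 if region == "CA1" else 0)
    return spike_template(
        fs,
        width_ms=1.2 + 0.12 * k,
        asym=0.35 + 0.06 * k,
        neg_frac=0.30 + 0.03 * k,
    )


def render_broadband(
    lfp: Recording, trains: list[SpikeTrain], spec: SynthSpec
) -> Recording:
    """Broadband recording at fs_raw: upsampled LFP + spike templates + noise.

    Each spike inserts the unit's biphasic template (trough depth
    template_amplitude, trough aligned to the spike time); white Gaussian
    noise of sd noise_sd is added.
    """
    from scipy.signal import resample_poly

    q = int(round(spec.fs_raw / lfp.fs))
    n_raw = lfp.n_samples * q
    out = resample_poly(lfp.samples, q, 1, axis=1)
    t0, t1 = lfp.t_span
    for tr in trains:
        if tr.n_spikes and (tr.times[0] < t0 or tr.times[-1] >= t1):
            raise ValueError("spike time outside the recording span")
        try:
            ch = lfp.regions.index(tr.region)
        except ValueError:
            raise ValueError(f"train region {tr.region!r} not in recording") from None
        tmpl = spec.template_amplitude * unit_template(spec.fs_raw, tr.region, tr.unit_id)
        trough = int(np.argmin(tmpl))
        idx = np.round((tr.times - t0) * spec.fs_raw).astype(int) - trough
        for i in idx:
            a, b = max(i, 0), min(i + tmpl.size, n_raw)
            if a < b:
                out[ch, a:b] += tmpl[a - i : b - i]
    if spec.noise_sd > 0:
        rng = substream(spec.seed, lfp.phase_label, "render")
        out += rng.normal(0.0, spec.noise_sd, out.shape)
    return Recording(lfp.regions, out, spec.fs_raw, t0, lfp.phase_label)


__all__ = [
    "SynthSpec",
    "default_spec",
    "default_phase_multipliers",
    "fractions_from_exponent",
    "gen_lfp_pair",
    "gen_spike_trains",
    "render_broadband",
    "spike_template",
    "unit_template",
]
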