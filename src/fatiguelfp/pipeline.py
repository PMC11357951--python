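"""Session orchestration: simulate/load, analyze all epochs, assemble results.

A session is the pre-exercise baseline epoch plus five 2-min post-exercise
epochs, two sites each.  For every (region, epoch) the pipeline reports
normalized band powers, inter-site band coherence, gravity frequency,
spectral entropy, mean unit firing rate, Poisson-surprise burst summaries,
and the cross-correlogram lag of CA1 relative to M1.  Runs are
deterministic under a fixed seed and write a canonical results CSV plus a
structured parameter log.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import bursts as bursts_mod
from . import sigio, spikes, synthgen, xcorr
from .core import (
    PHASES,
    BandScheme,
    ComputationError,
    ConfigError,
    EpochWindow,
    Recording,
    SpikeTrain,
    log,
)
from .preprocess import preprocess_lfp
from .spectral import (
    DEFAULT_RESOLUTION,
    GF_RANGE,
    band_coherence,
    band_powers,
    gravity_frequency,
    msc_coherence,
    spectral_entropy,
    welch_psd,
)

VERSION = "0.1.0"


@dataclass
class AnalysisConfig:
    """Everything run_session needs; synth mode or file mode.

    In synth mode `spec` drives the generator; in file mode `session_dir`
    must hold, for every phase, lfp_<phase>.tsv and
    spikes_<region>_<phase>.tsv as written by the `simulate` command.
    """

    spec: synthgen.SynthSpec | None = None
    session_dir: str | None = None
    band_scheme: BandScheme = field(default_factory=BandScheme)
    resolution: float = DEFAULT_RESOLUTION
    gf_range: tuple[float, float] = GF_RANGE
    spike_k: float = spikes.DEFAULT_K
    max_units: int = spikes.MAX_UNITS
    s_min: float = bursts_mod.S_MIN
    bin_ms: float = xcorr.BIN_MS
    half_window_ms: float = xcorr.HALF_WINDOW_MS
    use_broadband: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.spec is None and self.session_dir is None:
            raise ConfigError("either a synth spec or a session directory is required")
        if self.spec is not None and self.session_dir is not None:
            raise ConfigError("give a synth spec or a session directory, not both")

    def hash(self) -> str:
        payload = {k: repr(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SessionResult:
    """Full per-epoch output table plus provenance."""

    table: pd.DataFrame
    seed: int
    config_hash: str
    version: str = VERSION

    def metric_vector(self, region: str, metric: str,
                      phases: tuple[str, ...] = PHASES) -> np.ndarray:
        """Per-epoch values of one metric, in session phase order."""
        sub = self.table[(self.table.region == region) & (self.table.metric == metric)]
        lut = dict(zip(sub.phase, sub.value))
        return np.array([lut[p] for p in phases])

    def value(self, region: str, phase: str, metric: str) -> float:
        sub = self.table[
            (self.table.region == region)
            & (self.table.phase == phase)
            & (self.table.metric == metric)
        ]
        if len(sub) != 1:
            raise KeyError((region, phase, metric))
        return float(sub.value.iloc[0])


def _session_paths(config: AnalysisConfig, regions) -> dict[str, dict[str, str]]:
    d = config.session_dir
    paths: dict[str, dict[str, str]] = {}
    for phase in PHASES:
        entry = {"lfp": os.path.join(d, f"lfp_{phase}.tsv")}
        for region in regions:
            entry[f"spikes_{region}"] = os.path.join(
                d, f"spikes_{region}_{phase}.tsv"
            )
        paths[phase] = entry
    missing = [
        p for entry in paths.values() for p in entry.values() if not os.path.exists(p)
    ]
    if missing:
        raise FileNotFoundError(f"missing session files: {missing}")
    return paths


def _load_phase(paths: dict[str, str], regions) -> tuple[Recording, list[SpikeTrain]]:
    lfp = sigio.read_timeseries(paths["lfp"])
    trains: list[SpikeTrain] = []
    for region in regions:
        trains.extend(sigio.read_spike_times(paths[f"spikes_{region}"]))
    return lfp, trains


def _spikes_from_broadband(
    raw: Recording, config: AnalysisConfig
) -> list[SpikeTrain]:
    """Full spike path: MUA extraction, detection, PCA sorting per channel."""
    mua = spikes.extract_mua(raw)
    trains: list[SpikeTrain] = []
    for region in raw.regions:
        train, wfs = spikes.detect_spikes(mua.channel(region), k=config.spike_k)
        if train.n_spikes < 2:
            trains.append(train)
            continue
        labels = spikes.sort_units(wfs, max_units=config.max_units, seed=config.seed)
        trains.extend(spikes.split_by_unit(train, wfs, labels))
    return trains


def _merge_region(trains: list[SpikeTrain], region: str) -> SpikeTrain | None:
    times = np.unique(
        np.concatenate([tr.times for tr in trains if tr.region == region] or [[]])
    )
    spans = [tr.t_span for tr in trains if tr.region == region]
    if times.size == 0 or not spans:
        return None
    t0 = min(s[0] for s in spans)
    t1 = max(s[1] for s in spans)
    return SpikeTrain(region, -1, times, (t0, t1))


def run_session(config: AnalysisConfig) -> SessionResult:
    """Execute the full per-epoch analysis for one session.

    Deterministic under a fixed config and seed; when out_dir is set, the
    canonical results CSV and a JSON log of stage parameters are written.
    """
    if config.spec is not None:
        spec = config.spec
        regions = spec.regions
        source = {phase: None for phase in PHASES}
    else:
        regions = ("M1", "CA1")
        source = _session_paths(config, regions)

    rows: list[dict] = []
    pair = f"{regions[0]}-{regions[1]}"
    for phase in PHASES:
        if config.spec is not None:
            lfp = synthgen.gen_lfp_pair(spec, phase)
            trains = synthgen.gen_spike_trains(spec, phase)
            if config.use_broadband:
                raw = synthgen.render_broadband(lfp, trains, spec)
                lfp = preprocess_lfp(raw)
                trains = _spikes_from_broadband(raw, config)
            else:
                lfp = preprocess_lfp(lfp)
        else:
            lfp, trains = _load_phase(source[phase], regions)
            lfp = preprocess_lfp(lfp)
        epoch = EpochWindow(phase, lfp.t_start, lfp.t_span[1])

        spectra = {}
        for region in regions:
            spectrum = welch_psd(lfp.channel(region), resolution=config.resolution)
            spectra[region] = spectrum
            bp = band_powers(spectrum, config.band_scheme, region, phase)
            for band, frac in bp.fractions.items():
                rows.append(_row(region, phase, f"power_{band}", frac, "fraction"))
            rows.append(_row(region, phase, "total_power", bp.total_power, "uV^2"))
            rows.append(
                _row(region, phase, "gravity_frequency",
                     gravity_frequency(spectrum, *config.gf_range), "Hz")
            )
            rows.append(
                _row(region, phase, "spectral_entropy",
                     spectral_entropy(spectrum, *config.gf_range), "unitless")
            )

        cspec = msc_coherence(
            lfp.channel(regions[0]).samples[0],
            lfp.channel(regions[1]).samples[0],
            lfp.fs,
            config.resolution,
        )
        for band, coh in band_coherence(cspec, config.band_scheme).items():
            rows.append(_row(pair, phase, f"coherence_{band}", coh, "MSC"))

        rate_df = spikes.firing_rates(trains, [epoch])
        all_bursts: list[bursts_mod.BurstRecord] = []
        for tr in trains:
            all_bursts.extend(
                bursts_mod.detect_bursts(tr, epoch, s_min=config.s_min)
            )
        summary = bursts_mod.burst_summary(all_bursts, trains, [epoch])
        for region in regions:
            r_rates = rate_df[rate_df.region == region].rate
            rows.append(
                _row(region, phase, "firing_rate",
                     float(r_rates.mean()) if len(r_rates) else 0.0, "Hz")
            )
            srow = summary[summary.region == region].iloc[0]
            rows.append(_row(region, phase, "bursts_per_epoch",
                             float(srow.bursts_per_epoch), "count"))
            rows.append(_row(region, phase, "normalized_burst_rate",
                             float(srow.normalized_burst_rate), "fraction"))
            rows.append(_row(region, phase, "spikes_in_burst",
                             float(srow.mean_spikes_in_burst), "count"))
            rows.append(_row(region, phase, "burst_duration",
                             float(srow.mean_burst_duration), "s"))
            rows.append(_row(region, phase, "burst_unit_ratio",
                             float(srow.burst_unit_ratio), "fraction"))

        ref = _merge_region(trains, regions[0])
        tgt = _merge_region(trains, regions[1])
        if ref is not None and tgt is not None:
            cg = xcorr.cross_correlogram(ref, tgt, config.bin_ms, config.half_window_ms)
            lag, peak, flat = xcorr.peak_lag(cg)
            rows.append(_row(pair, phase, "lag", lag, "ms"))
            rows.append(_row(pair, phase, "lag_peak", peak, "count"))
            rows.append(_row(pair, phase, "lag_flat", float(flat), "bool"))
        else:
            log.warning("phase %s: empty merged train, no correlogram", phase)

    table = sigio.results_table(rows)
    result = SessionResult(table, config.seed, config.hash())
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        sigio.write_results(table, os.path.join(config.out_dir, "results.csv"))
        params = {
            "config_hash": result.config_hash,
            "seed": config.seed,
            "version": VERSION,
            "resolution_hz": config.resolution,
            "gf_range_hz": list(config.gf_range),
            "spike_k": config.spike_k,
            "s_min": config.s_min,
            "bin_ms": config.bin_ms,
            "half_window_ms": config.half_window_ms,
            "use_broadband": config.use_broadband,
            "mode": "synth" if config.spec is not None else "files",
        }
        with open(os.path.join(config.out_dir, "run_log.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(params, fh, indent=2, sort_keys=True)
    return result


def _row(region: str, phase: str, metric: str, value: float, units: str) -> dict:
    return {
        "region": region,
        "phase": phase,
        "metric": metric,
        "value": float(value),
        "units": units,
    }


def timecourse_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of two per-epoch metric time courses.

    Requires equal lengths >= 3 and non-zero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 epochs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def simulate_session(spec: synthgen.SynthSpec, out_dir: str,
                     broadband: bool = False) -> None:
    """Write a full synthetic session as text files (one set per phase)."""
    os.makedirs(out_dir, exist_ok=True)
    for phase in PHASES:
        lfp = synthgen.gen_lfp_pair(spec, phase)
        trains = synthgen.gen_spike_trains(spec, phase)
        sigio.write_timeseries(lfp, os.path.join(out_dir, f"lfp_{phase}.tsv"))
        for region in spec.regions:
            sigio.write_spike_times(
                [tr for tr in trains if tr.region == region],
                os.path.join(out_dir, f"spikes_{region}_{phase}.tsv"),
            )
        if broadband:
            raw = synthgen.render_broadband(lfp, trains, spec)
            sigio.write_timeseries(raw, os.path.join(out_dir, f"raw_{phase}.tsv"))


__all__ = [
    "AnalysisConfig",
    "SessionResult",
    "run_session",
    "timecourse_correlation",
    "simulate_session",
    "VERSION",
]
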