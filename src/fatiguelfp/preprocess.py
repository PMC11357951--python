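"""Raw-to-LFP conditioning and session epoching.

The LFP chain mirrors the acquisition convention for these recordings:
anti-aliased decimation of the 10 kHz broadband signal to 500 Hz, DC
removal, clipping of extreme excursions (artifact rectification), a 50 Hz
notch, and a 2nd-order Butterworth band-pass at 1.3-80 Hz.  Filtering is
zero-phase (forward-backward) by default so cross-site coherence and lag
estimates are not corrupted by filter phase delay; the stated filter order
is the per-pass order and the effective magnitude response is squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import PHASES, EpochWindow, Recording, SpikeTrain, log

LFP_FS = 500.0
LFP_BAND = (1.3, 80.0)
NOTCH_FREQ = 50.0
NOTCH_Q = 30.0
CLIP_MADS = 8.0        # symmetric clipping threshold, x robust signal scale
ANTIALIAS_ORDER = 8    # low-pass order ahead of decimation


@dataclass(frozen=True)
class FilterSpec:
    """IIR filter description: band-pass, high-pass or notch."""

    kind: str                       # "band-pass" | "high-pass" | "notch"
    corners: tuple[float, ...]      # Hz
    order: int = 2
    q: float = NOTCH_Q              # notch only

    def __post_init__(self):
        if self.kind not in ("band-pass", "high-pass", "low-pass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if any(c <= 0 for c in self.corners):
            raise ValueError("corner frequencies must be positive")


def _apply_sos(samples: np.ndarray, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, samples, axis=-1)
    return signal.sosfilt(sos, samples, axis=-1)


def butterworth_filter(
    rec: Recording, spec: FilterSpec, zero_phase: bool = True
) -> Recording:
    """Apply a Butterworth (or IIR-notch) filter; same fs and length out.

    With zero_phase the forward-backward pass squares the magnitude
    response and cancels group delay.  Corners at or above Nyquist raise.
    """
    nyq = rec.fs / 2.0
    if any(c >= nyq for c in spec.corners):
        raise ValueError(f"corner >= Nyquist ({nyq} Hz)")
    if spec.kind == "notch":
        b, a = signal.iirnotch(spec.corners[0], spec.q, fs=rec.fs)
        if zero_phase:
            out = signal.filtfilt(b, a, rec.samples, axis=-1)
        else:
            out = signal.lfilter(b, a, rec.samples, axis=-1)
    else:
        btype = {"band-pass": "bandpass", "high-pass": "highpass",
                 "low-pass": "lowpass"}[spec.kind]
        corners = spec.corners if len(spec.corners) > 1 else spec.corners[0]
        sos = signal.butter(spec.order, corners, btype=btype, fs=rec.fs, output="sos")
        out = _apply_sos(rec.samples, sos, zero_phase)
    return Recording(rec.regions, out, rec.fs, rec.t_start, rec.phase_label)


def butterworth_gain(spec: FilterSpec, f: float, fs: float) -> float:
    """Analytic single-pass magnitude response |H(f)| of a FilterSpec."""
    if spec.kind == "notch":
        b, a = signal.iirnotch(spec.corners[0], spec.q, fs=fs)
        _, h = signal.freqz(b, a, worN=[f], fs=fs)
    else:
        btype = {"band-pass": "bandpass", "high-pass": "highpass",
                 "low-pass": "lowpass"}[spec.kind]
        corners = spec.corners if len(spec.corners) > 1 else spec.corners[0]
        sos = signal.butter(spec.order, corners, btype=btype, fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[f], fs=fs)
    return float(np.abs(h[0]))


def clip_artifacts(rec: Recording, n_mads: float = CLIP_MADS) -> Recording:
    """Symmetric amplitude clipping at n_mads x the robust per-channel scale.

    The scale is median(|x|)/0.6745 (consistent with a Gaussian sd), so a
    clean channel is untouched while large transients are rectified.
    """
    out = rec.samples.copy()
    for ch in range(out.shape[0]):
        scale = np.median(np.abs(out[ch])) / 0.6745
        if scale > 0:
            np.clip(out[ch], -n_mads * scale, n_mads * scale, out=out[ch])
    return Recording(rec.regions, out, rec.fs, rec.t_start, rec.phase_label)


def decimate_to(rec: Recording, target_fs: float, zero_phase: bool = True) -> Recording:
    """Anti-aliased integer-factor decimation (identity if already there)."""
    ratio = rec.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValueError(f"fs {rec.fs} is not an integer multiple of {target_fs}")
    if factor == 1:
        return rec
    lp = FilterSpec("low-pass", (0.4 * target_fs,), order=ANTIALIAS_ORDER)
    filtered = butterworth_filter(rec, lp, zero_phase=zero_phase)
    return Recording(
        rec.regions, filtered.samples[:, ::factor], target_fs, rec.t_start,
        rec.phase_label,
    )


def preprocess_lfp(
    raw: Recording,
    target_fs: float = LFP_FS,
    band: tuple[float, float] = LFP_BAND,
    notch_freq: float = NOTCH_FREQ,
    notch_q: float = NOTCH_Q,
    clip_mads: float = CLIP_MADS,
    zero_phase: bool = True,
) -> Recording:
    """Broadband (or already-decimated) recording -> analysis-ready LFP.

    Stages: decimate to 500 Hz, remove the mean, clip extreme excursions,
    notch 50 Hz, band-pass 1.3-80 Hz.  Raw fs must be an integer multiple
    of the target rate.
    """
    rec = decimate_to(raw, target_fs, zero_phase=zero_phase)
    demeaned = rec.samples - rec.samples.mean(axis=1, keepdims=True)
    rec = Recording(rec.regions, demeaned, rec.fs, rec.t_start, rec.phase_label)
    rec = clip_artifacts(rec, clip_mads)
    rec = butterworth_filter(
        rec, FilterSpec("notch", (notch_freq,), q=notch_q), zero_phase=zero_phase
    )
    return butterworth_filter(
        rec, FilterSpec("band-pass", band, order=2), zero_phase=zero_phase
    )


@dataclass(frozen=True)
class EpochScheme:
    """Session layout: pre segment then post segment, cut into epochs.

    The session time axis is [0, pre_len) for the pre segment immediately
    followed by [pre_len, pre_len + post_len) for the post segment.
    """

    pre_len: float = 120.0
    post_len: float = 600.0
    epoch_len: float = 120.0

    def __post_init__(self):
        if min(self.pre_len, self.post_len, self.epoch_len) <= 0:
            raise ValueError("scheme lengths must be positive")


def split_epochs(obj: Recording | SpikeTrain, scheme: EpochScheme) -> list[EpochWindow]:
    """Epoch windows for a session: last epoch of pre, then five post slots.

    The pre window is the final epoch_len seconds of the pre segment; the
    post segment is tiled with consecutive half-open epoch_len windows
    labelled post_0_2 ... post_8_10.  A trailing remainder shorter than one
    epoch is dropped with a warning; a post segment shorter than one epoch
    is an error.
    """
    t0, t1 = obj.t_span
    duration = t1 - t0
    if scheme.post_len < scheme.epoch_len:
        raise ValueError("post segment shorter than one epoch")
    if duration + 1e-9 < scheme.pre_len + scheme.post_len:
        raise ValueError(
            f"session of {duration:.1f}s cannot hold pre {scheme.pre_len}s "
            f"+ post {scheme.post_len}s"
        )
    windows = [
        EpochWindow("pre", t0 + max(scheme.pre_len - scheme.epoch_len, 0.0),
                    t0 + scheme.pre_len)
    ]
    post_start = t0 + scheme.pre_len
    n_post = int(scheme.post_len / scheme.epoch_len + 1e-9)
    remainder = scheme.post_len - n_post * scheme.epoch_len
    if remainder > 1e-9:
        log.warning(
            "post segment leaves a %.1f s remainder; trailing data dropped",
            remainder,
        )
    labels = PHASES[1:]
    if n_post > len(labels):
        log.warning("post segment longer than %d epochs; extra epochs dropped",
                    len(labels))
        n_post = len(labels)
    for k in range(n_post):
        windows.append(
            EpochWindow(
                labels[k],
                post_start + k * scheme.epoch_len,
                post_start + (k + 1) * scheme.epoch_len,
            )
        )
    return windows


__all__ = [
    "FilterSpec",
    "EpochScheme",
    "butterworth_filter",
    "butterworth_gain",
    "clip_artifacts",
    "decimate_to",
    "preprocess_lfp",
    "split_epochs",
    "LFP_FS",
    "LFP_BAND",
]
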