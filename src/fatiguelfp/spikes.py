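"""Multi-unit activity: extraction, spike detection, PCA sorting, rates.

Spikes ride on the high-frequency (>500 Hz) part of the extracellular
signal.  Detection uses negative-going threshold crossings at k times a
robust noise scale (median absolute amplitude / 0.6745), trough alignment
and a refractory lockout; sorting projects aligned waveform snippets onto
leading principal components and partitions them with k-means, choosing
the cluster count by silhouette score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EpochWindow, Recording, SpikeTrain, log
from .preprocess import FilterSpec, butterworth_filter, decimate_to

MUA_HP_HZ = 500.0
MUA_FS = 2000.0
DEFAULT_K = 4.5            # detection threshold, x robust noise sd
LOCKOUT_MS = 1.0
SNIPPET_PRE_MS = 0.6       # window before the trough
SNIPPET_POST_MS = 1.0      # window after the trough
PCA_COMPONENTS = 3
MAX_UNITS = 4
MIN_SILHOUETTE = 0.5       # below this, a single cluster is reported


@dataclass
class WaveformSet:
    """Trough-aligned spike snippets (events x samples, uV)."""

    snippets: np.ndarray
    window_ms: tuple[float, float]    # (before, after) the trough
    fs: float
    times: np.ndarray                 # seconds, strictly increasing

    def __post_init__(self):
        self.snippets = np.atleast_2d(np.asarray(self.snippets, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.snippets.shape[0] != self.times.size:
            raise ValueError("one snippet per event required")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.times.size


def extract_mua(raw: Recording, hp_hz: float = MUA_HP_HZ,
                target_fs: float = MUA_FS) -> Recording:
    """High-pass the broadband signal at 500 Hz and resample to 2 kHz.

    The high-pass is a 2nd-order zero-phase Butterworth; the resampling is
    anti-aliased.  Raw fs must be at least 4 kHz.
    """
    if raw.fs < 4000.0:
        raise ValueError("extract_mua requires fs >= 4 kHz")
    hp = butterworth_filter(raw, FilterSpec("high-pass", (hp_hz,), order=2))
    return decimate_to(hp, target_fs)


def robust_noise_sd(x: np.ndarray) -> float:
    """MAD-based noise scale: median(|x|) / 0.6745."""
    return float(np.median(np.abs(x)) / 0.6745)


def detect_spikes(
    mua: Recording,
    k: float = DEFAULT_K,
    lockout_ms: float = LOCKOUT_MS,
    pre_ms: float = SNIPPET_PRE_MS,
    post_ms: float = SNIPPET_POST_MS,
) -> tuple[SpikeTrain, WaveformSet]:
    """Negative-threshold spike detection with trough alignment.

    Events are crossings of -k * sigma-hat (robust scale); each is aligned
    to the local trough within the lockout window, re-triggering within
    lockout_ms is suppressed, and a snippet of (pre_ms + post_ms) is cut
    around each trough.  Events whose snippet would leave the recording
    are dropped.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if mua.samples.shape[0] != 1:
        raise ValueError("detect_spikes expects a single channel; use .channel()")
    x = mua.samples[0]
    fs = mua.fs
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_post = int(round(post_ms * fs / 1000.0))
    if x.size < n_pre + n_post + 1:
        raise ValueError("recording shorter than one snippet window")
    sigma = robust_noise_sd(x)
    thr = -k * sigma
    below = x < thr
    onsets = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    lock = max(int(round(lockout_ms * fs / 1000.0)), 1)
    troughs: list[int] = []
    last = -np.inf
    for i in onsets:
        j = i + int(np.argmin(x[i : i + lock]))
        if j - last < lock:
            continue
        troughs.append(j)
        last = j
    idx = [j for j in troughs if j - n_pre >= 0 and j + n_post + 1 <= x.size]
    times = mua.t_start + np.asarray(idx, dtype=float) / fs
    snippets = (
        np.stack([x[j - n_pre : j + n_post + 1] for j in idx])
        if idx else np.empty((0, n_pre + n_post + 1))
    )
    train = SpikeTrain(mua.regions[0], 0, times, mua.t_span)
    return train, WaveformSet(snippets, (pre_ms, post_ms), fs, times)


def sort_units(
    wfs: WaveformSet,
    max_units: int = MAX_UNITS,
    n_components: int = PCA_COMPONENTS,
    seed: int = 0,
    min_silhouette: float = MIN_SILHOUETTE,
) -> np.ndarray:
    """PCA + k-means unit labels for each event (0..k-1).

    Snippets are projected onto the leading principal components; k-means
    is run for k = 2..max_units and the silhouette-optimal k is chosen; if
    the best silhouette falls below min_silhouette (or the events are
    effectively identical) a single cluster is reported.  Fewer events
    than requested clusters fall back to fewer clusters with a log note.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    n = wfs.n_events
    if n < 2:
        raise ValueError("need at least two events to sort")
    X = wfs.snippets - wfs.snippets.mean(axis=0)
    if np.allclose(X, 0):
        return np.zeros(n, dtype=int)
    n_comp = min(n_components, n - 1, X.shape[1])
    proj = PCA(n_components=n_comp, random_state=seed).fit_transform(wfs.snippets)
    k_max = min(max_units, n - 1)
    if k_max < max_units:
        log.info("only %d events; trying at most %d clusters", n, k_max)
    best_k, best_score, best_labels = 1, -1.0, np.zeros(n, dtype=int)
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(proj)
        if len(np.unique(km.labels_)) < 2:
            continue
        score = silhouette_score(proj, km.labels_)
        if score > best_score:
            best_k, best_score, best_labels = k, score, km.labels_
    if best_k == 1 or best_score < min_silhouette:
        return np.zeros(n, dtype=int)
    return best_labels.astype(int)


def split_by_unit(train: SpikeTrain, wfs: WaveformSet,
                  labels: np.ndarray) -> list[SpikeTrain]:
    """Partition a detected multi-unit train by sorted labels."""
    return [
        SpikeTrain(train.region, int(u), train.times[labels == u], train.t_span)
        for u in np.unique(labels)
    ]


def firing_rates(trains: list[SpikeTrain],
                 epochs: list[EpochWindow]) -> pd.DataFrame:
    """Per-(region, unit, epoch) firing rate = spike count / epoch length.

    Epochs must lie within each train's span; rates are in Hz.
    """
    rows = []
    for tr in trains:
        t0, t1 = tr.t_span
        for ep in epochs:
            if ep.start < t0 - 1e-9 or ep.end > t1 + 1e-9:
                raise ValueError(
                    f"epoch {ep.label!r} [{ep.start}, {ep.end}) outside train span"
                )
            count = tr.in_window(ep.start, ep.end).size
            rows.append(
                {
                    "region": tr.region,
                    "unit_id": tr.unit_id,
                    "epoch": ep.label,
                    "rate": count / ep.duration,
                }
            )
    return pd.DataFrame(rows, columns=["region", "unit_id", "epoch", "rate"])


__all__ = [
    "WaveformSet",
    "extract_mua",
    "robust_noise_sd",
    "detect_spikes",
    "sort_units",
    "split_by_unit",
    "firing_rates",
    "DEFAULT_K",
]
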