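"""Spike-train cross-correlograms and lag estimation.

The correlogram histograms all target-minus-reference spike-time
differences within a symmetric window; with M1 as reference and CA1 as
target, a positive peak lag means CA1 fires after M1.  A flat correlogram
(independent firing) is recognized when the peak does not exceed the
chance level expected for two independent Poisson trains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ComputationError, SpikeTrain

BIN_MS = 1.0
HALF_WINDOW_MS = 50.0
FLAT_ALPHA = 0.01       # family-wise false-alarm rate of the flatness test


@dataclass
class Correlogram:
    """Lag histogram of target spikes relative to reference spikes."""

    lags_ms: np.ndarray     # bin centers, symmetric about 0
    counts: np.ndarray      # non-negative integers
    bin_ms: float
    n_reference: int
    n_target: int
    duration: float         # overlap of the two train spans, s

    def __post_init__(self):
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.lags_ms.shape != self.counts.shape:
            raise ValueError("lags and counts must align")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def expected_flat(self) -> float:
        """Expected count per bin for independent Poisson trains."""
        if self.duration <= 0:
            return 0.0
        rate_tgt = self.n_target / self.duration
        return self.n_reference * rate_tgt * self.bin_ms / 1000.0


def cross_correlogram(
    ref: SpikeTrain,
    tgt: SpikeTrain,
    bin_ms: float = BIN_MS,
    half_window_ms: float = HALF_WINDOW_MS,
) -> Correlogram:
    """All-pairs lag histogram of (t_target - t_reference).

    Bin centers run from -half_window to +half_window in steps of bin_ms
    (a bin is centered on zero); pairs beyond the outermost bin edges are
    excluded.  bin_ms must divide half_window_ms.
    """
    if ref.n_spikes == 0 or tgt.n_spikes == 0:
        raise ValueError("cross_correlogram requires non-empty trains")
    n_half = half_window_ms / bin_ms
    if abs(n_half - round(n_half)) > 1e-9:
        raise ValueError("bin_ms must divide half_window_ms")
    n_half = int(round(n_half))
    centers = np.arange(-n_half, n_half + 1) * bin_ms
    edges = np.concatenate([centers - bin_ms / 2, [centers[-1] + bin_ms / 2]])
    w = (half_window_ms + bin_ms / 2) / 1000.0
    counts = np.zeros(centers.size, dtype=int)
    t_tgt = tgt.times
    # sliding two-pointer scan over sorted times: O(n + pairs)
    lo = 0
    hi = 0
    diffs = []
    for t in ref.times:
        while lo < t_tgt.size and t_tgt[lo] < t - w:
            lo += 1
        while hi < t_tgt.size and t_tgt[hi] <= t + w:
            hi += 1
        if hi > lo:
            diffs.append((t_tgt[lo:hi] - t) * 1000.0)
    if diffs:
        counts += np.histogram(np.concatenate(diffs), bins=edges)[0]
    overlap = min(ref.t_span[1], tgt.t_span[1]) - max(ref.t_span[0], tgt.t_span[0])
    return Correlogram(
        centers, counts, bin_ms, ref.n_spikes, tgt.n_spikes, max(overlap, 0.0)
    )


def peak_lag(cg: Correlogram, smoothing: int = 0,
             flat_alpha: float = FLAT_ALPHA) -> tuple[float, float, bool]:
    """(lag_ms, peak height, flat flag) of the correlogram maximum.

    Optional boxcar smoothing over the given number of bins.  Ties break
    toward the smallest absolute lag.  The flat flag is set when the peak
    does not exceed the independent-Poisson chance level mu plus
    z * sqrt(mu), with z the normal quantile at flat_alpha Bonferroni-
    corrected over the number of bins (so a genuinely flat correlogram is
    flagged flat with probability ~ 1 - flat_alpha).
    """
    counts = cg.counts.astype(float)
    if not counts.any():
        raise ComputationError("all-zero correlogram; lag undefined")
    if smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        counts = np.convolve(counts, kernel, mode="same")
    peak = counts.max()
    order = np.lexsort((cg.lags_ms, np.abs(cg.lags_ms)))
    for i in order:
        if counts[i] == peak:
            lag = float(cg.lags_ms[i])
            break
    mu = cg.expected_flat
    if mu > 0:
        z = stats.norm.isf(flat_alpha / counts.size)
        flat = bool(peak <= mu + z * np.sqrt(mu))
    else:
        flat = False
    return lag, float(peak), flat


__all__ = ["Correlogram", "cross_correlogram", "peak_lag", "BIN_MS", "HALF_WINDOW_MS"]
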