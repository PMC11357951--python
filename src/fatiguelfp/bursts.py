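"""Poisson-surprise burst detection (Legendy-Salcman) and summaries.

A burst seed is a run of at least three consecutive spikes whose first two
inter-spike intervals (ISIs) are each shorter than half the unit's mean
ISI in the analysis epoch.  Each seed is grown into the window that
maximizes the Poisson surprise

    S = -ln P(N >= n | N ~ Poisson(r T)),

where n is the spike count in the window, T its first-to-last spike span,
and r the unit's mean rate over the epoch.  Extension and trimming are
carried to the surprise optimum by an exact search over all windows that
contain the seed's short-ISI pair (bounded by a spike-count cap);
overlapping candidates are resolved keeping the higher-surprise burst and
re-optimizing the remainder.  Bursts are retained when S exceeds the
threshold (default 10).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .core import EpochWindow, SpikeTrain

S_MIN = 10.0            # retention threshold on the surprise
MAX_EXTENT = 150        # spike-count cap on window search around a seed
PRUNE_LOOKAHEAD = 12    # cheap first-pass extent for background seeds
SMALL_TRAIN = 60        # below this epoch count the full search is always used


@dataclass
class BurstRecord:
    """One retained burst of one unit."""

    region: str
    unit_id: int
    epoch: str
    start: float          # time of the first spike, s
    end: float            # time of the last spike, s
    n_spikes: int
    surprise: float
    spike_times: np.ndarray

    @property
    def duration(self) -> float:
        return self.end - self.start


def log_poisson_sf(n: np.ndarray | int, lam: np.ndarray | float) -> np.ndarray:
    """log P(N >= n) for N ~ Poisson(lam), stable far into the tail.

    Uses the regularized incomplete gamma identity P(N >= n) =
    gammainc(n, lam); where that underflows (surprise beyond ~700 nats)
    the tail is evaluated by its leading-term series in log space.
    """
    n = np.atleast_1d(np.asarray(n, dtype=float))
    lam = np.broadcast_to(np.atleast_1d(np.asarray(lam, dtype=float)), n.shape).copy()
    out = np.full(n.shape, -np.inf)
    pos = lam > 0
    p = np.zeros_like(lam)
    p[pos] = special.gammainc(n[pos], lam[pos])
    ok = p > 0
    out[ok] = np.log(p[ok])
    under = pos & ~ok
    if under.any():
        nn, ll = n[under], lam[under]
        # ln P = -lam + n ln lam - ln n! + ln sum_j prod_{i<=j} lam/(n+i)
        term = np.ones_like(ll)
        acc = np.ones_like(ll)
        for j in range(1, 200):
            term = term * ll / (nn + j)
            acc += term
            if np.all(term < 1e-18 * acc):
                break
        out[under] = -ll + nn * np.log(ll) - special.gammaln(nn + 1) + np.log(acc)
    return out


def poisson_surprise(n: int, T: float, r: float, base: float | None = None) -> float:
    """Surprise S = -log P(N >= n) for a Poisson count at rate r over T.

    Natural log by default; pass base to change it.  Numerically stable up
    to and beyond S ~ 700.
    """
    if n < 1 or T <= 0 or r <= 0:
        raise ValueError("need n >= 1, T > 0, r > 0")
    s = -float(log_poisson_sf(n, r * T)[0])
    if base is not None:
        s /= math.log(base)
    return s


def _seed_runs(short: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [i0, i1] (ISI indices, inclusive) of >= 2 short ISIs."""
    runs = []
    i = 0
    m = short.size
    while i < m:
        if short[i]:
            j = i
            while j + 1 < m and short[j + 1]:
                j += 1
            if j > i:            # at least two consecutive short ISIs
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _best_window(
    times: np.ndarray,
    run: tuple[int, int],
    r: float,
    extent: int,
    occupied_cum: np.ndarray | None,
) -> tuple[float, int, int]:
    """Max-surprise window containing one of the run's short-ISI pairs.

    Windows are spike index pairs (a, b), a <= p, b >= p+2 for a pair
    start p in [i0, i1-1]; a ranges extent spikes left of the run and b
    extent spikes right of it.  Windows overlapping occupied spikes are
    excluded.  Returns (S, a, b) or (-inf, -1, -1).
    """
    n = times.size
    i0, i1 = run
    a_idx = np.arange(max(0, i0 - extent), i1)            # a <= i1 - 1
    b_idx = np.arange(i0 + 2, min(n, i1 + 2 + extent))    # b >= i0 + 2
    if a_idx.size == 0 or b_idx.size == 0:
        return -np.inf, -1, -1
    A = a_idx[:, None]
    B = b_idx[None, :]
    valid = np.maximum(A, i0) <= np.minimum(B - 2, i1 - 1)
    valid &= (B - A) >= 2                                  # >= 3 spikes
    if occupied_cum is not None:
        valid &= (occupied_cum[B + 1] - occupied_cum[A]) == 0
    if not valid.any():
        return -np.inf, -1, -1
    n_w = (B - A + 1).astype(float)
    lam = r * (times[B] - times[A])
    s = np.where(valid, -log_poisson_sf(n_w.ravel(), lam.ravel()).reshape(n_w.shape),
                 -np.inf)
    flat = int(np.argmax(s))
    ia, ib = np.unravel_index(flat, s.shape)
    return float(s[ia, ib]), int(a_idx[ia]), int(b_idx[ib])


def detect_bursts(
    train: SpikeTrain,
    epoch: EpochWindow,
    s_min: float = S_MIN,
    max_extent: int = MAX_EXTENT,
) -> list[BurstRecord]:
    """Poisson-surprise bursts of one unit within one epoch.

    Fewer than three spikes (or no qualifying seed) yields an empty list.
    Retained bursts are non-overlapping, time-ordered, each containing a
    short-ISI seed pair and exceeding the surprise threshold.
    """
    times = train.in_window(epoch.start, epoch.end)
    n = times.size
    if n < 3:
        return []
    r = n / epoch.duration
    isi = np.diff(times)
    half_mean = isi.mean() / 2.0
    runs = _seed_runs(isi < half_mean)
    if not runs:
        return []

    small = n <= SMALL_TRAIN
    heap: list[tuple[float, int, int, int, tuple[int, int]]] = []
    stamped: dict[int, int] = {}
    for ridx, run in enumerate(runs):
        extent = max_extent if small else PRUNE_LOOKAHEAD
        s, a, b = _best_window(times, run, r, extent, None)
        if not small and s > s_min and extent < max_extent:
            s, a, b = _best_window(times, run, r, max_extent, None)
        if s > s_min:
            heapq.heappush(heap, (-s, ridx, a, b, run))
            stamped[ridx] = 0

    occupied = np.zeros(n, dtype=bool)
    cum = np.concatenate(([0], np.cumsum(occupied)))
    version = 0
    bursts: list[BurstRecord] = []
    while heap:
        neg_s, ridx, a, b, run = heapq.heappop(heap)
        if stamped.get(ridx, -1) != version and occupied[a : b + 1].any():
            # the scored optimum now collides with an accepted burst:
            # re-optimize this seed within the free spikes
            s, a, b = _best_window(times, run, r, max_extent, cum)
            stamped[ridx] = version
            if s > s_min:
                heapq.heappush(heap, (-s, ridx, a, b, run))
            continue
        if occupied[a : b + 1].any():
            continue
        occupied[a : b + 1] = True
        cum = np.concatenate(([0], np.cumsum(occupied)))
        version += 1
        bursts.append(
            BurstRecord(
                train.region,
                train.unit_id,
                epoch.label,
                float(times[a]),
                float(times[b]),
                int(b - a + 1),
                -neg_s,
                times[a : b + 1].copy(),
            )
        )
    bursts.sort(key=lambda rec: rec.start)
    return bursts


def burst_summary(
    bursts: list[BurstRecord],
    trains: list[SpikeTrain],
    epochs: list[EpochWindow],
) -> pd.DataFrame:
    """Per (region, epoch) burst aggregates.

    Columns: burst count, normalized burst rate (fraction of all spikes
    that fall inside bursts), mean spikes per burst, mean burst duration,
    and the fraction of units with at least one burst.  Means are NaN when
    an epoch has no bursts.
    """
    regions = sorted({tr.region for tr in trains})
    rows = []
    for region in regions:
        r_trains = [tr for tr in trains if tr.region == region]
        for ep in epochs:
            eb = [b for b in bursts if b.region == region and b.epoch == ep.label]
            total_spikes = sum(tr.in_window(ep.start, ep.end).size for tr in r_trains)
            burst_spikes = sum(b.n_spikes for b in eb)
            bursting_units = {(b.unit_id) for b in eb}
            rows.append(
                {
                    "region": region,
                    "epoch": ep.label,
                    "bursts_per_epoch": len(eb),
                    "normalized_burst_rate": (
                        burst_spikes / total_spikes if total_spikes else 0.0
                    ),
                    "mean_spikes_in_burst": (
                        float(np.mean([b.n_spikes for b in eb])) if eb else np.nan
                    ),
                    "mean_burst_duration": (
                        float(np.mean([b.duration for b in eb])) if eb else np.nan
                    ),
                    "burst_unit_ratio": (
                        len(bursting_units) / len(r_trains) if r_trains else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "BurstRecord",
    "poisson_surprise",
    "log_poisson_sf",
    "detect_bursts",
    "burst_summary",
    "S_MIN",
]
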