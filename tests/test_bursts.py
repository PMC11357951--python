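"""Poisson-surprise bursts: exact-tail oracle, exhaustive-search equivalence."""

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatiguelfp.core import EpochWindow, SpikeTrain
from fatiguelfp.bursts import (
    burst_summary,
    detect_bursts,
    log_poisson_sf,
    poisson_surprise,
)


def surprise_oracle(n, lam, dps=60):
    """-ln P(N >= n) by arbitrary-precision upper-tail summation."""
    with mpmath.workdps(dps):
        # P(N >= n) = 1 - gammainc_regularized_upper ... use direct sum of
        # the complementary lower tail for exactness
        lam_m = mpmath.mpf(lam)
        tail = mpmath.mpf(0)
        term = mpmath.e ** (-lam_m) * lam_m**n / mpmath.factorial(n)
        k = n
        while True:
            tail += term
            k += 1
            term = term * lam_m / k
            if term < tail * mpmath.mpf(10) ** (-dps):
                break
        return float(-mpmath.log(tail))


def exhaustive_max_surprise(times, rate):
    """Brute force: score every contiguous subsequence of >= 3 spikes.

    Only windows that qualify as bursts are scored, i.e. windows holding
    two consecutive ISIs each below half the train's mean ISI (the burst
    definition); the maximum is -inf when no window qualifies.
    """
    n = times.size
    isi = np.diff(times)
    half = isi.mean() / 2.0
    short = isi < half
    pair_ok = short[:-1] & short[1:]          # pair_ok[p]: isi[p], isi[p+1] short
    pair_cum = np.concatenate(([0], np.cumsum(pair_ok)))
    best = -np.inf
    for a in range(n - 2):
        for b in range(a + 2, n):
            if pair_cum[b - 1] - pair_cum[a] == 0:
                continue                      # no seed pair inside [a, b]
            s = poisson_surprise(b - a + 1, times[b] - times[a], rate)
            best = max(best, s)
    return best


class TestPoissonSurprise:
    @pytest.mark.parametrize(
        "n,lam",
        [(10, 10.0), (10, 0.1), (3, 0.8), (50, 5.0), (200, 20.0), (400, 30.0),
         (5, 100.0), (1, 0.01)],
    )
    def test_matches_arbitrary_precision_oracle(self, n, lam):
        got = poisson_surprise(n, 1.0, lam)  # T=1, r=lam
        assert got == pytest.approx(surprise_oracle(n, lam), rel=1e-9)

    def test_deep_tail_no_overflow(self):
        """The stable tail stays finite and accurate out to S ~ 700."""
        s = poisson_surprise(300, 1.0, 7.5)
        assert np.isfinite(s)
        assert s == pytest.approx(surprise_oracle(300, 7.5), rel=1e-9)
        assert s > 600

    def test_limit_large_expectation(self):
        # with rT >> n the tail probability approaches 1, so S -> 0
        assert poisson_surprise(10, 1000.0, 1.0) < 1e-6

    def test_configurable_log_base(self):
        nat = poisson_surprise(10, 10.0, 1.0)
        ten = poisson_surprise(10, 10.0, 1.0, base=10.0)
        assert ten == pytest.approx(nat / np.log(10))

    def test_invalid_arguments(self):
        for bad in [(0, 1.0, 1.0), (3, 0.0, 1.0), (3, 1.0, 0.0)]:
            with pytest.raises(ValueError):
                poisson_surprise(*bad)

    def test_vectorized_consistency(self):
        ns = np.array([3.0, 10.0, 40.0])
        lams = np.array([1.0, 5.0, 2.0])
        vec = log_poisson_sf(ns, lams)
        for i in range(3):
            assert vec[i] == pytest.approx(float(log_poisson_sf(int(ns[i]), lams[i])[0]))


class TestDetectBursts:
    def test_regular_train_has_no_bursts(self):
        times = np.arange(0.05, 60.0, 0.5)
        tr = SpikeTrain("M1", 0, times, (0.0, 60.0))
        assert detect_bursts(tr, EpochWindow("pre", 0.0, 60.0)) == []

    def test_too_few_spikes_empty(self):
        tr = SpikeTrain("M1", 0, np.array([1.0, 2.0]), (0.0, 60.0))
        assert detect_bursts(tr, EpochWindow("pre", 0.0, 60.0)) == []

    def test_planted_episode_recovered(self, rng):
        """One 20-spike 100 Hz episode in 2 Hz background: one burst,
        containing >= 18 of the planted spikes, S > 10."""
        bg = np.sort(rng.uniform(0.0, 60.0, rng.poisson(2.0 * 60.0)))
        planted = 30.0 + np.arange(20) * 0.01
        times = np.unique(np.concatenate([bg, planted]))
        tr = SpikeTrain("M1", 0, times, (0.0, 60.0))
        found = detect_bursts(tr, EpochWindow("pre", 0.0, 60.0))
        assert len(found) == 1
        b = found[0]
        assert b.surprise > 10
        inside = np.sum((planted >= b.start - 1e-9) & (planted <= b.end + 1e-9))
        assert inside >= 18

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_small_trains(self, seed):
        """On random trains of <= 30 spikes the detector attains the
        exhaustive contiguous-subsequence maximal surprise."""
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 31))
        duration = 30.0
        if r.random() < 0.5:
            times = np.sort(r.uniform(0, duration, n))
        else:  # plant a dense patch to exercise the seed logic
            k = int(r.integers(3, max(4, n)))
            dense = r.uniform(0, duration - 1) + np.sort(r.uniform(0, 0.3, k))
            rest = r.uniform(0, duration, n - k)
            times = np.sort(np.concatenate([dense, rest]))
        times = np.unique(times)
        if times.size < 3:
            return
        tr = SpikeTrain("M1", 0, times, (0.0, duration))
        ep = EpochWindow("pre", 0.0, duration)
        rate = times.size / duration
        oracle = exhaustive_max_surprise(times, rate)
        found = detect_bursts(tr, ep, s_min=10.0)
        if oracle > 10.0:
            assert found, f"oracle found S={oracle:.2f} but detector none"
            best = max(b.surprise for b in found)
            assert best == pytest.approx(oracle, rel=1e-9)
        else:
            assert not found

    def test_bursts_non_overlapping_and_seeded(self, rng):
        bg = np.sort(rng.uniform(0.0, 120.0, rng.poisson(5.0 * 120.0)))
        bursts_t = [20.0 + np.arange(25) * 0.008, 70.0 + np.arange(30) * 0.01]
        times = np.unique(np.concatenate([bg, *bursts_t]))
        tr = SpikeTrain("M1", 0, times, (0.0, 120.0))
        ep = EpochWindow("pre", 0.0, 120.0)
        found = detect_bursts(tr, ep)
        assert len(found) >= 2
        mean_isi = np.diff(tr.in_window(0, 120.0)).mean()
        for a, b in zip(found, found[1:]):
            assert a.end < b.start           # ordered, disjoint
        for b in found:
            assert b.surprise > 10.0
            assert b.n_spikes >= 3
            isis = np.diff(b.spike_times)
            two_short = np.any((isis[:-1] < mean_isi / 2) & (isis[1:] < mean_isi / 2))
            assert two_short                 # contains a seed pair

    def test_added_spike_in_burst_never_lowers_surprise(self, rng):
        bg = np.sort(rng.uniform(0.0, 60.0, rng.poisson(2.0 * 60.0)))
        planted = 30.0 + np.arange(20) * 0.01
        times = np.unique(np.concatenate([bg, planted]))
        tr = SpikeTrain("M1", 0, times, (0.0, 60.0))
        ep = EpochWindow("pre", 0.0, 60.0)
        s0 = max(b.surprise for b in detect_bursts(tr, ep))
        times2 = np.unique(np.concatenate([times, [30.095]]))
        tr2 = SpikeTrain("M1", 0, times2, (0.0, 60.0))
        s1 = max(b.surprise for b in detect_bursts(tr2, ep))
        assert s1 >= s0

    def test_scale_invariance(self, rng):
        bg = np.sort(rng.uniform(0.0, 60.0, rng.poisson(3.0 * 60.0)))
        planted = 10.0 + np.arange(15) * 0.012
        times = np.unique(np.concatenate([bg, planted]))
        ep = EpochWindow("pre", 0.0, 60.0)
        found = detect_bursts(SpikeTrain("M1", 0, times, (0.0, 60.0)), ep)
        c = 7.0
        found_scaled = detect_bursts(
            SpikeTrain("M1", 0, times * c, (0.0, 60.0 * c)),
            EpochWindow("pre", 0.0, 60.0 * c),
        )
        assert len(found) == len(found_scaled)
        for a, b in zip(found, found_scaled):
            assert a.n_spikes == b.n_spikes
            assert a.surprise == pytest.approx(b.surprise, rel=1e-9)


class TestBurstSummary:
    def test_every_spike_in_burst(self):
        from fatiguelfp.bursts import BurstRecord

        times = np.arange(10.0, 10.2, 0.01)
        tr = SpikeTrain("M1", 0, times, (0.0, 120.0))
        ep = EpochWindow("pre", 0.0, 120.0)
        covering = BurstRecord("M1", 0, "pre", times[0], times[-1],
                               times.size, 50.0, times)
        df = burst_summary([covering], [tr], [ep])
        row = df.iloc[0]
        assert row.normalized_burst_rate == pytest.approx(1.0)
        assert row.mean_spikes_in_burst == times.size
        assert row.burst_unit_ratio == pytest.approx(1.0)

    def test_zero_bursts_missing_means(self):
        times = np.arange(0.5, 119.5, 1.0)
        tr = SpikeTrain("M1", 0, times, (0.0, 120.0))
        ep = EpochWindow("pre", 0.0, 120.0)
        df = burst_summary([], [tr], [ep])
        row = df.iloc[0]
        assert row.bursts_per_epoch == 0
        assert row.normalized_burst_rate == 0.0
        assert np.isnan(row.mean_spikes_in_burst)
        assert np.isnan(row.mean_burst_duration)

    def test_default_spec_spikes_per_burst_recovered(self):
        """Planted ~71.8 spikes/episode recovered within 15% on pre data."""
        from fatiguelfp import default_spec, gen_spike_trains

        means = []
        for seed in (51, 52):
            spec = default_spec({"seed": seed})
            trains = [t for t in gen_spike_trains(spec, "pre") if t.region == "M1"]
            ep = EpochWindow("pre", 0.0, spec.duration)
            bursts = [b for tr in trains for b in detect_bursts(tr, ep)]
            df = burst_summary(bursts, trains, [ep])
            means.append(df.iloc[0].mean_spikes_in_burst)
        planted = default_spec({}).spikes_per_burst_mean["M1"]
        assert np.mean(means) == pytest.approx(planted, rel=0.15)

    def test_burst_unit_ratio(self):
        burst_train = SpikeTrain(
            "M1", 0,
            np.unique(np.concatenate([np.arange(0.5, 119.5, 1.0),
                                      60.0 + np.arange(20) * 0.01])),
            (0.0, 120.0),
        )
        quiet_train = SpikeTrain("M1", 1, np.arange(0.25, 119.5, 1.0), (0.0, 120.0))
        ep = EpochWindow("pre", 0.0, 120.0)
        bursts = [b for tr in (burst_train, quiet_train)
                  for b in detect_bursts(tr, ep)]
        df = burst_summary(bursts, [burst_train, quiet_train], [ep])
        assert df.iloc[0].burst_unit_ratio == pytest.approx(0.5)
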