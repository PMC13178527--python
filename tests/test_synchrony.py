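"""SPIKE distance (both variants against brute-force oracles), event
detection, event-triggered profiles and circular-shift surrogates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mnpool.spikes import CumulativeSpikeTrain, SpikeTrainSet
from mnpool.synchrony import (circular_shift, detect_sync_events,
                              event_triggered_profile,
                              multivariate_spike_distance,
                              pairwise_spike_distance, surrogate_profiles)
from mnpool.synthetic import (ImpulseInjectionSpec, RenewalSpec,
                              gen_renewal_trains, inject_common_impulses)


# ---------------------------------------------------------------------------
# brute-force oracles (direct, unoptimized evaluation)

def _aug(train, T):
    out = list(train)
    if not out or out[0] > 0:
        out = [0.0] + out
    if out[-1] < T:
        out = out + [T]
    return np.array(out)


def oracle_printed(t, a, b, T):
    """Literal evaluation: preceding/following spikes by definition, offsets
    as differences of the two trains' corner spikes, ISI-square-sum
    normalisation."""
    a, b = _aug(a, T), _aug(b, T)
    tp1 = a[a <= t].max(); tf1 = a[a > t].min()
    tp2 = b[b <= t].max(); tf2 = b[b > t].min()
    dP1, dF1 = t - tp1, tf1 - t
    dP2, dF2 = t - tp2, tf2 - t
    T1, T2 = tf1 - tp1, tf2 - tp2
    return (abs(tp1 - tp2) * (dF1 + dF2) + abs(tf1 - tf2) * (dP1 + dP2)) \
        / (T1 ** 2 + T2 ** 2)


def oracle_nearest(t, a, b, T):
    """Literal evaluation of the nearest-neighbour formulation."""
    a, b = _aug(a, T), _aug(b, T)
    tp1 = a[a <= t].max(); tf1 = a[a > t].min()
    tp2 = b[b <= t].max(); tf2 = b[b > t].min()
    dP1, dF1 = t - tp1, tf1 - t
    dP2, dF2 = t - tp2, tf2 - t
    T1, T2 = tf1 - tp1, tf2 - tp2
    dtp1 = np.min(np.abs(b - tp1)); dtf1 = np.min(np.abs(b - tf1))
    dtp2 = np.min(np.abs(a - tp2)); dtf2 = np.min(np.abs(a - tf2))
    S1 = (dtp1 * dF1 + dtf1 * dP1) / T1
    S2 = (dtp2 * dF2 + dtf2 * dP2) / T2
    Tm = 0.5 * (T1 + T2)
    return (S1 * T2 + S2 * T1) / (2 * Tm ** 2)


def _random_pair(rng, T=4.0):
    a = np.sort(rng.uniform(0.05, T - 0.05, rng.integers(3, 25)))
    b = np.sort(rng.uniform(0.05, T - 0.05, rng.integers(3, 25)))
    a = a[np.r_[True, np.diff(a) > 1e-4]]
    b = b[np.r_[True, np.diff(b) > 1e-4]]
    return a, b


class TestSpikeDistanceOracle:
    @pytest.mark.parametrize("variant,oracle",
                             [("printed", oracle_printed),
                              ("nearest", oracle_nearest)])
    def test_production_matches_bruteforce_on_100_random_instances(
            self, variant, oracle):
        rng = np.random.default_rng(2024)
        T = 4.0
        for _ in range(100):
            a, b = _random_pair(rng, T)
            grid = rng.uniform(0.01, T - 0.01, 7)
            grid.sort()
            prof = pairwise_spike_distance(a, b, grid, T, variant=variant)
            expect = [oracle(t, a, b, T) for t in grid]
            np.testing.assert_allclose(prof.values, expect, atol=1e-10)

    def test_worked_pair_matches_oracle(self):
        """Offset regular trains: the value at an interior instant equals
        the literal evaluation (frozen from the oracle)."""
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.1, 2.1, 3.1])
        T = 4.0
        prof = pairwise_spike_distance(a, b, np.array([1.5]), T)
        assert prof.values[0] == pytest.approx(oracle_printed(1.5, a, b, T),
                                               abs=1e-12)
        # hand evaluation: corners (1, 2) vs (1.1, 2.1), both local ISIs 1 s
        # -> [0.1*(0.5+0.6) + 0.1*(0.5+0.4)] / (1 + 1) = 0.1
        assert prof.values[0] == pytest.approx(0.1, abs=1e-12)


class TestSpikeDistanceProperties:
    def test_identical_trains_zero_everywhere(self):
        t = np.array([0.5, 1.2, 1.9, 2.6])
        grid = np.linspace(0.1, 2.9, 40)
        for variant in ("printed", "nearest"):
            prof = pairwise_spike_distance(t, t, grid, 3.0, variant=variant)
            np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_bounded_unit_interval_1000_random_pairs(self):
        rng = np.random.default_rng(7)
        grid = np.linspace(0.01, 3.99, 101)
        for _ in range(1000):
            a, b = _random_pair(rng)
            for variant in ("printed", "nearest"):
                prof = pairwise_spike_distance(a, b, grid, 4.0, variant=variant)
                assert prof.values.min() >= -1e-12
                assert prof.values.max() <= 1.0 + 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(0.1, 0.9), seed=st.integers(0, 10 ** 6))
    def test_common_time_shift_invariance(self, shift, seed):
        """S(t) is unchanged when both trains and the evaluation instant are
        shifted together (interior evaluation)."""
        rng = np.random.default_rng(seed)
        a, b = _random_pair(rng, T=3.0)
        grid = np.linspace(1.0, 2.0, 11)
        base = pairwise_spike_distance(a + 0.0, b + 0.0, grid, 5.0).values
        shifted = pairwise_spike_distance(a + shift, b + shift, grid + shift,
                                          5.0).values
        # exclude points whose bracketing spikes are the recording edges
        inner = (grid > a.min() + 0.01) & (grid < a.max() - 0.01) \
            & (grid > b.min() + 0.01) & (grid < b.max() - 0.01)
        np.testing.assert_allclose(shifted[inner], base[inner], atol=1e-9)

    def test_multivariate_two_trains_equals_pairwise(self):
        rng = np.random.default_rng(3)
        a, b = _random_pair(rng)
        grid = np.linspace(0.1, 3.9, 50)
        sts = SpikeTrainSet([a, b], 4.0, 1000.0)
        multi = multivariate_spike_distance(sts, grid)
        pair = pairwise_spike_distance(a, b, grid, 4.0)
        np.testing.assert_allclose(multi.values, pair.values, atol=1e-12)

    def test_multivariate_three_trains_is_pair_mean(self):
        rng = np.random.default_rng(4)
        trains = [_random_pair(rng)[0] for _ in range(3)]
        grid = np.linspace(0.1, 3.9, 30)
        sts = SpikeTrainSet(trains, 4.0, 1000.0)
        multi = multivariate_spike_distance(sts, grid)
        pairs = [pairwise_spike_distance(trains[i], trains[j], grid, 4.0).values
                 for i in range(3) for j in range(i + 1, 3)]
        np.testing.assert_allclose(multi.values, np.mean(pairs, axis=0),
                                   atol=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        trains = [_random_pair(rng)[0] for _ in range(5)]
        grid = np.linspace(0.1, 3.9, 20)
        a = multivariate_spike_distance(
            SpikeTrainSet(trains, 4.0, 1000.0), grid)
        perm = [3, 1, 4, 0, 2]
        b = multivariate_spike_distance(
            SpikeTrainSet([trains[i] for i in perm], 4.0, 1000.0), grid)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_grid_outside_recording_rejected(self):
        with pytest.raises(ValueError):
            pairwise_spike_distance(np.array([1.0]), np.array([2.0]),
                                    np.array([5.0]), 4.0)


class TestEventDetection:
    def _cst(self, x, fs, rate=10.4):
        return CumulativeSpikeTrain(np.asarray(x, float), fs,
                                    np.arange(5), "mean", rate)

    def test_pure_sinusoid_yields_no_events(self):
        """A constant-envelope carrier never exceeds mean + 1 SD."""
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        ev = detect_sync_events(self._cst(np.cos(2 * np.pi * 10.4 * t), fs))
        assert ev.times.size == 0

    def test_amplitude_modulated_bursts_recovered(self):
        """A 10.4 Hz carrier with raised 1/s amplitude bursts: one event per
        burst, each within +-50 ms of its modulation maximum."""
        fs = 1000.0
        dur = 30.0
        t = np.arange(int(dur * fs)) / fs
        centres = np.arange(1.5, 29.0, 1.0)
        env = 1.0 + sum(4.0 * np.exp(-0.5 * ((t - c) / 0.05) ** 2)
                        for c in centres)
        ev = detect_sync_events(self._cst(env * np.cos(2 * np.pi * 10.4 * t), fs))
        assert ev.rate == pytest.approx(len(centres) / dur, abs=0.15)
        matched = 0
        for c in centres:
            if np.any(np.abs(ev.times - c) < 0.05):
                matched += 1
        assert matched >= 0.9 * len(centres)

    def test_band_outside_nyquist_rejected(self):
        fs = 100.0
        with pytest.raises(ValueError):
            detect_sync_events(self._cst(np.zeros(3000), fs), f_dr=49.5)

    def test_detection_deterministic(self, renewal_set):
        from mnpool.spikes import cumulative_spike_train
        cst = cumulative_spike_train(renewal_set, fs=1000.0)
        a = detect_sync_events(cst)
        b = detect_sync_events(cst)
        np.testing.assert_array_equal(a.times, b.times)


class TestEventTriggeredProfile:
    def test_identical_trains_give_zero_profile(self):
        from mnpool.synchrony import SyncEventSet
        rng = np.random.default_rng(0)
        base = np.arange(0.2, 29.8, 0.1) + rng.uniform(0, 0.02, 296)
        sts = SpikeTrainSet([base.copy() for _ in range(5)], 30.0, 1000.0)
        events = SyncEventSet(np.arange(3.0, 28.0, 5.0), 0.0, 10.0, 4.0, 30.0)
        prof = event_triggered_profile(sts, events=events, subpool=None, seed=1)
        assert prof.min_value == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_profile_deterministic_under_seed(self, renewal_set):
        a = event_triggered_profile(renewal_set, subpool=20, iterations=3,
                                    seed=9)
        b = event_triggered_profile(renewal_set, subpool=20, iterations=3,
                                    seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.min_value == b.min_value


class TestSurrogates:
    def test_circular_shift_preserves_counts_and_isi_multiset(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0.1, 29.9, 200))
        shifted = circular_shift(t, 5.321, 30.0)
        assert shifted.size == t.size
        # ISI multiset identical except the single wrap-around interval
        isi_a = np.sort(np.diff(np.r_[t, t[0] + 30.0]))
        isi_b = np.sort(np.diff(np.r_[shifted, shifted[0] + 30.0]))
        np.testing.assert_allclose(isi_a, isi_b, atol=1e-9)

    def test_zero_shift_is_identity(self):
        t = np.array([1.0, 2.5, 7.0])
        np.testing.assert_allclose(circular_shift(t, 0.0, 30.0), t)

    def test_shift_range_validated(self, renewal_set):
        with pytest.raises(ValueError, match="shift range"):
            surrogate_profiles(renewal_set, n_surrogates=1,
                               shift_range=(2.0, 60.0))

    def test_surrogates_destroy_injected_synchrony(self):
        """With injected common impulses, the surrogate-mean minimum exceeds
        the true event-triggered minimum."""
        sts = gen_renewal_trains(RenewalSpec(n_units=18, seed=13))
        sync = inject_common_impulses(sts, ImpulseInjectionSpec(rate=1.0,
                                                                seed=14))
        true = event_triggered_profile(sync, subpool=None, seed=2)
        minima, mean_min, _ = surrogate_profiles(sync, n_surrogates=6,
                                                 seed=3, subpool=None)
        assert mean_min > true.min_value
        assert (minima > true.min_value).mean() >= 0.8
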