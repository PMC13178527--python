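"""Common-input generators: burst trains, narrowband noise, combinations and
their analytic properties."""

import numpy as np
import pytest

from mnpool.inputs import (NarrowbandSpec, PulseTrainSpec, make_cci,
                           make_combined_ci, make_ici, make_matched_sinusoid,
                           pulse_train_line_power, pulse_times)
from mnpool.spectral import welch_psd

FS = 5000.0


class TestPulseTrain:
    def test_zero_rate_gives_silence(self):
        sig = make_ici(PulseTrainSpec(rate=0.0), 10.0, FS)
        assert not sig.samples.any()

    def test_pulse_count_and_width_at_reference_settings(self):
        """30 s at 1 burst/s with 1 s guards: 28 bursts of 25 samples each
        at 5 kHz."""
        spec = PulseTrainSpec(amplitude=2.0, rate=1.0, seed=3)
        sig = make_ici(spec, 30.0, FS)
        assert len(sig.pulse_times) == 28
        assert sig.samples.sum() == pytest.approx(28 * 25 * 2.0)
        assert sig.samples.max() == 2.0

    def test_jitter_bounded_by_20_percent_of_period(self):
        spec = PulseTrainSpec(rate=1.0, jitter_frac=0.2, seed=11)
        t = pulse_times(spec, 30.0)
        nominal = 1.0 + np.arange(len(t)) * 1.0
        assert np.all(np.abs(t - nominal) <= 0.2 + 1e-12)

    def test_guards_respected(self):
        for seed in range(5):
            sig = make_ici(PulseTrainSpec(rate=2.0, seed=seed), 30.0, FS)
            assert sig.pulse_times.min() >= 1.0
            assert sig.pulse_times.max() + 0.005 <= 29.0

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_ici(PulseTrainSpec(rate=150.0), 10.0, FS)

    def test_fixed_seed_reproduces_waveform(self):
        a = make_ici(PulseTrainSpec(rate=3.0, seed=5), 20.0, FS)
        b = make_ici(PulseTrainSpec(rate=3.0, seed=5), 20.0, FS)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_nonnegative(self):
        sig = make_ici(PulseTrainSpec(rate=4.0, seed=1), 20.0, FS)
        assert sig.samples.min() >= 0

    def test_jitter_free_train_has_harmonic_lines_jittered_less(self):
        """Without jitter the PSD shows lines at exact multiples of 1/D;
        with 20% jitter the harmonics lose power relative to the
        fundamental."""
        clean = make_ici(PulseTrainSpec(rate=1.0, jitter_frac=0.0), 30.0, FS)
        jit = make_ici(PulseTrainSpec(rate=1.0, jitter_frac=0.2, seed=2),
                       30.0, FS)
        def line_and_background(sig, f):
            """Full-resolution periodogram: power within +-0.1 Hz of f vs
            the local broadband level 0.2-0.8 Hz away."""
            x = sig.samples - sig.samples.mean()
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(x.size, 1 / FS)
            line = spec[np.abs(freqs - f) <= 0.1].sum()
            off = (np.abs(freqs - f) > 0.2) & (np.abs(freqs - f) <= 0.8)
            bg = spec[off].sum() * 0.2 / 0.6   # rescaled to the same width
            return line, bg
        # harmonic-to-fundamental ratio shrinks under jitter
        r_clean = line_and_background(clean, 10.0)[0] \
            / line_and_background(clean, 1.0)[0]
        r_jit = line_and_background(jit, 10.0)[0] \
            / line_and_background(jit, 1.0)[0]
        assert r_jit < r_clean
        # without jitter both lines stand clear of their local background;
        # 20% jitter wipes out the 10th-harmonic line but not the fundamental
        for f in (1.0, 10.0):
            v, bg = line_and_background(clean, f)
            assert v > 10 * bg
        v1, bg1 = line_and_background(jit, 1.0)
        v10, bg10 = line_and_background(jit, 10.0)
        assert v1 > 2 * bg1
        assert v10 < 2 * bg10


class TestNarrowband:
    def test_zero_power_gives_silence(self):
        sig = make_cci(NarrowbandSpec(centre=20.0, power=0.0), 30.0, FS)
        assert not sig.samples.any()

    @pytest.mark.parametrize("power", [0.5, 2.0])
    def test_realized_power_exact(self, power):
        sig = make_cci(NarrowbandSpec(centre=20.0, power=power, seed=4),
                       30.0, FS)
        assert np.mean(sig.samples ** 2) == pytest.approx(power, rel=1e-9)

    def test_zero_mean_within_one_percent_of_rms(self):
        sig = make_cci(NarrowbandSpec(centre=20.0, power=1.0, seed=9), 30.0, FS)
        assert abs(sig.samples.mean()) < 0.01 * np.sqrt(np.mean(sig.samples ** 2))

    def test_spectrum_concentrated_at_centre(self):
        """The Welch PSD peaks at the bin containing the centre frequency,
        and a full-resolution periodogram puts >=90% of the power within
        +-1 Hz of it (the 1 s Welch windows themselves smear the band
        edges)."""
        sig = make_cci(NarrowbandSpec(centre=20.0, power=1.0, seed=6), 30.0, FS)
        est = welch_psd(sig.samples - sig.samples.mean(), FS)
        peak = est.freqs[np.argmax(est.values)]
        assert abs(peak - 20.0) <= 0.5
        x = sig.samples - sig.samples.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / FS)
        band = np.abs(freqs - 20.0) <= 1.0
        assert spec[band].sum() / spec.sum() >= 0.90

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NarrowbandSpec(centre=0.4, bandwidth=1.0)
        with pytest.raises(ValueError):
            NarrowbandSpec(centre=20.0, power=-1.0)
        with pytest.raises(ValueError, match="duration"):
            make_cci(NarrowbandSpec(centre=20.0, power=1.0), 5.0, FS)


class TestCombined:
    def test_sum_is_exact(self):
        n = NarrowbandSpec(centre=20.0, power=0.3, seed=1)
        p = PulseTrainSpec(amplitude=0.5, rate=1.0, seed=2)
        combo = make_combined_ci(n, p, 30.0, FS)
        np.testing.assert_allclose(
            combo.samples - make_cci(n, 30.0, FS).samples,
            make_ici(p, 30.0, FS).samples, atol=1e-12)

    def test_zero_component_passthrough(self):
        n = NarrowbandSpec(centre=20.0, power=0.0, seed=1)
        p = PulseTrainSpec(amplitude=0.5, rate=1.0, seed=2)
        combo = make_combined_ci(n, p, 30.0, FS)
        np.testing.assert_array_equal(combo.samples,
                                      make_ici(p, 30.0, FS).samples)


class TestMatchedSinusoid:
    def test_line_power_matches_pulse_harmonic(self):
        """The pure cosine carries exactly the analytic line power of the
        jitter-free burst train's harmonic nearest F_DR, and the analytic
        line power matches a periodogram measurement of the pulse train."""
        p = PulseTrainSpec(amplitude=1.0, rate=1.0, jitter_frac=0.0)
        sin = make_matched_sinusoid(p, 10.4, 30.0, FS)
        k = 10
        expect = pulse_train_line_power(p, k)
        assert np.mean(sin.samples ** 2) == pytest.approx(expect, rel=1e-3)
        # measure the 10 Hz line of a long deterministic pulse train
        long = make_ici(PulseTrainSpec(amplitude=1.0, rate=1.0,
                                       jitter_frac=0.0, guard=0.0), 64.0, FS)
        x = long.samples - long.samples.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2 / x.size ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / FS)
        line = 2 * spec[np.argmin(np.abs(freqs - 10.0))]
        assert line == pytest.approx(expect, rel=0.05)
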