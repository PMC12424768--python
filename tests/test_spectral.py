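"""Spectral-analysis tests: filter contracts, Morlet scalogram conventions,
oracle equivalence, cycle handling, peak extraction and exclusion rules."""

import numpy as np
import pytest

from mecgamma.spectral import (FilterSpec, ScalogramSpec, ExclusionCriteria,
                               GammaPeakSummary, zero_phase_bandpass,
                               morlet_cwt, cycle_scalograms, peak_gamma,
                               apply_exclusions, analyze_trace,
                               EmptyScalogramError)
from mecgamma.synth import SynthTraceSpec, make_theta_nested_gamma

FS = 10000.0
SCALE_STEP = 2.0 ** (1.0 / 32.0)


def tone(freq, duration_s=2.0, amp=1.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestZeroPhaseBandpass:
    def test_passband_center_preserved(self):
        x = tone(100.0)
        y = zero_phase_bandpass(x, FS)
        seg = slice(5000, 15000)
        assert np.abs(y[seg]).max() == pytest.approx(1.0, rel=0.05)
        # zero net phase: cross-correlation peak at zero lag
        xc = np.correlate(y[seg], x[seg], "full")
        lag = np.argmax(xc) - (len(xc) - 1) // 2
        assert abs(lag) * 1000.0 / FS < 1.0 / 36.0  # < 1 degree at 100 Hz

    def test_theta_strongly_attenuated(self):
        y = zero_phase_bandpass(tone(8.0, 4.0), FS)
        assert np.abs(y[10000:30000]).max() < 0.05

    def test_time_reversal_symmetry(self):
        # equality away from the finite-length edge transients
        rng = np.random.default_rng(0)
        x = rng.standard_normal(16384)
        a = zero_phase_bandpass(x[::-1], FS)
        b = zero_phase_bandpass(x, FS)[::-1]
        assert np.allclose(a[3000:-3000], b[3000:-3000], atol=1e-8)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            zero_phase_bandpass(np.zeros(100), 300.0)


class TestMorletCWT:
    def test_tone_peak_location_and_amplitude_convention(self):
        spec = ScalogramSpec()
        freqs = spec.frequencies()
        for a in (1.0, 3.0):
            p = morlet_cwt(tone(100.0, amp=a), FS, freqs)
            mid = p[:, 5000:15000].mean(axis=1)
            f_hat = freqs[np.argmax(mid)]
            assert abs(np.log2(f_hat / 100.0)) <= 1.001 / 32.0
            # envelope-amplitude-squared convention: peak power = a^2
            assert mid.max() == pytest.approx(a ** 2, rel=0.05)

    def test_power_scales_quadratically(self):
        spec = ScalogramSpec()
        x = tone(120.0)
        p1 = morlet_cwt(x, FS, spec.frequencies())
        p3 = morlet_cwt(3.0 * x, FS, spec.frequencies())
        assert np.allclose(p3, 9.0 * p1, rtol=1e-9, atol=1e-12)

    def test_two_tone_argmax(self):
        spec = ScalogramSpec()
        freqs = spec.frequencies()
        x = tone(80.0) + 1.5 * tone(140.0)
        p = morlet_cwt(x, FS, freqs).mean(axis=1)
        assert abs(np.log2(freqs[np.argmax(p)] / 140.0)) <= 1.001 / 32.0

    def test_constant_trace_has_zero_power(self):
        # away from the boundary discontinuity the analytic wavelet
        # rejects DC entirely
        p = morlet_cwt(np.full(8000, 7.5), FS, [60.0, 100.0, 200.0])
        assert np.max(p[:, 2000:-2000]) < 1e-12

    def test_direct_convolution_oracle_within_1pct(self):
        """FFT implementation vs brute-force convolution with sampled
        Morlet atoms, on a short multicomponent signal."""
        fs = 2000.0
        t = np.arange(2048) / fs
        x = np.sin(2 * np.pi * 70 * t) + 0.5 * np.sin(2 * np.pi * 150 * t)
        freqs = [60.0, 70.0, 100.0, 150.0]
        w0 = 6.0
        p_fft = morlet_cwt(x, fs, freqs, w0)
        # amplitude normalization: a tone of amplitude a has |W| = a
        norm = 2.0 / (np.pi ** -0.25 * np.sqrt(2 * np.pi))
        for j, f in enumerate(freqs):
            s = w0 / (2 * np.pi * f)          # seconds
            half = int(np.ceil(6 * s * fs))
            tt = np.arange(-half, half + 1) / fs
            psi = (np.pi ** -0.25) * np.exp(1j * w0 * tt / s) \
                * np.exp(-0.5 * (tt / s) ** 2)
            conv = np.convolve(x, psi, "same") / (s * fs)
            p_direct = np.abs(norm * conv) ** 2
            mid = slice(400, 1600)   # away from edges
            denom = p_fft[j, mid].max()
            assert np.max(np.abs(p_fft[j, mid] - p_direct[mid])) / denom < 0.01

    def test_peak_frequency_agrees_with_mne(self):
        """Independent oracle: MNE's Morlet TFR finds the same ridge."""
        mne = pytest.importorskip("mne")
        spec = ScalogramSpec()
        freqs = spec.frequencies()
        x = tone(115.0, 1.5) + 0.1 * np.random.default_rng(0).standard_normal(15000)
        p = morlet_cwt(x, FS, freqs).mean(axis=1)
        tfr = mne.time_frequency.tfr_array_morlet(
            x[np.newaxis, np.newaxis, :], FS, freqs, n_cycles=6.0,
            output="power", verbose="error")[0, 0]
        f_mine = freqs[np.argmax(p)]
        f_mne = freqs[np.argmax(tfr.mean(axis=1))]
        assert abs(np.log2(f_mine / f_mne)) <= 1.001 / 32.0


class TestCycleScalograms:
    def test_first_cycle_dropped_and_artifact_cycles_removed(self):
        spec = SynthTraceSpec(f_gamma=125.0, amplitude=100.0, noise_sd=5.0,
                              n_cycles=11, artifact_cycles=[(5, 5000.0)])
        _, x, _ = make_theta_nested_gamma(spec, seed=0)
        filt = zero_phase_bandpass(x, spec.fs)
        cs = cycle_scalograms(filt, spec.fs, artifact_trace=x)
        # 11 cycles, first dropped, one artifact cycle dropped
        assert cs.n_cycles_used == 9
        assert 0 not in cs.kept_cycles and 5 not in cs.kept_cycles
        # without the artifact, exactly one more cycle is retained
        spec2 = SynthTraceSpec(f_gamma=125.0, amplitude=100.0, noise_sd=5.0,
                               n_cycles=11)
        _, x2, _ = make_theta_nested_gamma(spec2, seed=0)
        cs2 = cycle_scalograms(zero_phase_bandpass(x2, spec2.fs), spec2.fs,
                               artifact_trace=x2)
        assert cs2.n_cycles_used == cs.n_cycles_used + 1

    def test_all_cycles_excluded_raises(self):
        x = np.full(int(FS), 4000.0)
        with pytest.raises(EmptyScalogramError):
            cycle_scalograms(x, FS)

    def test_linearity_in_power(self):
        spec = SynthTraceSpec(f_gamma=90.0, amplitude=50.0, n_cycles=5)
        _, x, _ = make_theta_nested_gamma(spec, seed=1)
        a = cycle_scalograms(x, spec.fs).average
        b = cycle_scalograms(2.0 * x, spec.fs).average
        assert np.allclose(b, 4.0 * a, rtol=1e-9)


class TestPeakGamma:
    def test_gamma_burst_ridge_recovered(self):
        spec = SynthTraceSpec(f_gamma=125.0, amplitude=100.0, noise_sd=5.0,
                              n_cycles=11)
        _, x, _ = make_theta_nested_gamma(spec, seed=2)
        summary, decision, _ = analyze_trace(x, spec.fs)
        assert abs(np.log2(summary.peak_frequency / 125.0)) <= 1.001 / 32.0
        assert decision.keep

    def test_white_noise_fails_snr_criterion(self):
        rng = np.random.default_rng(3)
        x = 50.0 * rng.standard_normal(int(11 * FS / 8.0))
        summary, decision, _ = analyze_trace(x, FS)
        assert summary.snr < 5.0
        assert decision.keep is False

    def test_frequency_recovery_over_100_fixtures(self):
        """Median |recovered - true| <= one scale step over 100 synthetic
        theta-nested traces with gamma frequency uniform in [60, 150] Hz."""
        rng = np.random.default_rng(4)
        errs = []
        for k in range(100):
            f_true = rng.uniform(60.0, 150.0)
            spec = SynthTraceSpec(f_gamma=f_true, amplitude=100.0,
                                  noise_sd=10.0, n_cycles=6, fs=2000.0)
            _, x, _ = make_theta_nested_gamma(spec, seed=1000 + k)
            summary, _, _ = analyze_trace(x, spec.fs)
            errs.append(abs(np.log2(summary.peak_frequency / f_true)))
        assert np.median(errs) <= 1.001 / 32.0


class TestExclusions:
    @pytest.mark.parametrize("power,bw,snr,mode,keep,reason", [
        (19.0, 50.0, 10.0, "thy1", False, "power"),
        (19.0, 50.0, 10.0, "pv", True, None),
        (500.0, 105.0, 10.0, "pv", True, None),
        (500.0, 105.0, 10.0, "thy1", False, "bandwidth"),
        (500.0, 50.0, 4.9, "thy1", False, "snr"),
        (500.0, 50.0, 5.0, "thy1", True, None),
    ])
    def test_rules(self, power, bw, snr, mode, keep, reason):
        s = GammaPeakSummary(peak_frequency=100.0, peak_power=power,
                             bandwidth=bw, snr=snr, n_cycles_used=40)
        d = apply_exclusions(s, ExclusionCriteria(), mode)
        assert d.keep is keep and d.reason == reason
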