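"""Deconvolution and the full inverse-filter pipeline."""

import numpy as np
import pytest
from scipy.linalg import solve_triangular, toeplitz

from isarestore import (
    DomainError,
    InverseFilterConfig,
    NoiseSpec,
    TimeSeries,
    TooShortError,
    add_noise,
    chunked_inverse_filter,
    deconvolve,
    default_chain,
    downsample,
    drift_frequency,
    inverse_filter,
    make_mixed_sine,
    make_step_with_sine,
    min_length_for,
    remove_drift,
    simulate_recording,
    zero_mean,
)
from isarestore.invfilter import UnstableUirError, deconvolve_frequency
from isarestore.uir import UIRModel
from isarestore.validate import amplitude_spectrum
from isarestore.forward_model import analytic_attenuation
from isarestore.core import FilterSpec


def uir_of(h, rate=1.0, norm=1.0):
    return UIRModel(h=np.asarray(h, float), rate=rate, norm=norm, source="analytic")


class TestDeconvolve:
    def test_delta_is_identity(self):
        y = TimeSeries([3.0, -1.0, 2.0, 0.5], 1.0)
        x = deconvolve(y, uir_of([1.0]))
        np.testing.assert_allclose(x.samples, y.samples)

    def test_scalar_division(self):
        y = TimeSeries([2.0, 4.0, 6.0], 1.0)
        x = deconvolve(y, uir_of([2.0]))
        np.testing.assert_allclose(x.samples, [1.0, 2.0, 3.0])

    def test_forward_convolution_oracle_double_step(self, uir, double_step,
                                                    double_step_recorded):
        x = deconvolve(double_step_recorded, uir)
        r = np.corrcoef(double_step.samples, x.samples)[0, 1]
        assert r >= 0.999
        # the flat feature of the step functions is restored
        t = double_step.times
        m = (t >= 12) & (t < 18)
        slope = np.polyfit(t[m], x.samples[m], 1)[0]
        assert abs(slope) < 0.01
        assert x.samples[m].mean() == pytest.approx(1.0, rel=0.02)

    def test_matches_triangular_system_solve(self):
        # brute-force oracle: y = T(h) x solved directly, n <= 256
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(8, 257))
            m = int(rng.integers(1, min(n, 32)))
            h = rng.normal(size=m)
            # dominant leading sample: the stable regime of long division,
            # as for a high-pass system's onset-spiked UIR
            h[0] = np.sign(h[0] or 1.0) * (np.abs(h[1:]).sum() + 1.0)
            x = rng.normal(size=n)
            y = np.convolve(x, h)[:n]
            col = np.zeros(n)
            col[:m] = h
            T = toeplitz(col, np.zeros(n))
            x_direct = solve_triangular(T, y, lower=True)
            x_ours = deconvolve(TimeSeries(y, 1.0), uir_of(h)).samples
            np.testing.assert_allclose(
                x_ours, x_direct, atol=1e-8 * np.abs(x_direct).max()
            )

    def test_round_trip_convolution(self, uir, double_step_recorded):
        y = zero_mean(double_step_recorded)
        x = deconvolve(y, uir)
        y_back = np.convolve(x.samples / uir.norm, uir.h)[: len(y)]
        np.testing.assert_allclose(
            y_back, y.samples, atol=1e-6 * np.abs(y.samples).max()
        )

    def test_zero_lead_rejected(self):
        y = TimeSeries(np.ones(16), 1.0)
        with pytest.raises(UnstableUirError):
            deconvolve(y, uir_of([0.0, 1.0]))

    def test_rate_mismatch_without_resampling(self):
        from isarestore.invfilter import RateMismatchError

        y = TimeSeries(np.ones(16), 2.0)
        with pytest.raises(RateMismatchError):
            deconvolve(y, uir_of([1.0], rate=1.0), resample_uir=False)

    def test_frequency_mode_agrees_on_smooth_signal(self, uir, mixed_loop):
        _, rec, _ = mixed_loop
        seg = TimeSeries(rec.samples[:65536], rec.rate)
        xt = deconvolve(zero_mean(seg), uir).samples
        xf = deconvolve_frequency(zero_mean(seg), uir, reg=1e-10).samples
        interior = slice(uir.h.size, 60000)
        assert np.corrcoef(xt[interior], xf[interior])[0, 1] > 0.99


class TestDriftRules:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(600.0, 1 / 1200), (100.0, 0.005), (1.0, 0.5)],
    )
    def test_drift_frequency(self, epoch, expected):
        assert drift_frequency(epoch) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "f_low,periods,expected",
        [(0.005, 3, 600.0), (0.01, 3, 300.0), (1.0, 3, 3.0)],
    )
    def test_min_length(self, f_low, periods, expected):
        assert min_length_for(f_low, periods) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            drift_frequency(0.0)
        with pytest.raises(DomainError):
            min_length_for(-1.0)


class TestRemoveDrift:
    def test_sine_amplitude_matches_analytic(self):
        rate, f = 10.0, 0.05
        t = np.arange(int(2000 * rate)) / rate
        ts = TimeSeries(np.sin(2 * np.pi * f * t), rate)
        out = remove_drift(ts, InverseFilterConfig())
        spec = FilterSpec("butterworth_highpass", 2, 0.005)
        predicted = analytic_attenuation(spec, f)
        amp = (out.samples[5000:].max() - out.samples[5000:].min()) / 2
        assert amp == pytest.approx(predicted, rel=0.02)

    def test_ramp_strongly_attenuated(self):
        rate = 10.0
        t = np.arange(int(1200 * rate)) / rate
        ts = TimeSeries(t / t.max(), rate)  # unit ramp over one epoch
        out = remove_drift(ts, InverseFilterConfig())
        assert np.abs(out.samples).max() < 0.1  # >= 10x reduction of unit range

    def test_constant_rejected_to_zero(self):
        ts = TimeSeries(np.full(20000, 5.0), 10.0)
        out = remove_drift(ts, InverseFilterConfig())
        assert np.abs(out.samples).max() < 1e-6

    def test_short_signal_warns(self):
        ts = TimeSeries(np.random.default_rng(0).normal(size=1000), 10.0)
        with pytest.warns(UserWarning, match="warm-up"):
            remove_drift(ts, InverseFilterConfig())


class TestInverseFilter:
    def test_mixed_sine_low_frequencies_restored(self, mixed_loop):
        mix, rec, recon = mixed_loop
        sp_in = amplitude_spectrum(mix)
        sp_rc = amplitude_spectrum(recon)
        for f in (0.01, 0.05, 0.07):
            k = np.argmin(np.abs(sp_in.freqs_hz - f))
            assert sp_rc.amplitude[k] == pytest.approx(sp_in.amplitude[k], rel=0.10)

    def test_step_sine_plateau_and_10hz_preserved(self, chain, uir):
        ts = make_step_with_sine(1000.0, 60.0, 10.0, sine_amp=0.25)
        rec = simulate_recording(ts, chain)
        # deconvolution restores the flat plateau under the oscillation
        x = deconvolve(rec, uir)
        t = ts.times
        m = (t >= 20) & (t < 50)
        assert abs(np.polyfit(t[m], x.samples[m], 1)[0]) < 0.01
        assert np.corrcoef(ts.samples, x.samples)[0, 1] >= 0.99
        # and the 10 Hz oscillation is unaffected by the full pipeline
        recon = inverse_filter(rec, uir, force=True)
        sp_in = amplitude_spectrum(ts)
        sp_rc = amplitude_spectrum(recon)
        k = np.argmin(np.abs(sp_in.freqs_hz - 10.0))
        assert sp_rc.amplitude[k] == pytest.approx(sp_in.amplitude[k], rel=0.02)

    def test_allpass_chain_round_trip(self):
        from isarestore import FilterSpec, RecordingChain, characterize_uir, make_step

        rec_chain = RecordingChain(filters=(FilterSpec("allpass"),))
        step = simulate_recording(make_step(100.0, 30.0, 5.0), rec_chain)
        uir0 = characterize_uir(step, "measured_step")
        mix = make_mixed_sine(100.0, 700.0, freqs_hz=[0.05, 1.0])
        rec = simulate_recording(mix, rec_chain)
        recon = inverse_filter(rec, uir0)
        # differences only below/near the drift cutoff: check the components
        sp_in = amplitude_spectrum(mix)
        sp_rc = amplitude_spectrum(recon)
        for f in (0.05, 1.0):
            k = np.argmin(np.abs(sp_in.freqs_hz - f))
            assert sp_rc.amplitude[k] == pytest.approx(sp_in.amplitude[k], rel=0.02)

    def test_linearity(self, uir, chain):
        a, b = 1.5, -2.0
        x1 = make_mixed_sine(1000.0, 60.0, freqs_hz=[0.2, 1.0])
        x2 = make_mixed_sine(1000.0, 60.0, freqs_hz=[0.5, 3.0])
        y1 = simulate_recording(x1, chain)
        y2 = simulate_recording(x2, chain)
        y12 = y1.with_samples(a * y1.samples + b * y2.samples)
        lhs = inverse_filter(y12, uir, force=True).samples
        rhs = (a * inverse_filter(y1, uir, force=True).samples
               + b * inverse_filter(y2, uir, force=True).samples)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8 * np.abs(rhs).max())

    def test_phase_restored_at_every_component(self, mixed_loop):
        from isarestore import MIXED_SINE_FREQS_HZ

        mix, rec, recon = mixed_loop
        sp_in = amplitude_spectrum(mix)
        sp_rec = amplitude_spectrum(rec)
        sp_rc = amplitude_spectrum(recon)
        for f in MIXED_SINE_FREQS_HZ:
            k = np.argmin(np.abs(sp_in.freqs_hz - f))
            err_rec = abs(np.angle(np.exp(1j * (sp_rec.phase_rad[k] - sp_in.phase_rad[k]))))
            err_rc = abs(np.angle(np.exp(1j * (sp_rc.phase_rad[k] - sp_in.phase_rad[k]))))
            assert err_rc < err_rec

    def test_noise_robustness_at_unit_snr(self, uir, double_step, double_step_recorded):
        truth = downsample(double_step, 256.0)
        noisy = add_noise(double_step_recorded, NoiseSpec(1.0, seed=11))
        recon = downsample(inverse_filter(noisy, uir, force=True), 256.0)
        r = np.corrcoef(truth.samples, recon.samples)[0, 1]
        assert r >= 0.9

    def test_length_guard(self, uir, chain):
        short = simulate_recording(make_mixed_sine(1000.0, 30.0, freqs_hz=[1.0]), chain)
        with pytest.raises(TooShortError) as exc:
            inverse_filter(short, uir)
        assert exc.value.required_s == pytest.approx(600.0)
        assert "600" in str(exc.value)


class TestChunkedInverseFilter:
    def test_single_chunk_identical_to_whole(self, uir, chain):
        y = simulate_recording(make_mixed_sine(1000.0, 120.0, freqs_hz=[0.05, 1.0]), chain)
        cfg = InverseFilterConfig(chunk_len_s=200.0, chunk_overlap_s=40.0)
        whole = inverse_filter(y, uir, cfg, force=True)
        chunked = chunked_inverse_filter(y, uir, cfg, force=True)
        np.testing.assert_array_equal(chunked.samples, whole.samples)

    def test_interior_agreement_with_whole_signal(self, uir, chain):
        y = simulate_recording(make_mixed_sine(256.0, 1800.0), chain)
        cfg = InverseFilterConfig(chunk_len_s=600.0, chunk_overlap_s=120.0)
        uir256 = uir.resampled(256.0)
        whole = inverse_filter(y, uir256, cfg)
        chunked = chunked_inverse_filter(y, uir256, cfg)
        interior = slice(int(60 * 256), int(1740 * 256))
        rms_dev = np.sqrt(np.mean((chunked.samples[interior] - whole.samples[interior]) ** 2))
        rms_sig = np.sqrt(np.mean(whole.samples[interior] ** 2))
        assert rms_dev < 0.05 * rms_sig

    def test_non_overlapping_request_rejected(self, uir):
        y = TimeSeries(np.zeros(10000) + np.sin(np.arange(10000)), 100.0)
        cfg = InverseFilterConfig(chunk_len_s=30.0, chunk_overlap_s=0.0)
        with pytest.raises(DomainError):
            chunked_inverse_filter(y, uir, cfg, force=True)

    def test_too_small_overlap_rejected(self, uir):
        y = TimeSeries(np.sin(np.arange(100000) / 50), 1000.0)
        cfg = InverseFilterConfig(chunk_len_s=30.0, chunk_overlap_s=2.0)
        with pytest.raises(DomainError, match="three"):
            chunked_inverse_filter(y, uir, cfg, force=True)
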