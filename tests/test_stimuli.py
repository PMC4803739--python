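"""Stimulus synthesis: spectral content, decay profiles, IRN periodicity,
calibration and WAV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.io import wavfile

from pitchnet.stimuli import (
    StimulusSpec,
    Waveform,
    calibrate,
    harmonic_amplitudes,
    make_harmonic_complex,
    make_irn,
    make_training_set,
    read_wav,
    sample_random_tau,
    synthesize,
    write_wav,
)


def line_spectrum(w: Waveform, f0: float, n_max: int = 30) -> np.ndarray:
    """Magnitudes at the harmonic bins of a tone-aligned DFT.

    With duration an integer number of F0 periods each component falls on
    an exact bin, so line magnitudes are read off without leakage.
    """
    n = w.samples.size
    assert abs((f0 * n / w.sample_rate) % 1.0) < 1e-9, "window not tone-aligned"
    spec = np.abs(np.fft.rfft(w.samples)) * 2.0 / n
    bins = (np.arange(1, n_max + 1) * f0 * n / w.sample_rate).round().astype(int)
    return spec[bins]


class TestHarmonicComplex:
    @pytest.mark.parametrize(
        "kind,expected_lines",
        [
            ("pure", [1]),
            ("harmonic", list(range(1, 11))),
            ("missing_fundamental", list(range(2, 11))),
        ],
    )
    def test_spectral_line_content(self, kind, expected_lines):
        """Flat complexes put equal-magnitude lines exactly at the
        included harmonics of F0 and nothing elsewhere."""
        spec = StimulusSpec(kind=kind, f0=200.0)
        w = make_harmonic_complex(spec)
        mags = line_spectrum(w, 200.0)
        present = set(np.flatnonzero(mags > 1e-6) + 1)
        assert present == set(expected_lines)
        np.testing.assert_allclose(
            mags[[k - 1 for k in expected_lines]], 1.0, rtol=1e-9
        )

    @pytest.mark.parametrize("tau_mult", [1.0, 10 / 3, 5.0, 10.0])
    def test_decay_profile_fidelity(self, tau_mult):
        """Measured line magnitudes follow exp(-k*f0/tau) to 1e-6."""
        f0 = 250.0
        spec = StimulusSpec(kind="harmonic", f0=f0, tau=tau_mult * f0)
        w = make_harmonic_complex(spec)
        mags = line_spectrum(w, f0)[:10]
        expected = np.exp(-np.arange(1, 11) * f0 / (tau_mult * f0))
        np.testing.assert_allclose(mags, expected, rtol=1e-6)

    def test_adjacent_harmonic_ratio_at_tau_equal_f0(self):
        """tau = F0 attenuates each successive harmonic by exp(-1)."""
        amps = harmonic_amplitudes(StimulusSpec(kind="harmonic", f0=300.0, tau=300.0))
        np.testing.assert_allclose(amps[1:] / amps[:-1], np.exp(-1.0), rtol=1e-12)

    def test_nyquist_rejection(self):
        with pytest.raises(ValueError, match="Nyquist"):
            StimulusSpec(kind="harmonic", f0=3000.0, n_harmonics=10)

    def test_irn_kind_rejected(self):
        spec = StimulusSpec(kind="irn", f0=200.0, noise_seed=0)
        with pytest.raises(ValueError):
            make_harmonic_complex(spec)


def norm_autocorr(x: np.ndarray, lag: int) -> float:
    return float(np.dot(x[:-lag], x[lag:]) / np.dot(x, x))


class TestIRN:
    def test_zero_iterations_is_raw_noise(self):
        spec = StimulusSpec(kind="irn", f0=400.0, irn_iterations=0, noise_seed=7)
        w = make_irn(spec)
        ref = np.random.default_rng(7).standard_normal(spec.n_samples)
        np.testing.assert_array_equal(w.samples, ref)

    def test_determinism(self):
        spec = StimulusSpec(kind="irn", f0=250.0, noise_seed=11)
        np.testing.assert_array_equal(make_irn(spec).samples, make_irn(spec).samples)

    def test_periodicity_grows_with_iterations(self):
        """Autocorrelation at the delay lag is non-decreasing in the
        iteration count and clearly above the raw-noise value by 30."""
        lag = round(50_000 / 400)
        acs = []
        for n_iter in [0, 1, 2, 4, 8, 16, 30]:
            spec = StimulusSpec(
                kind="irn", f0=400.0, irn_iterations=n_iter, noise_seed=3
            )
            acs.append(norm_autocorr(make_irn(spec).samples, lag))
        assert all(b >= a - 1e-12 for a, b in zip(acs, acs[1:]))
        assert acs[-1] > acs[0] + 0.3

    def test_spectral_peaks_at_harmonics(self):
        """30 iterations carve spectral peaks at multiples of 1/delay."""
        spec = StimulusSpec(kind="irn", f0=400.0, irn_iterations=30, noise_seed=5)
        w = make_irn(spec)
        mag = np.abs(np.fft.rfft(w.samples))
        freqs = np.fft.rfftfreq(w.samples.size, 1 / w.sample_rate)
        for k in range(1, 6):
            band = (freqs > (k - 0.5) * 400) & (freqs < (k + 0.5) * 400)
            peak_f = freqs[band][np.argmax(mag[band])]
            assert abs(peak_f - k * 400) < 40, f"harmonic {k} peak at {peak_f}"

    def test_sub_sample_delay_rejected(self):
        spec = StimulusSpec(kind="irn", f0=200.0, noise_seed=0, sample_rate=50_000.0)
        bad = StimulusSpec(
            kind="irn", f0=120_000.0, noise_seed=0, sample_rate=50_000.0
        )
        make_irn(spec)
        with pytest.raises(ValueError, match="shorter than one sample"):
            make_irn(bad)


class TestCalibration:
    def test_rms_matches_level(self):
        """50 dB SPL -> central-portion RMS of 20 uPa * 10^(50/20)."""
        spec = StimulusSpec(kind="harmonic", f0=200.0)
        w = calibrate(make_harmonic_complex(spec), 50.0, ramp=0.01)
        n_ramp = round(0.01 * w.sample_rate)
        core = w.samples[n_ramp:-n_ramp]
        target = 20e-6 * 10 ** (50 / 20)
        assert np.sqrt(np.mean(core**2)) == pytest.approx(target, rel=1e-9)

    def test_zero_ramp_identity_envelope(self):
        spec = StimulusSpec(kind="pure", f0=500.0, ramp=0.0)
        raw = make_harmonic_complex(spec)
        cal = calibrate(raw, 50.0, ramp=0.0)
        scale = cal.samples[1000] / raw.samples[1000]
        np.testing.assert_allclose(cal.samples, raw.samples * scale, rtol=1e-12)

    def test_ramp_endpoints_zero(self):
        spec = StimulusSpec(kind="harmonic", f0=200.0)
        w = synthesize(spec)
        assert w.samples[0] == 0.0 and w.samples[-1] == 0.0

    def test_silence_rejected(self):
        silent = Waveform(np.zeros(1000), 50_000.0)
        with pytest.raises(ValueError, match="silent"):
            calibrate(silent, 50.0, 0.0)


class TestTrainingSet:
    @pytest.mark.parametrize(
        "lo,hi,step,expected", [(200, 600, 20, 21), (200, 200, 20, 1), (200, 600, 50, 9)]
    )
    def test_grid_cardinality(self, lo, hi, step, expected):
        assert len(make_training_set(lo, hi, step, "flat")) == expected

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            make_training_set(600, 200, 20, "flat")

    def test_profile_scales_with_f0(self):
        specs = make_training_set(200, 600, 20, 10 / 3)
        assert all(s.tau == pytest.approx(10 / 3 * s.f0) for s in specs)
        assert all(s.tau is None for s in make_training_set(200, 400, 100, "flat"))


class TestRandomTau:
    def test_bounds_and_reproducibility(self):
        rng = np.random.default_rng(0)
        taus = np.array([sample_random_tau(300.0, rng) for _ in range(2000)])
        assert np.all(taus >= 300.0) and np.all(taus <= 300.0 * np.e**10)
        rng2 = np.random.default_rng(0)
        taus2 = np.array([sample_random_tau(300.0, rng2) for _ in range(2000)])
        np.testing.assert_array_equal(taus, taus2)

    def test_log_ratio_uniform(self):
        """log(tau/f0) is uniform on [0, 10] (KS test, alpha = 0.01)."""
        from scipy import stats

        rng = np.random.default_rng(42)
        x = np.log([sample_random_tau(200.0, rng) / 200.0 for _ in range(10_000)])
        assert stats.kstest(x / 10.0, "uniform").pvalue > 0.01


class TestWavRoundTrip:
    def test_float32_bit_exact(self, tmp_path):
        spec = StimulusSpec(kind="harmonic", f0=220.0, duration=0.05)
        w = synthesize(spec)
        path = tmp_path / "stim.wav"
        write_wav(Waveform(w.samples.astype(np.float32), w.sample_rate), path)
        back = read_wav(path)
        np.testing.assert_array_equal(
            back.samples, w.samples.astype(np.float32).astype(np.float64)
        )
        assert back.sample_rate == w.sample_rate

    def test_pcm16_within_quantization(self, tmp_path):
        rng = np.random.default_rng(1)
        w = Waveform(rng.uniform(-0.9, 0.9, 4000), 44_100.0)
        path = tmp_path / "q.wav"
        write_wav(w, path, subtype="pcm16")
        back = read_wav(path)
        assert np.max(np.abs(back.samples - w.samples)) <= 1.0 / 32767

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises((FileNotFoundError, OSError)):
            read_wav(tmp_path / "nope.wav")

    def test_multichannel_rejected(self, tmp_path):
        path = tmp_path / "stereo.wav"
        wavfile.write(path, 44_100, np.zeros((100, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="mono"):
            read_wav(path)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    f0=st.floats(100.0, 1000.0),
    n_harm=st.integers(2, 12),
    tau_mult=st.one_of(st.none(), st.floats(0.5, 20.0)),
)
def test_spectral_line_count_property(f0, n_harm, tau_mult):
    """Any harmonic spec yields exactly n_harmonics lines; the MF variant
    n_harmonics - 1 with nothing at F0 (tone-aligned DFT)."""
    fs = 50_000.0
    # snap f0 onto the DFT grid: an integer number of periods must fit an
    # integer number of samples, else bin leakage fakes extra lines
    periods = max(1, round(0.02 * f0))
    n_samples = round(periods * fs / f0)
    f0 = periods * fs / n_samples
    if 2 * n_harm * f0 >= fs:
        return
    duration = n_samples / fs
    for kind, expected in [("harmonic", n_harm), ("missing_fundamental", n_harm - 1)]:
        spec = StimulusSpec(
            kind=kind, f0=f0, n_harmonics=n_harm,
            tau=None if tau_mult is None else tau_mult * f0,
            duration=duration, ramp=0.0, sample_rate=fs,
        )
        w = make_harmonic_complex(spec)
        n = w.samples.size
        mag = np.abs(np.fft.rfft(w.samples)) * 2 / n
        floor = max(mag.max() * 1e-7, 1e-12)
        n_lines = int(np.sum(mag > floor))
        assert n_lines == expected
        f0_bin = round(f0 * n / fs)
        if kind == "missing_fundamental":
            assert mag[f0_bin] <= floor
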