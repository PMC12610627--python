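"""EEG pipeline: filtering, Welch band power, and the tanh trust mapping."""
import numpy as np
import pytest
from scipy import stats

from trustfuse import eeg
from trustfuse.errors import DegenerateInputError, InvalidArgumentError, InvalidSamplingRateError
from trustfuse.synthetic import ArtifactConfig, simulate_eeg_recording, simulate_latent_trajectory
from trustfuse.types import EEGRecording, Event, EventTimeline

FS = 500.0


def _rec(x, fs=FS, rest=10.0):
    return EEGRecording(np.asarray(x, dtype=float), fs=fs, rest_end_s=rest)


def _sine(freq, dur_s, fs=FS, amp=1.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def fft_amplitude(x, freq, fs=FS):
    spec = np.fft.rfft(x)
    k = int(round(freq * x.size / fs))
    return 2.0 * np.abs(spec[k]) / x.size


class TestPreprocess:
    def test_passband_preserves_alpha_sinusoid(self):
        x = _sine(10.0, 10.0)
        out = eeg.preprocess(_rec(x)).samples
        assert fft_amplitude(out, 10.0) == pytest.approx(1.0, rel=0.05)

    def test_stopband_rejects_slow_drift(self):
        x = _sine(0.2, 20.0)
        out = eeg.preprocess(_rec(x)).samples
        assert np.sqrt(np.mean(out**2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_zero_in_zero_out(self):
        out = eeg.preprocess(_rec(np.zeros(5000))).samples
        np.testing.assert_array_equal(out, np.zeros(5000))

    def test_preserves_length_and_fs(self):
        rec = _rec(np.random.default_rng(0).standard_normal(4096))
        out = eeg.preprocess(rec)
        assert out.samples.size == 4096 and out.fs == rec.fs

    def test_rejects_undersampled_recording(self):
        with pytest.raises(InvalidSamplingRateError):
            eeg.preprocess(_rec(np.zeros(500), fs=80.0))


class TestBandDecompose:
    @pytest.mark.parametrize(
        "freq,dominant,quiet",
        [(10.0, "alpha", "beta"), (20.0, "beta", "alpha")],
    )
    def test_sinusoid_lands_in_its_band(self, freq, dominant, quiet):
        bands = eeg.band_decompose(_rec(_sine(freq, 12.0)))
        assert np.var(bands[dominant]) >= 50.0 * np.var(bands[quiet])

    def test_zero_input_gives_five_zero_outputs(self):
        bands = eeg.band_decompose(_rec(np.zeros(6000)))
        assert set(bands) == {"delta", "theta", "alpha", "beta", "gamma"}
        for arr in bands.values():
            np.testing.assert_allclose(arr, 0.0, atol=1e-12)


class TestWelchBandPower:
    def test_zero_signal_zero_power(self):
        assert eeg.welch_band_power(np.zeros(2000), FS, (8, 13)) == 0.0

    def test_unit_sine_power_is_half(self):
        # variance of a unit-amplitude sinusoid is 1/2
        p = eeg.welch_band_power(_sine(10.0, 4.0), FS, (8, 13))
        assert p == pytest.approx(0.5, rel=0.05)

    def test_white_noise_band_fraction(self):
        x = np.random.default_rng(3).standard_normal(int(120 * FS))
        frac = eeg.welch_band_power(x, FS, (8, 13)) / np.var(x)
        assert frac == pytest.approx(5.0 / 250.0, rel=0.15)

    def test_matches_direct_hann_periodogram(self):
        # independent oracle: single periodic-Hann periodogram from the DFT
        x = np.random.default_rng(7).standard_normal(750)  # 1.5 s: one segment
        n = x.size
        xd = x - x.mean()
        w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)
        psd = (np.abs(np.fft.rfft(w * xd)) ** 2) / (FS * np.sum(w**2))
        psd[1:] *= 2.0
        if n % 2 == 0:
            psd[-1] /= 2.0
        freqs = np.fft.rfftfreq(n, 1.0 / FS)
        mask = (freqs >= 8) & (freqs <= 13)
        expected = np.trapezoid(psd[mask], freqs[mask])
        got = eeg.welch_band_power(x, FS, (8, 13))
        assert abs(got - expected) / expected < 1e-10

    def test_rejects_empty_segment(self):
        with pytest.raises(InvalidArgumentError):
            eeg.welch_band_power(np.array([]), FS, (8, 13))


class TestTrustMapping:
    def test_z_zero_maps_to_scale_midpoint(self):
        assert eeg.trust_score_from_z(0.0) == 5.0

    def test_unit_z_values(self):
        assert eeg.trust_score_from_z(1.0) == pytest.approx(6.9040, abs=5e-5)
        assert eeg.trust_score_from_z(-1.0) == pytest.approx(3.0960, abs=5e-5)

    def test_saturation_limits_never_attained(self):
        big = eeg.trust_score_from_z(np.array([-50.0, 50.0]))
        assert big[0] == pytest.approx(2.5, abs=1e-9) and big[0] > 2.5 - 1e-6
        assert big[1] == pytest.approx(7.5, abs=1e-9)

    def test_strictly_increasing_in_ratio(self, rng):
        z = np.sort(rng.normal(size=50))
        assert np.all(np.diff(eeg.trust_score_from_z(z)) > 0)


@pytest.fixture(scope="module")
def session():
    prof = simulate_latent_trajectory(8, 0.5, seed=17)
    return prof, *simulate_eeg_recording(prof, ArtifactConfig(), seed=18)


class TestComputeTrustCurve:
    def test_z_scores_standardized(self, session):
        _, rec, tl = session
        curve = eeg.compute_trust_curve(rec, tl)
        z = np.arctanh((curve.scores() - 5.0) / 2.5)
        assert abs(z.mean()) < 1e-9
        assert abs(np.std(z, ddof=1) - 1.0) < 1e-9

    def test_scores_inside_open_interval(self, session):
        _, rec, tl = session
        s = eeg.compute_trust_curve(rec, tl).scores()
        assert np.all((s > 2.5) & (s < 7.5))

    def test_stores_standardization_and_baseline(self, session):
        _, rec, tl = session
        curve = eeg.compute_trust_curve(rec, tl)
        assert curve.standardization["sigma"] > 0
        assert curve.baseline_ratio is not None and curve.baseline_ratio > 0

    def test_score_order_matches_ratio_order(self, session):
        # monotonicity: higher epoch ratio => higher score
        _, rec, tl = session
        curve = eeg.compute_trust_curve(rec, tl)
        fs = rec.fs
        pre = eeg.preprocess(rec)
        ratios = [
            eeg.band_power_epoch(
                pre.samples[int((e.t_start_s - 1) * fs) : int((e.t_start_s + 2) * fs)], fs
            ).ratio
            for e in tl.events
        ]
        assert np.array_equal(np.argsort(ratios), np.argsort(curve.scores()))

    def test_epoch_outside_recording_skipped_with_warning(self, session):
        _, rec, tl = session
        events = tl.events + [Event("late", rec.duration_s + 5.0)]
        with pytest.warns(UserWarning, match="skipped"):
            curve = eeg.compute_trust_curve(rec, EventTimeline(events))
        assert curve.skipped_events == ["late"]
        assert len(curve.points) == len(tl)

    def test_needs_two_events(self, session):
        _, rec, tl = session
        with pytest.raises(InvalidArgumentError):
            eeg.compute_trust_curve(rec, EventTimeline(tl.events[:1]))

    def test_identical_epochs_raise_degenerate(self):
        # tiled task block => bit-identical epochs => sigma = 0
        rng = np.random.default_rng(0)
        fs = 500
        block = rng.standard_normal(3 * fs)
        samples = np.concatenate([rng.standard_normal(10 * fs), np.tile(block, 4)])
        tl = EventTimeline([Event(f"E{k}", 11.0 + 3 * k) for k in range(4)])
        with pytest.raises(DegenerateInputError):
            eeg.compute_trust_curve(EEGRecording(samples, fs=fs), tl, apply_preprocessing=False)

    def test_preprocessing_reduces_artifact_impact(self):
        # same underlying neural signal, with and without heavy EMG/motion;
        # cleaning should shrink the artifact-induced score change
        heavy = ArtifactConfig(emg_burst_rate=20, emg_amplitude=25, motion_rate=6,
                               motion_amplitude=60, noise_sd=0)
        d_pre, d_raw = [], []
        for seed in range(6):
            prof = simulate_latent_trajectory(8, 0.5, seed)
            clean, tl = simulate_eeg_recording(prof, ArtifactConfig.none(), seed=seed + 100,
                                               background_sd=1.0)
            dirty, _ = simulate_eeg_recording(prof, heavy, seed=seed + 100, background_sd=1.0)
            for pre, store in ((True, d_pre), (False, d_raw)):
                c1 = eeg.compute_trust_curve(clean, tl, apply_preprocessing=pre)
                c2 = eeg.compute_trust_curve(dirty, tl, apply_preprocessing=pre)
                store.append(np.mean(np.abs(c1.scores() - c2.scores())))
        assert np.mean(d_pre) < np.mean(d_raw)
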