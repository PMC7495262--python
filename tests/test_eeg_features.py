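"""Band power/amplitude, theta/beta ratio, artifact rejection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from affectlab.eeg_features import (
    ALPHA,
    BETA,
    THETA,
    FeatureConfig,
    band_amplitude,
    band_power,
    extract_segment_features,
    reject_artifacts,
    theta_beta_ratio,
)
from affectlab.errors import ConfigurationError, UndefinedFeatureError
from affectlab.signal_io import BiosignalStream
from affectlab.synthetic_data import SegmentSpec, SynthConfig, generate_eeg

RATE = 256.0


def sinusoid(freq_hz, peak_uv, duration_s=8.0, rate=RATE):
    t = np.arange(int(duration_s * rate)) / rate
    return peak_uv * np.sin(2 * np.pi * freq_hz * t)


def eeg_stream(samples, start=0.0):
    return BiosignalStream("EEG", "Cz", RATE, start, samples)


class TestBandPower:
    def test_sinusoid_closed_form(self):
        """10 Hz sinusoid, peak A: alpha power = A^2/2, amplitude = A/sqrt(2)."""
        x = sinusoid(10.0, 10.0)
        assert band_power([x], ALPHA, RATE) == pytest.approx(50.0, rel=0.02)
        assert band_amplitude([x], ALPHA, RATE) == pytest.approx(10.0 / math.sqrt(2), rel=0.02)

    def test_out_of_band_rejection(self):
        x = sinusoid(10.0, 10.0)
        alpha = band_power([x], ALPHA, RATE)
        assert band_power([x], THETA, RATE) < 0.01 * alpha
        assert band_power([x], BETA, RATE) < 0.01 * alpha

    def test_zero_signal_zero_amplitude(self):
        assert band_amplitude([np.zeros(2048)], ALPHA, RATE) == 0.0

    def test_noise_carrier_matches_time_domain_mean_square(self):
        """Generator carrier with RMS 4 uV: Welch-integrated theta power must
        agree with the time-domain mean square of the noiseless component."""
        cfg = SynthConfig(
            duration_s=90.0,
            segments=(SegmentSpec(0, 90, theta_amp=4.0),),
            seed=2,
        )
        eeg, _ = generate_eeg(cfg)
        truth = float(np.mean(eeg.samples**2))  # noiseless: signal is the carrier
        assert truth == pytest.approx(16.0, abs=1e-9)
        assert band_power(eeg.samples, THETA, RATE) == pytest.approx(truth, rel=0.05)

    def test_no_epochs_is_undefined_feature(self):
        with pytest.raises(UndefinedFeatureError):
            band_power([], THETA, RATE)

    def test_peak_equivalent_convention(self):
        x = sinusoid(10.0, 10.0)
        rms = band_amplitude([x], ALPHA, RATE, convention="rms")
        peak = band_amplitude([x], ALPHA, RATE, convention="peak_equivalent")
        assert peak == pytest.approx(rms * math.sqrt(2))


class TestThetaBetaRatio:
    def test_composite_sinusoids(self):
        # theta RMS 4 + beta RMS 2 -> power 16/4 = 4.0
        x = sinusoid(6.0, 4 * math.sqrt(2)) + sinusoid(17.0, 2 * math.sqrt(2))
        assert theta_beta_ratio([x], RATE) == pytest.approx(4.0, rel=0.02)

    def test_equal_power_gives_unity(self):
        x = sinusoid(6.0, 5.0) + sinusoid(17.0, 5.0)
        assert theta_beta_ratio([x], RATE) == pytest.approx(1.0, rel=0.02)

    def test_doubling_theta_quadruples_ratio(self):
        x1 = sinusoid(6.0, 4.0) + sinusoid(17.0, 4.0)
        x2 = sinusoid(6.0, 8.0) + sinusoid(17.0, 4.0)
        r1, r2 = theta_beta_ratio([x1], RATE), theta_beta_ratio([x2], RATE)
        assert r2 / r1 == pytest.approx(4.0, rel=0.02)

    def test_ratio_monotone_in_theta_amplitude(self):
        ratios = [
            theta_beta_ratio([sinusoid(6.0, a) + sinusoid(17.0, 4.0)], RATE)
            for a in (2.0, 4.0, 6.0, 8.0)
        ]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_zero_beta_is_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            theta_beta_ratio([sinusoid(6.0, 4.0)], RATE)

    @given(c=st.floats(0.1, 50.0))
    def test_scale_equivariance(self, c):
        """Scaling the signal by c scales powers by c^2, amplitudes by |c|,
        and leaves the theta/beta ratio invariant."""
        x = sinusoid(6.0, 4.0) + sinusoid(10.0, 6.0) + sinusoid(17.0, 2.0)
        p1, p2 = band_power([x], ALPHA, RATE), band_power([c * x], ALPHA, RATE)
        assert p2 == pytest.approx(c**2 * p1, rel=1e-9)
        a1, a2 = band_amplitude([x], ALPHA, RATE), band_amplitude([c * x], ALPHA, RATE)
        assert a2 == pytest.approx(abs(c) * a1, rel=1e-9)
        assert theta_beta_ratio([c * x], RATE) == pytest.approx(
            theta_beta_ratio([x], RATE), rel=1e-9
        )


class TestArtifactRejection:
    def test_clean_signal_no_rejection(self):
        x = sinusoid(10.0, 50.0, duration_s=10.0)
        clean, rejected = reject_artifacts(eeg_stream(x), 1.0, 100.0)
        assert not rejected.any() and len(clean) == 10

    def test_exactly_contaminated_epochs_rejected(self):
        """Rejected epochs are exactly those holding a |sample| > threshold,
        verified by a brute-force scan against the generator's artifact
        ground truth."""
        cfg = SynthConfig(
            duration_s=60.0,
            segments=(SegmentSpec(0, 60, alpha_amp=8.0),),
            seed=6,
            artifact_rate=3.0,
        )
        eeg, artifacts = generate_eeg(cfg)
        assert len(artifacts) == 3
        clean, rejected = reject_artifacts(eeg, 1.0, 100.0)
        n_per = 256
        expected = np.array(
            [
                np.any(np.abs(eeg.samples[i * n_per : (i + 1) * n_per]) > 100.0)
                for i in range(len(rejected))
            ]
        )
        np.testing.assert_array_equal(rejected, expected)
        assert expected.any()  # the transients really contaminate epochs
        # every artifact lands inside a rejected epoch
        for onset, width in artifacts:
            assert rejected[int(onset) : int(math.ceil(onset + width)) + 1].any()

    def test_zero_threshold_is_error(self):
        with pytest.raises(ConfigurationError):
            reject_artifacts(eeg_stream(np.zeros(512)), 1.0, 0.0)

    def test_short_segment_single_truncated_epoch(self):
        clean, rejected = reject_artifacts(eeg_stream(np.zeros(100)), 1.0, 100.0)
        assert len(rejected) == 1 and len(clean[0]) == 100

    def test_all_rejected_flags_segment(self):
        x = np.full(2048, 500.0)
        with pytest.raises(UndefinedFeatureError):
            extract_segment_features(eeg_stream(x))

    def test_rejection_robustness_under_contamination(self):
        """Features from a contaminated stream stay within 5% of the same
        stream without artifacts (identical carrier realization)."""
        segs = (SegmentSpec(0, 240, theta_amp=4, alpha_amp=8, beta_amp=2),)
        base = dict(duration_s=240.0, segments=segs, seed=3, noise_scale=0.5)
        clean_eeg, _ = generate_eeg(SynthConfig(artifact_rate=0.0, **base))
        dirty_eeg, arts = generate_eeg(SynthConfig(artifact_rate=2.0, **base))
        assert len(arts) == 8
        f_clean = extract_segment_features(clean_eeg)
        f_dirty = extract_segment_features(dirty_eeg)
        assert f_dirty.n_epochs_rejected > 0
        assert f_dirty.alpha_amp == pytest.approx(f_clean.alpha_amp, rel=0.05)
        assert f_dirty.theta_beta_ratio == pytest.approx(
            f_clean.theta_beta_ratio, rel=0.05
        )
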