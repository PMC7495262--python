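"""Generator contracts: determinism, ground-truth fidelity, band purity."""

import math

import numpy as np
import pytest
from scipy.signal import find_peaks

from affectlab.eeg_features import (
    ALPHA,
    BETA,
    THETA,
    band_power,
    extract_segment_features,
)
from affectlab.errors import ConfigurationError
from affectlab.signal_io import slice_stream
from affectlab.synthetic_data import (
    STREAM_STAGGER_S,
    SegmentSpec,
    SynthConfig,
    generate_eda,
    generate_eeg,
    generate_hr,
    generate_session,
)


def one_segment(duration=60.0, **kw):
    return (SegmentSpec(0.0, duration, **kw),)


class TestConfigValidation:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            SynthConfig(
                duration_s=20.0,
                segments=(SegmentSpec(0, 15), SegmentSpec(10, 20)),
            )

    def test_gap_and_wrong_span_rejected(self):
        with pytest.raises(ConfigurationError, match="gap"):
            SynthConfig(
                duration_s=20.0, segments=(SegmentSpec(0, 5), SegmentSpec(10, 20))
            )
        with pytest.raises(ConfigurationError, match="end at duration"):
            SynthConfig(duration_s=30.0, segments=(SegmentSpec(0, 20),))

    def test_physiological_bounds(self):
        with pytest.raises(ConfigurationError):
            SegmentSpec(0, 10, hr_level=250)
        with pytest.raises(ConfigurationError):
            SegmentSpec(0, 10, eda_tonic=-1.0)


class TestDeterminism:
    def test_same_seed_same_samples_all_modalities(self):
        cfg = SynthConfig(
            duration_s=30.0,
            segments=one_segment(30.0, theta_amp=4, alpha_amp=8, beta_amp=2, scr_count=2),
            seed=7,
            noise_scale=1.0,
            artifact_rate=2.0,
        )
        for gen in (generate_eda, generate_hr):
            np.testing.assert_array_equal(gen(cfg).samples, gen(cfg).samples)
        (e1, a1), (e2, a2) = generate_eeg(cfg), generate_eeg(cfg)
        np.testing.assert_array_equal(e1.samples, e2.samples)
        np.testing.assert_array_equal(a1, a2)

    def test_different_seed_differs(self):
        base = dict(
            duration_s=30.0, segments=one_segment(30.0, alpha_amp=8), noise_scale=1.0
        )
        x1, _ = generate_eeg(SynthConfig(seed=1, **base))
        x2, _ = generate_eeg(SynthConfig(seed=2, **base))
        assert not np.array_equal(x1.samples, x2.samples)


class TestEEG:
    def test_pure_alpha_sinusoid_band_purity(self):
        """A lone alpha oscillation puts <1% of its RMS in theta or beta."""
        cfg = SynthConfig(
            duration_s=60.0,
            segments=one_segment(60.0, alpha_amp=10.0),
            carrier="sinusoid",
            seed=0,
        )
        eeg, _ = generate_eeg(cfg)
        alpha_rms = math.sqrt(band_power(eeg.samples, ALPHA, 256.0))
        assert alpha_rms == pytest.approx(10.0, rel=0.02)
        for band in (THETA, BETA):
            assert math.sqrt(band_power(eeg.samples, band, 256.0)) < 0.01 * alpha_rms

    def test_noise_carrier_band_leakage_bounded(self):
        """Noise carriers are spectrally confined: cross-band RMS stays under
        2% even for theta/alpha, which share the 8 Hz edge."""
        cfg = SynthConfig(
            duration_s=60.0, segments=one_segment(60.0, theta_amp=10.0), seed=3
        )
        eeg, _ = generate_eeg(cfg)
        theta_rms = math.sqrt(band_power(eeg.samples, THETA, 256.0))
        assert theta_rms == pytest.approx(10.0, rel=0.05)
        assert math.sqrt(band_power(eeg.samples, ALPHA, 256.0)) < 0.02 * theta_rms
        assert math.sqrt(band_power(eeg.samples, BETA, 256.0)) < 0.01 * theta_rms

    def test_theta_beta_composite_gives_ratio_four(self):
        cfg = SynthConfig(
            duration_s=180.0,
            segments=one_segment(180.0, theta_amp=4.0, beta_amp=2.0),
            seed=1,
        )
        eeg, _ = generate_eeg(cfg)
        feats = extract_segment_features(eeg)
        assert feats.theta_beta_ratio == pytest.approx(4.0, rel=0.05)

    def test_artifact_ground_truth_matches_injected_transients(self):
        cfg = SynthConfig(
            duration_s=120.0,
            segments=one_segment(120.0, alpha_amp=8.0),
            seed=4,
            artifact_rate=3.0,
        )
        eeg, artifacts = generate_eeg(cfg)
        assert len(artifacts) == 6  # 3/min for 2 min
        for onset, width in artifacts:
            assert 0.2 <= width <= 0.5
            lo = int(onset * 256)
            hi = int((onset + width) * 256)
            assert np.max(np.abs(eeg.samples[lo:hi])) > 100.0

    def test_parameter_recovery_within_five_percent(self):
        """noise at 10% of band RMS, no artifacts: every per-segment band RMS
        comes back within 5% through the full feature path."""
        segs = (
            SegmentSpec(0, 90, theta_amp=4, alpha_amp=8, beta_amp=2),
            SegmentSpec(90, 180, theta_amp=5, alpha_amp=6, beta_amp=2.5),
        )
        cfg = SynthConfig(duration_s=180.0, segments=segs, seed=11, noise_scale=0.2)
        eeg, _ = generate_eeg(cfg)
        for seg in segs:
            feats = extract_segment_features(slice_stream(eeg, seg.start_s, seg.end_s))
            assert math.sqrt(feats.theta_power) == pytest.approx(seg.theta_amp, rel=0.05)
            assert feats.alpha_amp == pytest.approx(seg.alpha_amp, rel=0.05)
            assert math.sqrt(feats.beta_power) == pytest.approx(seg.beta_amp, rel=0.05)


class TestEDA:
    def test_constant_tonic_without_phasics(self):
        cfg = SynthConfig(duration_s=30.0, segments=one_segment(30.0, eda_tonic=2.0))
        np.testing.assert_allclose(generate_eda(cfg).samples, 2.0)

    def test_scr_count_recoverable_as_local_maxima(self):
        cfg = SynthConfig(
            duration_s=60.0,
            segments=one_segment(60.0, eda_tonic=1.0, scr_count=3),
            seed=5,
        )
        x = generate_eda(cfg).samples
        peaks, _ = find_peaks(x, height=1.02)
        assert len(peaks) == 3

    def test_two_tonic_levels_ordered(self):
        cfg = SynthConfig(
            duration_s=120.0,
            segments=(
                SegmentSpec(0, 60, eda_tonic=1.0),
                SegmentSpec(60, 120, eda_tonic=5.0),
            ),
        )
        x = generate_eda(cfg).samples
        assert x[:240].mean() == pytest.approx(1.0, abs=0.3)
        assert x[240:].mean() == pytest.approx(5.0, abs=0.3)

    def test_non_negative_even_at_zero_tonic(self):
        cfg = SynthConfig(
            duration_s=60.0, segments=one_segment(60.0, eda_tonic=0.0, scr_count=2), seed=9
        )
        assert np.all(generate_eda(cfg).samples >= 0.0)


class TestHR:
    def test_constant_when_jitter_and_drift_disabled(self):
        cfg = SynthConfig(
            duration_s=60.0,
            segments=one_segment(60.0, hr_level=80),
            hr_jitter_sd=0.0,
            hr_drift_amp=0.0,
        )
        np.testing.assert_array_equal(generate_hr(cfg).samples, 80.0)

    def test_default_segment_mean_close_to_level(self):
        cfg = SynthConfig(duration_s=300.0, segments=one_segment(300.0, hr_level=80), seed=0)
        assert generate_hr(cfg).samples.mean() == pytest.approx(80.0, abs=1.0)

    def test_segment_levels_ordered_and_clamped(self):
        cfg = SynthConfig(
            duration_s=120.0,
            segments=(
                SegmentSpec(0, 60, hr_level=70),
                SegmentSpec(60, 120, hr_level=90),
            ),
            seed=1,
        )
        x = generate_hr(cfg).samples
        assert x[:60].mean() < x[60:].mean()
        lo = SynthConfig(
            duration_s=120.0,
            segments=one_segment(120.0, hr_level=30),
            seed=2,
            hr_jitter_sd=10.0,
        )
        assert np.all(generate_hr(lo).samples >= 30.0)


class TestSession:
    def test_internal_boundaries_become_annotations(self, small_session):
        events = [a for a in small_session.recording.annotations if a.kind == "node_transition"]
        assert len(events) == 2  # 3 segments -> 2 internal boundaries
        markers = {a.kind for a in small_session.recording.annotations}
        assert {"session_start", "session_end"} <= markers

    def test_streams_staggered_on_shared_clock(self, small_session):
        rec = small_session.recording
        t_eeg = rec.get_stream("EEG").start_utc
        assert rec.get_stream("EDA").start_utc - t_eeg == pytest.approx(
            STREAM_STAGGER_S["EDA"], abs=1e-6
        )
        assert rec.get_stream("HR").start_utc - t_eeg == pytest.approx(
            STREAM_STAGGER_S["HR"], abs=1e-6
        )

    def test_ground_truth_table_matches_config(self, small_session):
        gt = small_session.ground_truth
        assert list(gt["segment"]) == [1, 2, 3]
        assert list(gt["hr_level"]) == [80, 82, 81]
        assert gt["end_utc"].iloc[-1] - gt["start_utc"].iloc[0] == pytest.approx(180.0)
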