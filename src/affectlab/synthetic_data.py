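"""Synthetic multimodal recordings with known ground truth.

Emulates the recording rig — a 256 Hz EEG amplifier at Cz plus a wrist
wearable sampling heart rate at 1 Hz and electrodermal activity at 4 Hz —
well enough that every downstream stage (spectral features, artifact
rejection, segmentation, cohort aggregation) has a parameter-recovery test
surface.  It is a stated world, not a physiological simulator: EEG is
band-limited oscillations over 1/f background noise, EDA is a tonic level
plus bi-exponential phasic responses, HR is a level with Gaussian jitter and
slow drift.  See ``docs/methods.md`` for what this does and does not emulate.

All randomness flows from one seed through named substreams per modality, so
regenerating a single modality is reproducible independently of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .signal_io import (
    BiosignalStream,
    EventAnnotation,
    SessionRecording,
)

__all__ = [
    "SegmentSpec",
    "SynthConfig",
    "SyntheticSession",
    "BAND_EDGES",
    "BAND_CENTERS",
    "STREAM_STAGGER_S",
    "generate_eeg",
    "generate_eda",
    "generate_hr",
    "generate_session",
    "synth_config_from_dict",
]

#: Analysis bands of the rig: theta 4-8 Hz, alpha 8-12 Hz, beta 13-21 Hz.
BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (13.0, 21.0)}
BAND_CENTERS = {"theta": 6.0, "alpha": 10.0, "beta": 17.0}

#: Fixed start offsets (s) of each stream relative to session start.  Chosen
#: deliberately non-zero and non-commensurate with the sample grids so that
#: naive index alignment fails in tests; only UTC arithmetic lines them up.
STREAM_STAGGER_S = {"EEG": 0.0, "EDA": 0.5, "HR": 1.2}

_SCR_TAU_RISE_S = 1.0
_SCR_TAU_DECAY_S = 4.0


@dataclass(frozen=True)
class SegmentSpec:
    """Ground truth for one scenario segment.

    Band amplitudes are the RMS (uV) of each band-limited oscillation;
    ``hr_level`` is the mean heart rate (bpm); ``eda_tonic`` the tonic skin
    conductance level (uS); ``scr_count`` the number of phasic
    skin-conductance responses injected into the segment.
    """

    start_s: float
    end_s: float
    theta_amp: float = 0.0
    alpha_amp: float = 0.0
    beta_amp: float = 0.0
    hr_level: float = 70.0
    eda_tonic: float = 1.0
    scr_count: int = 0

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ConfigurationError("segment must have start_s < end_s")
        for name in ("theta_amp", "alpha_amp", "beta_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 30.0 <= self.hr_level <= 220.0:
            raise ConfigurationError("hr_level must lie in [30, 220] bpm")
        if self.eda_tonic < 0:
            raise ConfigurationError("eda_tonic must be >= 0")
        if self.scr_count < 0:
            raise ConfigurationError("scr_count must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic recording session.

    ``segments`` must tile ``[0, duration_s)`` contiguously without overlap.
    ``carrier`` selects how band oscillations are synthesized: band-pass
    filtered white noise rescaled to the target RMS (default, exercises PSD
    integration over the whole band) or a pure sinusoid at the band center
    (analytic oracle mode).
    """

    duration_s: float
    segments: tuple[SegmentSpec, ...]
    seed: int = 0
    eeg_rate: float = 256.0
    hr_rate: float = 1.0
    eda_rate: float = 4.0
    artifact_rate: float = 0.0  # artifacts / minute
    noise_scale: float = 0.0  # 1/f background RMS, uV
    carrier: str = "noise"  # "noise" | "sinusoid"
    hr_jitter_sd: float = 2.0  # bpm
    hr_drift_amp: float = 1.0  # bpm
    hr_drift_period_s: float = 120.0
    eda_ramp_s: float = 2.0  # tonic transition length at boundaries

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigurationError("duration_s must be > 0")
        for name in ("eeg_rate", "hr_rate", "eda_rate"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.artifact_rate < 0 or self.noise_scale < 0:
            raise ConfigurationError("artifact_rate and noise_scale must be >= 0")
        if self.carrier not in ("noise", "sinusoid"):
            raise ConfigurationError(f"unknown carrier {self.carrier!r}")
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ConfigurationError("at least one segment is required")
        segs = sorted(self.segments, key=lambda s: s.start_s)
        tol = 1e-9
        if abs(segs[0].start_s) > tol:
            raise ConfigurationError("segments must start at 0")
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s - tol:
                raise ConfigurationError("segment specs overlap")
            if b.start_s > a.end_s + tol:
                raise ConfigurationError("segments must tile the session without gaps")
        if abs(segs[-1].end_s - self.duration_s) > tol:
            raise ConfigurationError("segments must end at duration_s")
        object.__setattr__(self, "segments", tuple(segs))

    def rng(self, name: str) -> np.random.Generator:
        """Named, seed-derived substream (one per modality)."""
        return np.random.default_rng([self.seed, zlib.crc32(name.encode())])


@dataclass
class SyntheticSession:
    """A generated session bundled with its ground truth.

    ``ground_truth`` has one row per configured segment (UTC bounds plus the
    SegmentSpec parameters); ``artifact_times`` holds ``(onset_s, width_s)``
    of every injected EEG transient, in seconds from EEG stream start.
    """

    recording: SessionRecording
    ground_truth: pd.DataFrame
    artifact_times: np.ndarray


def _segment_index_bounds(config: SynthConfig, rate: float) -> list[tuple[int, int]]:
    n_total = int(round(config.duration_s * rate))
    bounds = []
    for seg in config.segments:
        lo = int(np.ceil(seg.start_s * rate - 1e-6))
        hi = int(np.ceil(seg.end_s * rate - 1e-6))
        bounds.append((max(lo, 0), min(hi, n_total)))
    return bounds


def _pink_noise(n: int, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power background: white spectrum shaped by f^-1/2, RMS-normalised."""
    if rms == 0:
        return np.zeros(n)
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    spec[0] = 0.0
    spec[1:] /= np.sqrt(freqs[1:])
    x = np.fft.irfft(spec, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return x


def _band_carrier(
    n: int,
    band: tuple[float, float],
    center_hz: float,
    rms: float,
    rate: float,
    t0: float,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if rms == 0 or n == 0:
        return np.zeros(n)
    if mode == "sinusoid":
        t = t0 + np.arange(n) / rate
        return rms * np.sqrt(2.0) * np.sin(2 * np.pi * center_hz * t)
    # Ideal (FFT brick-wall) band-pass of white noise, rescaled to target RMS.
    # Brick-wall support keeps adjacent bands spectrally disjoint (theta and
    # alpha share the 8 Hz edge), which an IIR filter's skirts would smear
    # badly enough to break band purity.  The support is inset by a guard of
    # half the spectral resolution of the default 2 s Welch window, so that
    # window smearing keeps the carrier's power inside its own band.
    guard = 0.75
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(freqs < band[0] + guard) | (freqs >= band[1] - guard)] = 0.0
    x = np.fft.irfft(spec, n=n)
    measured = np.sqrt(np.mean(x**2))
    if measured == 0:  # pragma: no cover - degenerate tiny segment
        return np.zeros(n)
    return x * (rms / measured)


def generate_eeg(
    config: SynthConfig, start_utc: float = 0.0, channel: str = "Cz"
) -> tuple[BiosignalStream, np.ndarray]:
    """Synthesize the EEG stream; returns ``(stream, artifact_times)``.

    Each segment superposes, per band, a carrier whose RMS equals the
    segment's spec amplitude, on top of 1/f background of RMS
    ``noise_scale``.  ``artifact_rate`` per-minute high-amplitude half-sine
    transients (width 0.2-0.5 s, peak >= 5x the largest band amplitude) are
    injected at seeded random times; their ``(onset_s, width_s)`` ground
    truth is returned so rejection tests can verify exactly which epochs are
    contaminated.
    """
    rate = config.eeg_rate
    n = int(round(config.duration_s * rate))
    rng = config.rng("eeg")
    x = _pink_noise(n, config.noise_scale, rng)
    for (lo, hi), seg in zip(_segment_index_bounds(config, rate), config.segments):
        for band, amps in (
            ("theta", seg.theta_amp),
            ("alpha", seg.alpha_amp),
            ("beta", seg.beta_amp),
        ):
            x[lo:hi] += _band_carrier(
                hi - lo,
                BAND_EDGES[band],
                BAND_CENTERS[band],
                amps,
                rate,
                lo / rate,
                config.carrier,
                rng,
            )

    art_rng = config.rng("artifacts")
    n_art = int(round(config.artifact_rate * config.duration_s / 60.0))
    artifacts = np.empty((n_art, 2))
    max_amp = max(
        (max(s.theta_amp, s.alpha_amp, s.beta_amp) for s in config.segments),
        default=0.0,
    )
    # Floor keeps transients well above any sane rejection threshold even for
    # small band amplitudes.
    peak = 5.0 * max(max_amp, 30.0)
    for i in range(n_art):
        width = art_rng.uniform(0.2, 0.5)
        onset = art_rng.uniform(0.0, max(config.duration_s - width, 0.0))
        lo = int(np.ceil(onset * rate - 1e-6))
        hi = min(int(np.ceil((onset + width) * rate - 1e-6)), n)
        tt = (np.arange(lo, hi) / rate - onset) / width
        x[lo:hi] += peak * np.sin(np.pi * np.clip(tt, 0.0, 1.0))
        artifacts[i] = (onset, width)
    stream = BiosignalStream("EEG", channel, rate, start_utc, x)
    return stream, artifacts


def generate_eda(config: SynthConfig, start_utc: float = 0.0) -> BiosignalStream:
    """Synthesize the EDA stream: per-segment tonic level (short linear ramp
    at boundaries) plus per-segment phasic skin-conductance responses.

    Each response is a bi-exponential pulse (rise 1 s, decay 4 s) of peak
    amplitude drawn uniformly in [0.1, 0.5] uS; onsets are jittered within
    equal slots of the segment so the configured count is recoverable as
    distinct local maxima.  All samples are >= 0.
    """
    rate = config.eda_rate
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate
    # tonic: constant per segment, linear ramp of eda_ramp_s after each boundary
    knots_t = [0.0]
    knots_v = [config.segments[0].eda_tonic]
    for prev, seg in zip(config.segments, config.segments[1:]):
        ramp_end = min(seg.start_s + config.eda_ramp_s, seg.end_s)
        knots_t += [seg.start_s, ramp_end]
        knots_v += [prev.eda_tonic, seg.eda_tonic]
    knots_t.append(config.duration_s)
    knots_v.append(config.segments[-1].eda_tonic)
    x = np.interp(t, knots_t, knots_v)

    rng = config.rng("eda")
    tau_r, tau_d = _SCR_TAU_RISE_S, _SCR_TAU_DECAY_S
    t_peak = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    peak_norm = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    for seg in config.segments:
        if seg.scr_count == 0:
            continue
        slot = (seg.end_s - seg.start_s) / seg.scr_count
        for k in range(seg.scr_count):
            onset = seg.start_s + slot * k + rng.uniform(0.0, 0.4 * slot)
            amp = rng.uniform(0.1, 0.5)
            rel = t - onset
            mask = rel > 0
            x[mask] += (
                amp
                / peak_norm
                * (np.exp(-rel[mask] / tau_d) - np.exp(-rel[mask] / tau_r))
            )
    np.clip(x, 0.0, None, out=x)
    return BiosignalStream("EDA", "wrist", rate, start_utc, x)


def generate_hr(config: SynthConfig, start_utc: float = 0.0) -> BiosignalStream:
    """Synthesize the HR stream: per-segment level + Gaussian jitter
    (``hr_jitter_sd``) + slow sinusoidal drift, clamped to [30, 220] bpm."""
    rate = config.hr_rate
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate
    x = np.empty(n)
    for (lo, hi), seg in zip(_segment_index_bounds(config, rate), config.segments):
        x[lo:hi] = seg.hr_level
    rng = config.rng("hr")
    if config.hr_jitter_sd > 0:
        x += rng.normal(0.0, config.hr_jitter_sd, size=n)
    if config.hr_drift_amp > 0:
        x += config.hr_drift_amp * np.sin(2 * np.pi * t / config.hr_drift_period_s)
    np.clip(x, 30.0, 220.0, out=x)
    return BiosignalStream("HR", "wrist", rate, start_utc, x)


def generate_session(
    config: SynthConfig,
    session_kind: str,
    participant_id: str = "sim-01",
    group: str = "student",
    t0_utc: float = 1.6e9,
) -> SyntheticSession:
    """Generate a full session: three staggered streams plus annotations.

    Streams start at ``t0_utc + STREAM_STAGGER_S[modality]`` so that only
    UTC-based alignment reconstructs the segments.  One event annotation
    (node transition for the baseline session, gesture for the MR session)
    is emitted per internal segment boundary; the first configured segment
    therefore acts as the orientation period that segmentation excludes.
    Session-start/end markers are placed at the joint stream span bounds.
    """
    eeg, artifacts = generate_eeg(config, start_utc=t0_utc + STREAM_STAGGER_S["EEG"])
    eda = generate_eda(config, start_utc=t0_utc + STREAM_STAGGER_S["EDA"])
    hr = generate_hr(config, start_utc=t0_utc + STREAM_STAGGER_S["HR"])

    kind = "node_transition" if session_kind == "VP_baseline" else "gesture"
    prefix = "node" if kind == "node_transition" else "gesture"
    annotations = []
    for i, seg in enumerate(config.segments[1:], start=2):
        annotations.append(EventAnnotation(t0_utc + seg.start_s, f"{prefix}_{i}", kind))
    recording = SessionRecording(
        participant_id=participant_id,
        group=group,
        session_kind=session_kind,
        streams=[eeg, hr, eda],
        annotations=annotations,
    )
    lo, hi = recording.span()
    recording.annotations = sorted(
        [
            EventAnnotation(lo, "session_start", "session_start"),
            *annotations,
            EventAnnotation(hi, "session_end", "session_end"),
        ]
    )
    truth = pd.DataFrame(
        {
            "segment": np.arange(1, len(config.segments) + 1),
            "start_utc": [t0_utc + s.start_s for s in config.segments],
            "end_utc": [t0_utc + s.end_s for s in config.segments],
            "theta_amp": [s.theta_amp for s in config.segments],
            "alpha_amp": [s.alpha_amp for s in config.segments],
            "beta_amp": [s.beta_amp for s in config.segments],
            "hr_level": [s.hr_level for s in config.segments],
            "eda_tonic": [s.eda_tonic for s in config.segments],
            "scr_count": [s.scr_count for s in config.segments],
        }
    )
    return SyntheticSession(recording, truth, artifacts)


def synth_config_from_dict(spec: dict) -> SynthConfig:
    """Build a :class:`SynthConfig` from a plain dict (YAML ``simulate`` config)."""
    segments = [SegmentSpec(**seg) for seg in spec.get("segments", [])]
    kwargs = {k: v for k, v in spec.items() if k != "segments"}
    return SynthConfig(segments=tuple(segments), **kwargs)
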