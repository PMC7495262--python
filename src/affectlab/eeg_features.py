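"""EEG band features: band power/amplitude and the theta/beta ratio.

The two reported EEG metrics are the alpha-band amplitude (uV) and the ratio
of theta-band to beta-band power, both computed per scenario segment on the
Cz channel.  Band power is the integral of a Welch power spectral density
over the band; amplitude is its square root, i.e. the RMS of the band-limited
component — for a pure sinusoid of peak amplitude A this gives A/sqrt(2),
which is the closed-form oracle used in the tests.  A ``peak_equivalent``
convention (RMS * sqrt(2)) is available because the original amplifier's
internal amplitude metric is not publicly defined.

Artifact handling is amplitude-threshold epoch rejection: the segment is cut
into consecutive 1 s epochs and an epoch is rejected iff any sample exceeds
the threshold (default +/-100 uV) in absolute value.  Surviving epochs are
concatenated for spectral estimation (optionally re-grouped into fixed-length
analysis epochs, see :class:`FeatureConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, UndefinedFeatureError
from .signal_io import BiosignalStream

__all__ = [
    "BandDefinition",
    "THETA",
    "ALPHA",
    "BETA",
    "EEGSegmentFeatures",
    "FeatureConfig",
    "reject_artifacts",
    "band_power",
    "band_amplitude",
    "theta_beta_ratio",
    "extract_segment_features",
]

_POWER_FLOOR = 1e-12  # uV^2; below this a denominator power is "undefined"


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low_hz, high_hz]."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigurationError("band requires 0 < low_hz < high_hz")


THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 13.0, 21.0)


@dataclass(frozen=True)
class EEGSegmentFeatures:
    """Per-segment EEG metrics plus rejection bookkeeping."""

    alpha_amp: float  # uV, RMS convention unless configured otherwise
    theta_power: float  # uV^2
    beta_power: float  # uV^2
    theta_beta_ratio: float
    n_epochs_total: int
    n_epochs_rejected: int


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the EEG feature path.

    ``rejection_epoch_s``/``threshold_uv`` control artifact rejection;
    ``welch_window_s`` is the Welch window (Hann, 50 % overlap) — 2 s gives
    >= 8 theta cycles per window at 4 Hz.  ``analysis_epoch_s`` optionally
    splits the cleaned samples into fixed-length spectral epochs whose band
    powers are averaged; the default (``None``) runs one Welch over the whole
    cleaned segment, which weights the samples almost uniformly and roughly
    halves the estimator spread of short fixed epochs, whose Hann tapers
    underweight every epoch's edges.
    """

    theta: BandDefinition = THETA
    alpha: BandDefinition = ALPHA
    beta: BandDefinition = BETA
    rejection_epoch_s: float = 1.0
    threshold_uv: float = 100.0
    analysis_epoch_s: float | None = None
    welch_window_s: float = 2.0
    amplitude_convention: str = "rms"  # "rms" | "peak_equivalent"

    def __post_init__(self) -> None:
        if self.amplitude_convention not in ("rms", "peak_equivalent"):
            raise ConfigurationError(
                f"unknown amplitude convention {self.amplitude_convention!r}"
            )


def reject_artifacts(
    eeg_segment: BiosignalStream | np.ndarray,
    epoch_s: float = 1.0,
    threshold_uv: float = 100.0,
    rate: float | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Split a segment into consecutive epochs and drop contaminated ones.

    An epoch is rejected iff any absolute sample value exceeds
    ``threshold_uv``.  Returns ``(clean_epochs, rejected_mask)`` where the
    boolean mask covers every epoch in order.  A segment shorter than one
    epoch yields a single truncated epoch evaluated as-is; a trailing
    remainder becomes a final shorter epoch.
    """
    if not epoch_s > 0:
        raise ConfigurationError("epoch_s must be > 0")
    if not threshold_uv > 0:
        raise ConfigurationError("threshold_uv must be > 0")
    if isinstance(eeg_segment, BiosignalStream):
        x, rate = eeg_segment.samples, eeg_segment.rate
    else:
        if rate is None:
            raise ConfigurationError("rate is required for bare arrays")
        x = np.asarray(eeg_segment, dtype=float)
    n_per = max(int(round(epoch_s * rate)), 1)
    edges = list(range(0, x.size, n_per))
    epochs = [x[lo : lo + n_per] for lo in edges]
    rejected = np.array([np.any(np.abs(e) > threshold_uv) for e in epochs])
    clean = [e for e, bad in zip(epochs, rejected) if not bad]
    return clean, rejected


def _welch_band(
    x: np.ndarray, band: BandDefinition, rate: float, welch_window_s: float
) -> float:
    nperseg = min(int(round(welch_window_s * rate)), x.size)
    freqs, psd = sps.welch(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    if band.high_hz >= rate / 2:
        raise ConfigurationError("band exceeds Nyquist frequency")
    # Half-open [low, high): each PSD bin belongs to exactly one band, so
    # adjacent bands (theta/alpha share the 8 Hz edge) never double count a
    # bin and window-smeared edge power is not attributed to both.
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    if mask.sum() < 2:
        raise ConfigurationError("epoch too short to resolve the band")
    return float(np.trapezoid(psd[mask], freqs[mask]))


def band_power(
    epochs: list[np.ndarray] | np.ndarray,
    band: BandDefinition,
    rate: float,
    welch_window_s: float = 2.0,
) -> float:
    """Mean over epochs of the Welch PSD integrated over ``band`` (uV^2).

    For a stationary signal this equals the mean square of its band-limited
    component, so a pure sinusoid of peak A inside the band gives A^2/2.
    """
    if isinstance(epochs, np.ndarray) and epochs.ndim == 1:
        epochs = [epochs]
    epochs = [np.asarray(e, dtype=float) for e in epochs]
    if len(epochs) == 0:
        raise UndefinedFeatureError("no surviving epochs")
    return float(np.mean([_welch_band(e, band, rate, welch_window_s) for e in epochs]))


def band_amplitude(
    epochs: list[np.ndarray] | np.ndarray,
    band: BandDefinition,
    rate: float,
    welch_window_s: float = 2.0,
    convention: str = "rms",
) -> float:
    """Band amplitude in uV: sqrt of band power (RMS of the band-limited
    component), or RMS*sqrt(2) under the ``peak_equivalent`` convention."""
    amp = float(np.sqrt(band_power(epochs, band, rate, welch_window_s)))
    if convention == "peak_equivalent":
        amp *= np.sqrt(2.0)
    elif convention != "rms":
        raise ConfigurationError(f"unknown amplitude convention {convention!r}")
    return amp


def theta_beta_ratio(
    epochs: list[np.ndarray] | np.ndarray,
    rate: float,
    theta: BandDefinition = THETA,
    beta: BandDefinition = BETA,
    welch_window_s: float = 2.0,
) -> float:
    """Ratio of mean theta-band power to mean beta-band power."""
    beta_p = band_power(epochs, beta, rate, welch_window_s)
    if beta_p <= _POWER_FLOOR:
        raise UndefinedFeatureError("beta power at numeric floor; ratio undefined")
    return band_power(epochs, theta, rate, welch_window_s) / beta_p


def _analysis_epochs(
    clean: list[np.ndarray],
    rate: float,
    analysis_epoch_s: float | None,
    welch_window_s: float,
) -> list[np.ndarray]:
    """Regroup surviving rejection epochs into analysis epochs.

    Clean samples are concatenated (rejected stretches excised) and, when
    ``analysis_epoch_s`` is set, cut into chunks of that length; a tail
    shorter than one Welch window is dropped unless it is all there is.
    ``None`` keeps the whole cleaned segment as a single epoch.
    """
    if not clean:
        return []
    x = np.concatenate(clean)
    if analysis_epoch_s is None:
        return [x]
    n_per = max(int(round(analysis_epoch_s * rate)), 1)
    chunks = [x[lo : lo + n_per] for lo in range(0, x.size, n_per)]
    min_len = int(round(welch_window_s * rate))
    kept = [c for c in chunks if c.size >= min_len]
    return kept if kept else [x]


def extract_segment_features(
    eeg_segment: BiosignalStream, config: FeatureConfig = FeatureConfig()
) -> EEGSegmentFeatures:
    """Full per-segment EEG feature path: rejection -> epoching -> spectra.

    Raises :class:`UndefinedFeatureError` when every epoch is rejected or the
    beta power sits at the numeric floor, so the segment is flagged rather
    than silently zeroed.
    """
    clean, rejected = reject_artifacts(
        eeg_segment, config.rejection_epoch_s, config.threshold_uv
    )
    if not clean:
        raise UndefinedFeatureError(
            f"all {rejected.size} epochs rejected at {config.threshold_uv} uV"
        )
    epochs = _analysis_epochs(
        clean, eeg_segment.rate, config.analysis_epoch_s, config.welch_window_s
    )
    rate = eeg_segment.rate
    theta_p = band_power(epochs, config.theta, rate, config.welch_window_s)
    beta_p = band_power(epochs, config.beta, rate, config.welch_window_s)
    alpha = band_amplitude(
        epochs, config.alpha, rate, config.welch_window_s, config.amplitude_convention
    )
    if beta_p <= _POWER_FLOOR:
        raise UndefinedFeatureError("beta power at numeric floor; ratio undefined")
    return EEGSegmentFeatures(
        alpha_amp=alpha,
        theta_power=theta_p,
        beta_power=beta_p,
        theta_beta_ratio=theta_p / beta_p,
        n_epochs_total=int(rejected.size),
        n_epochs_rejected=int(rejected.sum()),
    )
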