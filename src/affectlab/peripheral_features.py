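"""Per-segment heart-rate and electrodermal summaries.

Both modalities are summarised the same way the cohort analysis treats them:
arithmetic mean and population SD (divisor n) of the raw samples falling in
the half-open segment window.  EDA is deliberately summarised as raw mean
conductance without tonic/phasic decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass


from .errors import UndefinedFeatureError
from .signal_io import BiosignalStream, slice_stream

__all__ = ["PeripheralSegmentFeatures", "segment_hr", "segment_eda", "segment_stats"]


@dataclass(frozen=True)
class PeripheralSegmentFeatures:
    hr_mean: float  # bpm
    hr_sd: float
    eda_mean: float  # uS
    eda_sd: float
    n_samples_hr: int
    n_samples_eda: int


def segment_stats(
    stream: BiosignalStream, start_utc: float, end_utc: float
) -> tuple[float, float, int]:
    """(mean, population SD, n) of samples in [start_utc, end_utc)."""
    piece = slice_stream(stream, start_utc, end_utc)
    if piece is None:
        raise UndefinedFeatureError(
            f"no {stream.modality} samples in [{start_utc}, {end_utc})"
        )
    x = piece.samples
    return float(x.mean()), float(x.std(ddof=0)), int(x.size)


def segment_hr(stream: BiosignalStream, start_utc: float, end_utc: float) -> tuple[float, float]:
    """Mean and population SD of heart rate (bpm) in the window."""
    mean, sd, _ = segment_stats(stream, start_utc, end_utc)
    return mean, sd


def segment_eda(stream: BiosignalStream, start_utc: float, end_utc: float) -> tuple[float, float]:
    """Mean and population SD of skin conductance (uS) in the window."""
    mean, sd, _ = segment_stats(stream, start_utc, end_utc)
    return mean, sd
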