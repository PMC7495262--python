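"""End-to-end session analysis.

The procedure mirrors how the cohort study treats its recordings:

1. segment each session at its scenario events (node transitions in the
   web-based virtual-patient session, paced gestures in the mixed-reality
   session); the stretch before the first event is the orientation period
   and is excluded;
2. average each biosignal metric within each segment (EEG features from
   Welch spectra after artifact rejection; HR/EDA as raw means);
3. collapse the baseline session's segment means into one global baseline
   per metric, and the MR session's likewise into one MR mean per metric
   (unweighted across segments — each segment is one observation);
4. aggregate per group with arithmetic mean and population SD (divisor n);
5. count, per group and in total, participants whose theta/beta ratio
   increased, alpha amplitude decreased, HR increased and EDA increased
   from baseline to MR (strict inequalities on unrounded deltas; a zero
   delta counts as neither direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .eeg_features import FeatureConfig, extract_segment_features
from .errors import FormatError, IntegrityError, UndefinedFeatureError
from .peripheral_features import segment_stats
from .signal_io import (
    EVENT_KINDS,
    GROUPS,
    EventAnnotation,
    SessionRecording,
    read_session,
    slice_stream,
)

__all__ = [
    "METRICS",
    "Segment",
    "ParticipantSummary",
    "build_segments",
    "compute_segment_metrics",
    "session_summary",
    "baseline_summary",
    "participant_summary",
    "group_summary",
    "shift_table",
    "analyze_cohort",
]

#: The four reported biosignal metrics, in table order.
METRICS = ("theta_beta", "alpha_amp", "hr", "eda")

#: Shift-table column per metric: the directions the cohort analysis counts.
SHIFT_COLUMNS = {
    "theta_beta": "increased_theta_beta",
    "alpha_amp": "decreased_alpha",
    "hr": "increased_hr",
    "eda": "increased_eda",
}
_SHIFT_SIGN = {"theta_beta": +1, "alpha_amp": -1, "hr": +1, "eda": +1}


@dataclass(frozen=True)
class Segment:
    """A half-open analysis window between consecutive scenario events."""

    index: int
    start_utc: float
    end_utc: float
    source_annotation: str


def build_segments(
    annotations: Sequence[EventAnnotation],
    session_span: tuple[float, float],
    min_duration_s: float = 0.0,
) -> list[Segment]:
    """Segments between consecutive event annotations inside ``session_span``.

    The final segment runs from the last event to the span end; the interval
    from span start to the first event (orientation) is excluded.  Zero- or
    sub-``min_duration_s`` segments are dropped with a warning (e.g. an event
    stamped exactly at session end).
    """
    lo, hi = session_span
    if not lo < hi:
        raise IntegrityError("session span must have start < end")
    events = [a for a in annotations if a.kind in EVENT_KINDS and lo <= a.time_utc < hi]
    if not events:
        raise IntegrityError("cannot segment: no event annotations inside span")
    events = sorted(events)
    bounds = [(a.time_utc, a.label) for a in events] + [(hi, "session_end")]
    segments: list[Segment] = []
    for (start, label), (end, _) in zip(bounds, bounds[1:]):
        if end - start <= min_duration_s:
            warnings.warn(
                f"dropping degenerate segment [{start}, {end}) from {label!r}",
                stacklevel=2,
            )
            continue
        segments.append(Segment(len(segments) + 1, start, end, label))
    return segments


def compute_segment_metrics(
    recording: SessionRecording,
    segments: Sequence[Segment] | None = None,
    feature_config: FeatureConfig = FeatureConfig(),
    eeg_channel: str = "Cz",
) -> pd.DataFrame:
    """Per-segment metric table for one session.

    Columns: segment, start_utc, end_utc, theta_beta, alpha_amp, hr, eda,
    hr_sd, eda_sd, n_epochs_total, n_epochs_rejected.  A metric that cannot
    be computed for a segment (no samples / all epochs rejected) is NaN and
    a warning is emitted; it is excluded from downstream averaging.
    """
    if segments is None:
        segments = build_segments(recording.annotations, recording.span())
    eeg = recording.get_stream("EEG", eeg_channel)
    hr = recording.get_stream("HR")
    eda = recording.get_stream("EDA")
    rows = []
    for seg in segments:
        row: dict[str, float] = {
            "segment": seg.index,
            "start_utc": seg.start_utc,
            "end_utc": seg.end_utc,
            "theta_beta": np.nan,
            "alpha_amp": np.nan,
            "hr": np.nan,
            "hr_sd": np.nan,
            "eda": np.nan,
            "eda_sd": np.nan,
            "n_epochs_total": 0,
            "n_epochs_rejected": 0,
        }
        piece = slice_stream(eeg, seg.start_utc, seg.end_utc)
        if piece is None:
            warnings.warn(f"segment {seg.index}: no EEG samples", stacklevel=2)
        else:
            try:
                feats = extract_segment_features(piece, feature_config)
                row.update(
                    theta_beta=feats.theta_beta_ratio,
                    alpha_amp=feats.alpha_amp,
                    n_epochs_total=feats.n_epochs_total,
                    n_epochs_rejected=feats.n_epochs_rejected,
                )
            except UndefinedFeatureError as exc:
                warnings.warn(f"segment {seg.index}: EEG features undefined ({exc})", stacklevel=2)
        for name, stream in (("hr", hr), ("eda", eda)):
            try:
                mean, sd, _ = segment_stats(stream, seg.start_utc, seg.end_utc)
                row[name], row[f"{name}_sd"] = mean, sd
            except UndefinedFeatureError as exc:
                warnings.warn(f"segment {seg.index}: {exc}", stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows)


def session_summary(
    metrics: pd.DataFrame, duration_weighted: bool = False
) -> dict[str, float]:
    """Collapse per-segment metric means into one value per metric.

    Default is the unweighted mean across segments (each segment is one
    observation, regardless of its length); ``duration_weighted=True`` weighs
    by segment duration instead.  Undefined (NaN) segments are excluded; a
    metric undefined in every segment stays NaN.
    """
    out = {}
    weights = (metrics["end_utc"] - metrics["start_utc"]).to_numpy(float)
    for m in METRICS:
        vals = metrics[m].to_numpy(float)
        ok = ~np.isnan(vals)
        if not ok.any():
            out[m] = float("nan")
        elif duration_weighted:
            out[m] = float(np.average(vals[ok], weights=weights[ok]))
        else:
            out[m] = float(vals[ok].mean())
    return out


def baseline_summary(
    vp_metrics: pd.DataFrame, duration_weighted: bool = False
) -> dict[str, float]:
    """Global per-metric baseline: the mean over the baseline session's
    segment means."""
    return session_summary(vp_metrics, duration_weighted)


@dataclass(frozen=True)
class ParticipantSummary:
    """Baseline-session and MR-session global averages for one participant."""

    participant_id: str
    group: str
    baseline: Mapping[str, float]  # metric -> mean over baseline segments
    mr: Mapping[str, float]  # metric -> mean over MR segments

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise IntegrityError(f"unknown group {self.group!r}")
        for cond in (self.baseline, self.mr):
            missing = set(METRICS) - set(cond)
            if missing:
                raise IntegrityError(f"summary missing metrics {sorted(missing)}")

    def delta(self, metric: str) -> float:
        """MR minus baseline; NaN when either side is undefined."""
        return self.mr[metric] - self.baseline[metric]

    def deltas(self) -> dict[str, float]:
        return {m: self.delta(m) for m in METRICS}


def participant_summary(
    vp_session: SessionRecording,
    mr_session: SessionRecording,
    feature_config: FeatureConfig = FeatureConfig(),
    eeg_channel: str = "Cz",
    duration_weighted: bool = False,
) -> ParticipantSummary:
    """Run both sessions through segmentation + features and summarise."""
    if vp_session.participant_id != mr_session.participant_id:
        raise IntegrityError("sessions belong to different participants")
    if vp_session.session_kind != "VP_baseline" or mr_session.session_kind != "MR":
        raise IntegrityError("expected a VP_baseline session and an MR session")
    vp_metrics = compute_segment_metrics(vp_session, feature_config=feature_config, eeg_channel=eeg_channel)
    mr_metrics = compute_segment_metrics(mr_session, feature_config=feature_config, eeg_channel=eeg_channel)
    return ParticipantSummary(
        participant_id=vp_session.participant_id,
        group=vp_session.group,
        baseline=baseline_summary(vp_metrics, duration_weighted),
        mr=session_summary(mr_metrics, duration_weighted),
    )


def group_summary(summaries: Iterable[ParticipantSummary]) -> pd.DataFrame:
    """Per-group cohort table: mean and population SD per metric x condition.

    Long-format frame with columns ``group, metric, condition, mean, sd, n``;
    ``n`` counts participants with the metric defined.  Values are unrounded;
    display rounding lives in :mod:`affectlab.reporting`.
    """
    summaries = list(summaries)
    if not summaries:
        raise IntegrityError("no participant summaries")
    rows = []
    groups = [g for g in GROUPS if any(s.group == g for s in summaries)]
    for group in groups:
        members = [s for s in summaries if s.group == group]
        for metric in METRICS:
            for cond_name, getter in (("VP", "baseline"), ("MR", "mr")):
                vals = np.array(
                    [getattr(s, getter)[metric] for s in members], dtype=float
                )
                vals = vals[~np.isnan(vals)]
                rows.append(
                    {
                        "group": group,
                        "metric": metric,
                        "condition": cond_name,
                        "mean": vals.mean() if vals.size else np.nan,
                        "sd": vals.std(ddof=0) if vals.size else np.nan,
                        "n": int(vals.size),
                    }
                )
    return pd.DataFrame(rows)


def shift_table(summaries: Iterable[ParticipantSummary]) -> pd.DataFrame:
    """Directional shift counts per group plus a computed total row.

    Counts participants whose unrounded MR-baseline delta is strictly in the
    direction of interest (theta/beta up, alpha down, HR up, EDA up); a zero
    delta counts as neither, an undefined delta is excluded.  The total row
    is always the column sum over the group rows.
    """
    summaries = list(summaries)
    if not summaries:
        raise IntegrityError("no participant summaries")
    groups = [g for g in GROUPS if any(s.group == g for s in summaries)]
    rows = []
    for group in groups:
        members = [s for s in summaries if s.group == group]
        row: dict[str, object] = {"group": group, "n": len(members)}
        for metric, col in SHIFT_COLUMNS.items():
            deltas = np.array([s.delta(metric) for s in members], dtype=float)
            row[col] = int(np.sum(_SHIFT_SIGN[metric] * deltas > 0))
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("group")
    frame.loc["total"] = frame.sum(axis=0)
    return frame.reset_index()


# ---------------------------------------------------------------------------
# cohort driver


def analyze_cohort(
    manifest_path: str | Path,
    out_dir: str | Path,
    feature_config: FeatureConfig = FeatureConfig(),
) -> dict[str, pd.DataFrame]:
    """Run a whole cohort from a manifest and write the three result tables.

    The cohort manifest is YAML of the form::

        participants:
          - vp: p01/vp_session/session.yaml
            mr: p01/mr_session/session.yaml

    (paths relative to the manifest).  Writes ``participant_summary.csv``,
    ``group_summary.csv`` and ``shift_table.csv`` (the latter two with
    affect labels appended by :mod:`affectlab.affect_rules`) and returns the
    frames.
    """
    from .affect_rules import classify  # local import: avoid cycle

    manifest_path = Path(manifest_path)
    spec = yaml.safe_load(manifest_path.read_text())
    if not isinstance(spec, dict) or "participants" not in spec:
        raise FormatError(f"{manifest_path}: cohort manifest needs a 'participants' list")
    base = manifest_path.parent
    summaries = []
    for entry in spec["participants"]:
        vp = read_session(base / entry["vp"])
        mr = read_session(base / entry["mr"])
        summaries.append(participant_summary(vp, mr, feature_config))

    part_rows = []
    for s in summaries:
        label = classify(s.deltas())
        row = {"participant_id": s.participant_id, "group": s.group}
        for m in METRICS:
            row[f"{m}_vp"] = s.baseline[m]
            row[f"{m}_mr"] = s.mr[m]
            row[f"{m}_delta"] = s.delta(m)
        row["engagement"] = label.engagement
        row["arousal_elevated"] = label.arousal_elevated
        part_rows.append(row)
    participant_df = pd.DataFrame(part_rows)
    group_df = group_summary(summaries)
    shift_df = shift_table(summaries)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    participant_df.to_csv(out_dir / "participant_summary.csv", index=False)
    group_df.to_csv(out_dir / "group_summary.csv", index=False)
    shift_df.to_csv(out_dir / "shift_table.csv", index=False)
    return {
        "participants": participant_df,
        "groups": group_df,
        "shifts": shift_df,
    }
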