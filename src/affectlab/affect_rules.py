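"""Rule-based affective interpretation of metric shifts.

The engagement reading rests on two well-established EEG markers: midline
theta power (hence the theta/beta ratio) rises with working-memory load and
sustained attention, while alpha amplitude is suppressed by
attention-demanding engagement and rises in relaxed or disengaged states.
Crossing the two directions between the baseline and MR conditions gives
four patterns:

====================  ====================  ============================
theta/beta delta      alpha delta           engagement label
====================  ====================  ============================
up                    down                  full_cognitive_engagement
up                    up                    ambivalent_engagement
down                  up                    guided_disengagement
down                  down                  indeterminate (no rule)
====================  ====================  ============================

``guided_disengagement`` is the pattern of a learner relieved of judgement
calls (task control relegated to a facilitator); ``ambivalent_engagement``
the pattern of committing to the mechanics of a task without being
challenged by its content.  Elevated HR or EDA independently flags high
sympathetic arousal, which is valence-free.

Deltas are MR minus baseline.  A per-metric dead-zone turns small deltas
into "no change"; the default dead-zones are 0 (pure sign logic), which
matches a qualitative group-level reading — for noisy single-participant
use, set dead-zones of the order of the feature-estimation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError
from .session_pipeline import METRICS, ParticipantSummary

__all__ = ["ENGAGEMENT_LABELS", "AffectRuleConfig", "AffectLabel", "classify", "classify_summary"]

ENGAGEMENT_LABELS = (
    "full_cognitive_engagement",
    "ambivalent_engagement",
    "guided_disengagement",
    "indeterminate",
)


@dataclass(frozen=True)
class AffectRuleConfig:
    """Dead-zones (in each metric's units) below which |delta| is 'no change'."""

    min_abs_delta: Mapping[str, float] = field(
        default_factory=lambda: {m: 0.0 for m in METRICS}
    )

    def __post_init__(self) -> None:
        for metric, dz in self.min_abs_delta.items():
            if metric not in METRICS:
                raise ConfigurationError(f"unknown metric {metric!r}")
            if dz < 0:
                raise ConfigurationError("dead-zones must be >= 0")

    def deadzone(self, metric: str) -> float:
        return float(self.min_abs_delta.get(metric, 0.0))


@dataclass(frozen=True)
class AffectLabel:
    engagement: str
    arousal_elevated: bool
    rationale: str


def _sign(delta: float, deadzone: float) -> int:
    """-1 / 0 / +1 after dead-zoning; 0 for NaN (undefined delta)."""
    if math.isnan(delta) or abs(delta) <= deadzone:
        return 0
    return 1 if delta > 0 else -1


def classify(
    deltas: Mapping[str, float], config: AffectRuleConfig = AffectRuleConfig()
) -> AffectLabel:
    """Map metric deltas (MR - baseline) to an affect label.

    The engagement label is determined solely by the dead-zoned signs of the
    theta/beta and alpha deltas; every sign pattern maps to exactly one
    label, with patterns the rule set does not cover (either sign zero or
    undefined, or both markers down) labelled ``indeterminate``.
    ``arousal_elevated`` is true iff the EDA or HR delta exceeds its
    dead-zone upward.
    """
    missing = {"theta_beta", "alpha_amp"} - set(deltas)
    if missing:
        raise ConfigurationError(f"deltas missing metrics {sorted(missing)}")
    tbr = _sign(deltas["theta_beta"], config.deadzone("theta_beta"))
    alpha = _sign(deltas["alpha_amp"], config.deadzone("alpha_amp"))
    if tbr > 0 and alpha < 0:
        engagement = "full_cognitive_engagement"
    elif tbr > 0 and alpha > 0:
        engagement = "ambivalent_engagement"
    elif tbr < 0 and alpha > 0:
        engagement = "guided_disengagement"
    else:
        engagement = "indeterminate"
    hr = _sign(deltas.get("hr", float("nan")), config.deadzone("hr"))
    eda = _sign(deltas.get("eda", float("nan")), config.deadzone("eda"))
    arousal = hr > 0 or eda > 0
    words = {1: "up", 0: "no change", -1: "down"}
    rationale = (
        f"theta/beta {words[tbr]}, alpha {words[alpha]} -> {engagement}; "
        f"HR {words[hr]}, EDA {words[eda]} -> arousal "
        f"{'elevated' if arousal else 'not elevated'}"
    )
    return AffectLabel(engagement, arousal, rationale)


def classify_summary(
    summary: ParticipantSummary, config: AffectRuleConfig = AffectRuleConfig()
) -> AffectLabel:
    """Convenience wrapper: classify a participant's MR-vs-baseline deltas."""
    return classify(summary.deltas(), config)
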