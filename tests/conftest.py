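import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from affectlab.synthetic_data import SegmentSpec, SynthConfig, generate_session

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def graded_segments(values, seg_len=90.0, **common):
    """Contiguous segments from a list of per-segment kwargs dicts."""
    segs = []
    for i, v in enumerate(values):
        segs.append(SegmentSpec(i * seg_len, (i + 1) * seg_len, **{**common, **v}))
    return tuple(segs)


@pytest.fixture()
def small_session():
    """A 3-segment baseline session (first segment = orientation)."""
    cfg = SynthConfig(
        duration_s=180.0,
        segments=graded_segments(
            [
                {"theta_amp": 4, "alpha_amp": 8, "beta_amp": 2, "hr_level": 80, "eda_tonic": 1.0},
                {"theta_amp": 4, "alpha_amp": 8, "beta_amp": 2, "hr_level": 82, "eda_tonic": 1.2},
                {"theta_amp": 5, "alpha_amp": 7, "beta_amp": 2, "hr_level": 81, "eda_tonic": 1.1},
            ],
            seg_len=60.0,
        ),
        seed=42,
        noise_scale=0.5,
        artifact_rate=1.0,
    )
    return generate_session(cfg, "VP_baseline", participant_id="p-test", group="student")


def cohort_plan():
    """Six participants with hand-designed per-segment ground truth.

    Per participant: (group, vp segment values, mr segment values); each
    session is orientation + three 90 s scored segments.  Shift directions
    are mixed across participants so the expected shift table is nontrivial.
    """
    def seg(th, al, be, hr, eda):
        return {"theta_amp": th, "alpha_amp": al, "beta_amp": be,
                "hr_level": hr, "eda_tonic": eda, "scr_count": 1}

    return [
        # id, group, vp segments (incl. orientation first), mr segments
        ("p1", "student",
         [seg(4.0, 8.0, 2.0, 80, 1.0), seg(4.0, 8.0, 2.0, 80, 1.0),
          seg(4.2, 7.8, 2.0, 82, 1.1), seg(3.8, 8.2, 2.0, 81, 0.9)],
         [seg(5.0, 6.5, 2.0, 88, 3.0), seg(5.0, 6.5, 2.0, 88, 3.0),
          seg(5.2, 6.3, 2.0, 90, 3.2), seg(4.8, 6.7, 2.0, 87, 2.8)]),
        ("p2", "student",
         [seg(4.0, 7.0, 2.0, 90, 0.6), seg(4.0, 7.0, 2.0, 90, 0.5),
          seg(4.1, 7.1, 2.0, 91, 0.6), seg(3.9, 6.9, 2.0, 89, 0.5)],
         [seg(3.2, 8.5, 2.0, 84, 2.0), seg(3.2, 8.5, 2.0, 84, 2.0),
          seg(3.3, 8.6, 2.0, 83, 2.1), seg(3.1, 8.4, 2.0, 85, 1.9)]),
        ("p3", "neurosurgeon",
         [seg(3.0, 7.0, 2.0, 80, 0.8), seg(3.0, 7.0, 2.0, 80, 0.8),
          seg(3.1, 7.2, 2.0, 81, 0.9), seg(2.9, 6.8, 2.0, 79, 0.7)],
         [seg(3.8, 9.0, 2.0, 88, 2.5), seg(3.8, 9.0, 2.0, 88, 2.5),
          seg(3.9, 9.2, 2.0, 89, 2.6), seg(3.7, 8.8, 2.0, 87, 2.4)]),
        ("p4", "neurosurgeon",
         [seg(4.0, 9.0, 2.0, 85, 3.0), seg(4.0, 9.0, 2.0, 85, 3.0),
          seg(4.1, 9.1, 2.0, 86, 3.1), seg(3.9, 8.9, 2.0, 84, 2.9)],
         [seg(3.2, 7.0, 2.0, 78, 1.5), seg(3.2, 7.0, 2.0, 78, 1.5),
          seg(3.3, 7.1, 2.0, 77, 1.6), seg(3.1, 6.9, 2.0, 79, 1.4)]),
        ("p5", "postgraduate",
         [seg(3.5, 10.0, 2.0, 84, 0.5), seg(3.5, 10.0, 2.0, 84, 0.5),
          seg(3.6, 10.2, 2.0, 85, 0.6), seg(3.4, 9.8, 2.0, 83, 0.4)],
         [seg(4.5, 8.0, 2.0, 76, 2.0), seg(4.5, 8.0, 2.0, 76, 2.0),
          seg(4.6, 8.1, 2.0, 75, 2.1), seg(4.4, 7.9, 2.0, 77, 1.9)]),
        ("p6", "postgraduate",
         [seg(4.5, 7.0, 2.0, 72, 2.5), seg(4.5, 7.0, 2.0, 72, 2.5),
          seg(4.6, 7.1, 2.0, 73, 2.6), seg(4.4, 6.9, 2.0, 71, 2.4)],
         [seg(3.6, 9.0, 2.0, 80, 1.0), seg(3.6, 9.0, 2.0, 80, 1.0),
          seg(3.7, 9.1, 2.0, 81, 1.1), seg(3.5, 8.9, 2.0, 79, 0.9)]),
    ]


def build_cohort_sessions(seed: int):
    """Generate (vp, mr) SyntheticSession pairs for the six-participant plan.

    noise_scale 0.2 uV = 10% of the smallest band RMS (beta 2 uV); artifacts
    injected at the default 2/min so rejection is exercised end to end.
    """
    sessions = []
    for i, (pid, group, vp_vals, mr_vals) in enumerate(cohort_plan()):
        vp_cfg = SynthConfig(
            duration_s=360.0,
            segments=graded_segments(vp_vals, seg_len=90.0),
            seed=seed + 10 * i,
            noise_scale=0.2,
            artifact_rate=2.0,
        )
        mr_cfg = SynthConfig(
            duration_s=360.0,
            segments=graded_segments(mr_vals, seg_len=90.0),
            seed=seed + 10 * i + 5,
            noise_scale=0.2,
            artifact_rate=2.0,
        )
        vp = generate_session(vp_cfg, "VP_baseline", participant_id=pid, group=group)
        mr = generate_session(mr_cfg, "MR", participant_id=pid, group=group)
        sessions.append((vp, mr))
    return sessions
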