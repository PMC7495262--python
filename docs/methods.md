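# Methods

This note documents the analysis model, the tunable parameters, what the
synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Analysis model

### Time base and segmentation

Every stream is uniformly sampled with its own UTC start time; sample *k*
lies at `start_utc + k/rate`. Streams from different devices start at
different instants, so all alignment is timestamp arithmetic — index
arithmetic is never meaningful. Analysis windows are half-open `[t0, t1)`
with a shared index-mapping rule at both ends, which makes segmentation an
exact partition: slicing at any ordered boundaries and concatenating
reproduces the sample sequence bit for bit (asserted as a property test).

A session's analysable span is the intersection of its stream spans — the
only window where all three modalities exist. Segments are the intervals
between consecutive scenario events (node transitions in the web-based VP
session, paced interaction gestures in the MR session), plus a final
segment from the last event to span end. The stretch from span start to the
first event is treated as orientation/setup and excluded. Degenerate
(zero-length) segments are dropped with a warning. Clock drift between
devices is assumed absent (UTC stamps are trusted); drift correction is
future work.

### EEG features

Per segment, per channel (Cz by default, matching where the cohort's
features were reported):

1. **Artifact rejection.** The segment is cut into consecutive 1 s epochs;
   an epoch is rejected iff any |sample| exceeds 100 µV. This is the
   simplest defensible stand-in for an unspecified real-time "automatic
   artifact removal"; both epoch length and threshold are configurable
   (`FeatureConfig`). Rejection counts are carried through to the output so
   data loss is visible.
2. **Spectral estimation.** Surviving epochs are concatenated and a Welch
   PSD (Hann, 2 s windows, 50 % overlap) is computed over the whole cleaned
   segment. Band power is the trapezoidal integral of the PSD over the
   band; band bins are assigned half-open `[low, high)` so that adjacent
   bands — theta and alpha share the 8 Hz edge — never double-count a bin.
   `analysis_epoch_s` optionally splits the cleaned samples into fixed
   epochs whose band powers are averaged (e.g. 4 s); the default is the
   whole segment because Hann tapers underweight every epoch's edges, and
   with short fixed epochs that adds a segment-length-independent estimator
   spread large enough to break 5 % parameter recovery. With whole-segment
   Welch the sample weighting is near-uniform and recovery tightens by
   roughly a factor of two.
3. **Metrics.** Alpha amplitude is reported as the RMS of the band-limited
   component, `sqrt(integrated band power)` — chosen because it has a
   closed-form oracle (a sinusoid of peak A has RMS A/√2). The original
   amplifier's internal "amplitude" metric is undocumented, so absolute µV
   comparability with the instrument is not claimed; a
   `peak_equivalent` convention (RMS·√2) is available. The theta/beta
   ratio is the ratio of integrated band powers and is scale-invariant.

Band edges are fixed to the instrument's definitions: theta 4–8, alpha
8–12, beta 13–21 Hz. Whether the instrument treats edges as inclusive and
which estimator it runs in real time is unknowable; no attempt is made to
reproduce its absolute magnitudes from raw signals (cohort-table
reproduction enters at the aggregation stage from per-participant values).

A segment whose epochs are all rejected, or whose beta power sits at the
numeric floor (1e-12 µV²), raises an undefined-feature signal and is
flagged (NaN) rather than silently zeroed; downstream averages skip flagged
segments and group `n` counts only defined values.

### Peripheral features

HR and EDA are summarised per segment as the arithmetic mean and
population SD (divisor *n*) of the raw samples in the window. Population SD
is used everywhere because it is the convention the shipped cohort's group
table verifiably follows (the students' VP EDA SD reproduces under divisor
*n* and not under *n−1*). EDA is deliberately summarised as raw mean
conductance — no tonic/phasic decomposition — matching the cohort analysis
this package operationalises.

### Aggregation and rules

Session summaries are unweighted means over segment means (each segment is
one observation; duration-weighting is available as an option). Deltas are
MR − baseline. Group cells are mean and population SD over participants;
display rounding is half-away-from-zero at 2 decimals for ratio and alpha,
3 for EDA, integer bpm — comparisons always use unrounded values. Shift
counts use strict inequalities on unrounded deltas; a zero delta (one
student's HR was 92 bpm in both conditions) counts as neither direction.
The shift-table total row is always the computed column sum.

Engagement labels are a pure function of the dead-zoned signs of
(Δtheta/beta, Δalpha): `(↑,↓)` full cognitive engagement, `(↑,↑)`
ambivalent engagement (committed to the task mechanics but not challenged),
`(↓,↑)` guided disengagement (judgement calls relegated to a facilitator),
and anything else — including `(↓,↓)`, for which no interpretation is
established — indeterminate. Arousal is flagged when ΔEDA or ΔHR exceeds
its dead-zone upward; EDA/HR index arousal independent of valence. Default
dead-zones are 0 (pure sign logic), appropriate for group-level reading;
for single participants a dead-zone of the order of the feature-estimation
error (e.g. 3× the residuals the recovery tests measure) is recommended.

## Reference cohort and the reported-cell audit

The package ships, as plain CSV:

- per-participant VP/MR metric averages for the 11-participant pilot cohort
  (4 students, 4 neurosurgeons, 3 postgraduates);
- the representative participant's four baseline segment rows;
- the group summary table and shift counts *as originally reported*.

The as-reported cells are audit targets, not inputs:
`reporting.audit_reference_tables()` recomputes every group cell, shift
count and baseline average from the per-participant/per-segment data. A
cell counts as reproduced when the recomputed value prints as the reported
one under either common display convention (round half away from zero, or
truncation) at the reported precision. Most cells reproduce; the audit
surfaces a fixed set that cannot be derived from the per-participant data —
the neurosurgeons' alpha cells and MR theta/beta cell, three shift-table
totals and one postgraduate HR count (the totals disagree with their own
column sums), and the representative baseline HR/EDA averages. These are
reported as logged discrepancies; the package never adjusts its arithmetic
to reproduce them.

## Synthetic data: the stated world

The generator emulates the rig's acquisition geometry — 256 Hz EEG, 1 Hz
HR, 4 Hz EDA, staggered stream starts (EEG +0.0 s, EDA +0.5 s, HR +1.2 s
from session start; fixed constants chosen so naive index alignment fails),
event annotations at internal segment boundaries — with known ground truth
per segment. Defaults are calibrated once to the value ranges the cohort
tables report (alpha RMS ≈ 5–12 µV, theta/beta ≈ 1.4–5.4, HR 65–97 bpm,
EDA ≈ 0.2–6 µS).

- **EEG.** Per segment and band, a carrier whose RMS equals the spec
  amplitude, superposed on 1/f background noise (FFT-shaped, RMS
  `noise_scale`). The default carrier is white noise ideally band-limited
  by an FFT brick-wall and rescaled to the target RMS; an IIR band-pass was
  rejected because its skirts across the shared 8 Hz edge leak double-digit
  percentages of RMS between theta and alpha. The brick-wall support is
  inset 0.75 Hz per edge so Welch main-lobe smearing keeps carrier power
  inside its own band. A `sinusoid` mode (band-center frequencies 6/10/17
  Hz) provides analytic oracles. Artifacts are half-sine transients, 0.2–
  0.5 s wide, peak ≥ 5× the largest band amplitude (floor 150 µV), at
  `artifact_rate` per minute (default 2/min); their onset/width ground
  truth is emitted for rejection tests.
- **EDA.** Constant tonic level per segment with a 2 s linear ramp at
  boundaries, plus `scr_count` phasic responses per segment: bi-exponential
  pulses (rise 1 s, decay 4 s), peak drawn uniformly in [0.1, 0.5] µS,
  onsets jittered within equal slots of the segment so the configured count
  is recoverable as distinct local maxima. Samples are clamped ≥ 0.
- **HR.** Per-segment level plus Gaussian jitter (SD 2 bpm) and a slow
  sinusoidal drift (1 bpm, 120 s period), clamped to [30, 220] bpm.

All randomness derives from one seed through named substreams per modality,
so a single modality regenerates identically regardless of the others.

What the generator does **not** emulate: eye-blink/EMG artifact morphology,
non-stationary band power within a segment, EEG cross-channel structure,
HRV dynamics or pulse waveforms, SCR habituation, device clock drift, or
missing samples. A green recovery test therefore establishes that the
pipeline's arithmetic is correct on signals with the stated spectral and
amplitude structure — not that the features are robust to every real-world
recording pathology.

## Numerical choices and degenerate inputs

- Index mapping uses `ceil((t − start)·rate − 1e-6 samples)`; boundaries on
  exact sample times are included on the left, excluded on the right.
- A segment shorter than one rejection epoch is evaluated as a single
  truncated epoch; a trailing remainder becomes a final shorter epoch.
- Welch windows shrink to the epoch length when an epoch is shorter than
  2 s; a band needs ≥ 2 PSD bins or configuration fails loudly.
- Annotation files must be strictly increasing in time; out-of-order rows
  are sorted with a warning, duplicates are an integrity error.
- Stream files declare modality/rate; a rate that contradicts the
  modality's acquisition default (256/1/4 Hz) is an integrity error unless
  a manifest explicitly overrides it.

## Known limitations

- Descriptive statistics only, by design: no inference, no multiple-testing
  machinery (the cohort analysis this package operationalises performs
  none).
- Absolute EEG magnitudes are not comparable to the original instrument's
  internal metric (undocumented); only relative/directional statements and
  the RMS convention are supported.
- The engagement rule set covers three sign patterns; `(↓,↓)` is left
  indeterminate rather than guessed.
- Single-channel (Cz) reporting by default; no ICA/ocular correction, no
  source localisation, no bands beyond theta/alpha/beta.
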