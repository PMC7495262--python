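# affectlab

Affective learning analytics from multimodal wearable biosignals.

`affectlab` is for researchers who instrument educational sessions — e.g. a
web-based virtual-patient (VP) case followed by a mixed-reality (MR) serious
game — with a small wearable rig: a 2-channel EEG amplifier (Fz/Cz, 256 Hz),
and a wrist wearable recording heart rate (HR, 1 Hz) and electrodermal
activity (EDA, 4 Hz). It turns those raw, independently started, UTC-stamped
streams into per-segment, per-participant and per-group affect metrics, and
maps metric shifts between a baseline session and an MR session to
rule-based engagement/arousal interpretations.

## The metrics

All streams share a UTC clock; sample *k* of a stream lives at
`start_utc + k/rate`, and every analysis window is half-open `[t0, t1)`.
Sessions are segmented at scenario events (VP node transitions, MR
interaction gestures); the stretch before the first event is the
orientation period and is excluded.

Per segment, on the Cz channel, after ±100 µV epoch-wise artifact
rejection:

- **band power** `P_b = ∫_b S_xx(f) df` — Welch PSD (Hann, 2 s windows,
  50 % overlap) integrated over the band, with θ = 4–8 Hz, α = 8–12 Hz,
  β = 13–21 Hz;
- **alpha amplitude** `A_α = √P_α` (µV, the RMS of the band-limited
  component; for a sinusoid of peak A this is A/√2);
- **theta/beta ratio** `TBR = P_θ / P_β` — rises with working-memory load
  and sustained attention;
- **HR and EDA** — arithmetic mean (and population SD, divisor *n*) of the
  raw samples in the window.

Segment means are averaged (unweighted) into one baseline value and one MR
value per metric per participant; groups aggregate with mean and population
SD; a shift table counts participants with `TBR↑`, `A_α↓`, `HR↑`, `EDA↑`
(strict inequalities, ties count as neither). Sign patterns of
`(ΔTBR, ΔA_α)` map to engagement labels (`↑,↓` → full cognitive engagement;
`↑,↑` → ambivalent engagement; `↓,↑` → guided disengagement; anything else
indeterminate), and `ΔHR` or `ΔEDA` above a dead-zone flags elevated
arousal. See `docs/methods.md` for assumptions and numerical choices.

A first-class synthetic-data module emulates the rig (band-limited EEG
carriers over 1/f noise with injected artifacts, tonic+phasic EDA, drifting
HR, staggered stream starts, event annotations) with full ground truth, so
every stage has a parameter-recovery test surface without any hardware.

## Worked example

The package ships the per-participant averages of an 11-participant pilot
cohort (4 medical students, 4 neurosurgeons, 3 postgraduates; one VP
baseline and one MR session each):

```python
from affectlab import group_summary, shift_table
from affectlab.affect_rules import classify
from affectlab.reporting import format_group_summary, load_reference_cohort

cohort = load_reference_cohort()
g = format_group_summary(group_summary(cohort))
print(g[g.metric == "theta_beta"].to_string(index=False))
print(shift_table(cohort).to_string(index=False))
```

```
       group     metric condition  mean   sd  n
     student theta_beta        VP  3.49 0.82  4
     student theta_beta        MR  3.23 0.94  4
postgraduate theta_beta        VP  2.33 0.26  3
postgraduate theta_beta        MR  2.56 0.62  3
neurosurgeon theta_beta        VP  2.59 0.96  4
neurosurgeon theta_beta        MR  2.96 1.55  4

       group  n  increased_theta_beta  decreased_alpha  increased_hr  increased_eda
     student  4                     2                1             0              4
postgraduate  3                     2                3             1              2
neurosurgeon  4                     3                1             3              4
       total 11                     7                5             4             10
```

Students' theta/beta ratio fell (3.49 → 3.23) while postgraduates' and
neurosurgeons' rose; 5 of 11 participants showed alpha suppression and 10
showed an EDA increase in MR. Classifying a group's mean deltas:

```python
gg = group_summary(cohort).set_index(["group", "metric", "condition"])
deltas = {m: gg.loc[("postgraduate", m, "MR"), "mean"]
             - gg.loc[("postgraduate", m, "VP"), "mean"]
          for m in ("theta_beta", "alpha_amp", "hr", "eda")}
print(classify(deltas).rationale)
```

```
theta/beta up, alpha down -> full_cognitive_engagement; HR down, EDA up -> arousal elevated
```

`affectlab reproduce-tables` prints the same tables plus an audit of the
as-reported summary cells: most reproduce from the per-participant data
after display rounding; the handful that cannot be derived from it are
listed as logged discrepancies rather than patched over.

## Command line

```sh
affectlab simulate --config cfg.yaml --out session_dir/ --seed 7   # synthetic session + ground truth
affectlab validate session_dir/                                    # formats, rates, annotation contract
affectlab analyze --manifest cohort.yaml --out results/            # participant/group/shift CSVs
affectlab reproduce-tables                                         # shipped cohort + reported-cell audit
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: (1) the cohort group tables, shift counts and the
reported-cell audit from the shipped per-participant data, and (2) a seeded
six-participant synthetic cohort pushed through file round trip,
segmentation, feature extraction, aggregation and affect classification,
checking that every planned shift direction is recovered. It writes the
(empty) JSON object of named numeric targets to `--out`.
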