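# wearpa

Minute-level wearable activity processing and physical-activity guideline
adherence statistics.

`wearpa` turns long-format minute records (timestamp, steps/min, heart rate,
optional device intensity label) plus a demographics table into per-participant
guideline-adherence scores and cohort-level statistics:

1. **Ingest** — strict CSV readers with row-level error accounting.
2. **Wear validation** — a fixed overnight 23:00–05:00 presumed-sleep window is
   excluded; a valid wear day needs ≥600 heart-rate minutes and ≥100 steps; a
   valid week (7-day interval anchored on January 1) needs ≥3 valid days;
   participants need ≥1 valid week.
3. **Intensity classification** — each minute is labelled
   sedentary/light/moderate/vigorous under three algorithms: cadence thresholds
   (60/100/130 steps/min), %HRmax thresholds (0.57/0.64/0.77 of 208 − 0.7×age),
   and the device's own labels.
4. **Adherence** — weekly weighted MVPA (moderate + 2×vigorous) averaged over
   valid weeks, scored against a 150 min/week target; a bout-restricted variant
   counts only MVPA inside ≥10-minute bouts tolerating ≤2 interruption minutes.
5. **Cohort statistics** — age-group assignment (most-valid-weeks rule), BMI
   averaging with outlier removal, grouped proportions with 95% Wald CIs,
   pairwise chi-square tests, univariate/multivariate logistic regression with
   VIF screening, paired McNemar method comparisons, and small-cell suppression
   (<20 participants) applied at display time.
6. **Synthetic cohorts** — a seeded generator emits minute-level cohorts with
   controlled demographics, activity archetypes, wear/HR noise, and analytic
   ground truth, so every stage is testable without any real data.

## CLI

```bash
# generate a synthetic cohort (presets: clean | noisy | divergent)
wearpa simulate --out sim/ --n 50 --days 21 --seed 1 --preset noisy

# run the full pipeline
wearpa process --minutes sim/minutes.csv --demographics sim/demographics.csv \
    --bmi sim/bmi.csv --out out/

# recompute grouped summaries / model fits from written tables
wearpa stats --adherence out/adherence.csv --participants out/participants.csv \
    --out stats/

# paired McNemar comparisons between the three algorithms
wearpa compare-methods --adherence out/adherence.csv --out compare.csv
```

`process` writes `adherence.csv`, `participants.csv`, `group_summaries.csv`
(suppressed cells hold the literal token `SUPPRESSED`), `model_fits.csv`,
`method_comparison.csv`, and a `manifest.json` with the effective config and
stage-by-stage attrition counts. Configuration comes from a YAML file
(`--config`) with `--set key=value` overrides; defaults reproduce the published
analysis parameters.

## Input formats

- **Minutes** (`minutes.csv`): `person_id, datetime, steps, heart_rate,
  device_label`. One row per observed device-minute; absent minutes are
  nonwear. Timestamps are naive local clock time at minute resolution.
  `device_label` ∈ {sedentary, lightly_active, fairly_active, very_active} or
  empty.
- **Demographics** (`demographics.csv`): `person_id, sex, race_ethnicity,
  birth_date` with strict vocabularies.
- **BMI** (`bmi.csv`, optional): long table `person_id, bmi_date, bmi_value`.

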