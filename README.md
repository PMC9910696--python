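# posture-ensemble

Ensemble-averaging imputation and trunk-angle posture classification for
24-h wearable accelerometer recordings.

## The problem

Continuous recordings of patient activity over 24 h or more — typically a
chest-worn tri-axial acceleration sensor streaming to a phone — lose data:
batteries die, wireless links drop, garments are changed. Classical
imputation (multiple imputation, ML models) needs many subjects or many
covariates; a lone posture label series from one person offers neither.

If a subject's daily routine is stable over a short measurement session,
the same time of day on *another* measurement day is an excellent stand-in
for a lost epoch. This package implements that idea for **categorical**
time series: instead of averaging label values (meaningless), it averages
the **period of occurrence** of each posture across days.

## The method

Postures are classified per 1-min epoch into three states — `reclining`,
`sitting_or_standing`, `walking` — from the trunk angle

θ(t) = ±(180/π)·arccos(a_z(t)/|a(t)|),  signed by a_y(t),

where |a(t)| is the acceleration norm; the upright band is
35° ≤ θ ≤ 143° (boundaries estimable per subject from the valleys of the
trunk-angle occurrence histogram), and an upright epoch with detected
steps is `walking`.

Given N measurement days, the ensemble-averaged period of posture *i* at
time-of-day epoch *t* is

P_i(t) = N_i(t) / (f · N(t)),

with N_i(t) the number of valid days showing posture *i* at *t*, N(t) the
number of valid days at *t*, and f the posture sampling rate (1/min by
default, so P_i(t) is minutes per epoch). An epoch is unimputable only
when it is lost on **all** days — so for independent losses at rate r per
day, the residual missing rate after a 2-day session is about r².
Daily totals are T_i = Σ_t P_i(t).

The package also ships the quantitative analogue (per-epoch mean, e.g.
for heart rate), the conventional baseline (keep the day with the least
missing data), an MCAR block-loss injection harness for validation, a
synthetic inpatient-session generator, and 24-h visualisations.

## Worked example

```python
import numpy as np
from posture_ensemble import (
    LossSpec, default_schedule, ensemble_categorical, conventional_select_day,
    inject_losses, missing_rate, simulate_posture_days, total_periods,
)

# a synthetic 2-day inpatient session, then ~6% random 1-min losses per day
days = simulate_posture_days(default_schedule(seed=3), n_days=2)
rng = np.random.default_rng(0)
spec = LossSpec(target_rate=0.06, block_length=1)
lossy = [inject_losses(d, spec, rng=rng) for d in days]

ens = ensemble_categorical(lossy)
print(f"reference (no imputation): {missing_rate(lossy):.2f}% missing")
print(f"conventional (best day):   {missing_rate(conventional_select_day(lossy)):.2f}% missing")
print(f"ensemble averaging:        {missing_rate(ens):.2f}% missing")
totals = total_periods(ens)
for lab, minutes in totals.minutes.items():
    print(f"{lab:>20}: {minutes:7.1f} min  ({100 * totals.ratios[lab]:.2f}%)")
```

prints

```
reference (no imputation): 5.97% missing
conventional (best day):   5.97% missing
ensemble averaging:        0.42% missing
           reclining:   973.5 min  (67.89%)
 sitting_or_standing:   456.5 min  (31.83%)
             walking:     4.0 min  (0.28%)
```

Both days lost ~6% of their epochs, so discarding a day cannot help; the
ensemble is missing only where the two loss masks intersect (0.42% here,
close to the 0.36% expected from 0.06²). The totals are the imputed 24-h
posture budget in minutes and its ratios over the measured period.

## Command line

```sh
posture-ensemble synth --out-dir fixtures --sessions 1 --days 2   # synthetic CSVs
posture-ensemble classify fixtures/*_accel.csv --out-dir out      # accel -> posture
posture-ensemble impute out/*_posture.csv --out-dir out           # ensemble + totals
posture-ensemble simulate-loss --synthetic-sessions 10 --out-dir exp
posture-ensemble report out/*_posture.csv --out-dir figs          # 24-h figures
```

All commands accept a flat YAML config (`--config`); explicit flags win.

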