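# Methods

## Posture model

Three posture states are distinguished: `reclining` (prone and supine
merged), `sitting_or_standing`, and `walking`. The classifier assumes a
chest-worn tri-axial sensor whose measured acceleration at rest is
dominated by gravity, so the sensor's declination in the sagittal plane —
the trunk angle — is recoverable from the acceleration direction:

θ = (180/π)·arccos(a_z/|a|) if a_y ≥ 0, else −(180/π)·arccos(a_z/|a|),

with |a| = √(a_x² + a_y² + a_z²). θ is scale-invariant and undefined at
|a| = 0 (such samples are marked invalid and excluded). The static
postures are separated by two thresholds: inside the upright band
[35°, 143°] the subject is sitting or standing; everything outside —
including all negative (prone-side) angles — is classed reclining. The
mapping of the sign convention to prone vs. supine anatomy is a package
decision, not something the angle alone determines; since `reclining`
merges both, nothing downstream depends on it.

Walking is an overlay on the upright state. A rules-based step detector
operates on the acceleration norm: the norm is detrended by a centered
1-s moving average, peaks above 0.1 g are extracted, and a run of ≥ 4
peaks whose successive intervals lie in [0.3, 2.0] s (the plausible human
cadence band) marks a walking span. These constants are this package's
defaults, configurable via `WalkingRule`; step detection while θ is
outside the upright band is ignored. The detector is deliberately simple
— no frequency-domain features, no autocorrelation — because the walking
state only needs to be separable from static postures, not gait-graded.

Per-sample labels are aggregated to the epoch grid (1-min epochs anchored
at local midnight, half-open) by plurality; ties break by specificity
(walking > sitting_or_standing > reclining). An epoch is `missing` when
it holds fewer than `min_fraction` (default 0.5) of its expected
`nominal_rate × epoch_length` samples, or no valid samples at all. The
0.5 default is a package construct: epoch-level missingness has to be
defined somewhere, and half the expected 25-Hz samples is a conservative
floor for a plurality vote over ~750 samples.

### Threshold estimation

Long recordings of static postures produce well-separated modes in the
trunk-angle occurrence histogram; the boundaries are taken at the
valleys. `estimate_thresholds` smooths a 1°-bin histogram with a 5-bin
centered moving average and returns the minimum-count bin center within
each search range (defaults [15°, 60°] and [120°, 165°], bracketing the
canonical 35°/143° with margin). Ties resolve to the lowest angle; a flat
range yields its midpoint with a warning. Both per-session estimation and
the fixed 35°/143° defaults are supported, since cohort-level thresholds
may not fit an individual (elderly patients, hyperkyphosis, sloped beds).

## Ensemble averaging

For a session of N measurement days sharing one epoch grid, the
ensemble-averaged period of posture i at time-of-day epoch t is

P_i(t) = N_i(t) / (f · N(t)),

where N_i(t) counts valid days showing posture i at t, N(t) = Σ_i N_i(t)
counts valid days, and f is the posture sampling rate. P_i is reported in
minutes (f⁻¹ = epoch length), so Σ_i P_i(t) = f⁻¹ at every epoch with
N(t) ≥ 1 and P_i(t) ∈ [0, f⁻¹]. Epochs lost on all days are the only
unimputable ones; the post-imputation missing set is exactly the
intersection of the per-day missing sets. The quantitative analogue
(`ensemble_quantitative`) takes the per-epoch mean over valid days,
passing a single valid day's value through unchanged.

Daily totals are T_i = Σ_t P_i(t) over epochs with N(t) ≥ 1; unimputable
epochs are excluded, not redistributed, so Σ_i T_i equals the epoch
length times the number of imputable epochs. Posture ratios are taken
over Σ_i T_i (the measured total), which keeps them comparable across
sessions with different residual missingness.

The ensemble output keeps the fractional P_i per epoch — that is the
method's value — but a hard-label view (argmax_i N_i(t), ties by the same
specificity priority) is provided for CSV export and for the population
figure, which needs one label per epoch per session.

Two baselines frame the method: *reference* (no imputation; for a
multi-day session the mean of the per-day missing rates — the neutral
reading of a 48-h missing fraction on a 24-h grid) and *conventional*
(discard all but the day with the fewest missing epochs; ties to the
earliest day). The dominance ordering
ensemble ≤ best day = conventional ≤ reference holds for every input by
construction, and the suite asserts it on randomized sessions.

## Loss-injection validation

`inject_losses` masks ⌊rate × epochs_per_day / block_length⌋ ×
block_length epochs as missing, placed as non-overlapping fixed-length
blocks (1 min by default), uniformly at random and independent of
posture and time of day (MCAR). Placement samples the block starts
uniformly over all non-overlapping configurations via the standard
bijection with unordered slot choices, which keeps the masked count
exact and cannot dead-end at high densities. Pre-existing missing epochs
stay missing.

`run_imputation_comparison` reports per-session missing rates for the
three methods and group medians/quartiles with sessions binned by their
reference rate (default edges: the 25th/50th/75th percentiles of the
input sessions' reference rates, rather than any hard-coded cohort
values). `run_ratio_stability` sweeps injection rates over complete
sessions with replicate draws and tracks the totals T_i and ratios
against the session's no-loss values. Hypothesis testing is intentionally
out of scope; the tidy per-group records are the interface to external
statistics tools.

Under MCAR the ratios are stable essentially by design — losses hit all
postures proportionally — and the suite checks the medians stay within
1 percentage point of the no-loss ratios for the two dominant postures at
rates up to 25%. Time-of-day-correlated (MNAR) dropout would break this
and is deliberately not a default anywhere.

## Synthetic sessions

The generator emulates a convalescent-ward routine, not free-living
behaviour. `default_schedule` uses time-of-day blocks — reclining
probability 0.97 from 21:00 to 6:00, dips to 0.25 in mealtime hours
around 8:00/12:00/18:00, 0.6 otherwise — and a persistence parameter
(default 0.9) giving mean dwell times of ~10 min; because a
non-persistent step redraws from the block distribution, the within-block
stationary distribution equals the block distribution for the static
postures. Walking is drawn as bouts: a fresh draw of `walking` (per-block
initiation probability, 0.025 in daytime blocks) fixes the next
`walk_bout_length` = 3 epochs, so the realized walking share is about
(1 − persistence) × initiation × bout length ≈ 0.75% of daytime epochs,
i.e. roughly 0.4–0.5% of the 24-h day — the order observed in ward
cohorts. Realized session-level ratios are therefore roughly 70/30/0.4
reclining/upright/walking.

Acceleration is rendered per epoch: samples point along
(0, sin θ, cos θ) for the label's mean angle (reclining 10°, upright 90°,
optionally a supine share at 170°), with per-sample Gaussian angular
jitter (sd 8°) and per-axis sensor noise (sd 0.03 g); walking epochs
modulate the norm by a 0.3-g sinusoid at 2 Hz cadence, inside the
detector's cadence band. These defaults separate the angle regimes by
more than 3 jitter standard deviations from the 35° boundary, so
closed-loop label recovery (render → classify) exceeds 99% of
non-missing epochs — the generator's acceptance surface. What the
generator does **not** emulate: postural transitions inside an epoch,
sensor re-orientation and garment shift, non-gait norm disturbances
(transfers, wheelchair propulsion), or MNAR losses; passing closed-loop
tests therefore bounds pipeline self-consistency, not field accuracy on
real patients.

All generators take explicit seeds or `numpy` Generators; fixture sets
regenerate byte-identically from a seed, and the fixture manifest records
the exact injected-loss epochs per day.

## Numerical and design notes

- Epoch grids must divide 86400 s; all cross-day alignment is by epoch
  index within the 24-h clock. Cross-midnight acceleration files are
  rejected rather than split (ward data are day-segmented).
- Malformed CSV rows are skipped with a logged count rather than failing
  the file; an all-bad file raises.
- `arccos` arguments are clipped to [−1, 1] to absorb rounding at
  |a_z| ≈ |a|.
- Valley search ties (including exactly-zero plateaus) resolve to the
  lowest angle; this biases estimates toward the lower edge of a flat
  valley by at most half its width, which is why the recovery tests
  assert ±5° rather than bin-level precision.
- Experiment problem sizes in the test suite (sessions of 2 × 1440
  epochs, 50 replicate loss draws, 50-session batches) were chosen as the
  smallest batches at which the medians of interest are stable across
  seeds.
- The CLI is a thin layer over the library; every run writes a JSON/CSV
  summary next to its figures so that figures are regenerable from saved
  tables alone.

## Known limitations

- The walking detector's constants are package defaults, not a validated
  gait algorithm; swap in a dedicated step detector for clinical use.
- The reference missing rate of a multi-day session is defined as the
  mean of per-day rates; max or pooled-48-h conventions would shift the
  baseline (not the ensemble or conventional results).
- Ensemble averaging presumes routine stability across the session's
  days; irregular events, rapid recovery, or weekday/weekend contrasts
  violate that premise and are out of scope here.
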