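# Methods

This note records how `caninescore` models the problem, which knobs exist,
what the defaults are and why, and where the design was genuinely open.

## Problem setting and assumptions

A collar-mounted IMU (tri-axial accelerometer, ±2 g; tri-axial gyro,
±2000 °/s; 50 Hz) observes a dog continuously. Four behaviors carry the
clinical signal: scratching, licking, swallowing and sleeping. The model
assumes (i) behaviors appear as episodic, band-separable motion patterns;
(ii) hourly episode counts (daily hours, for sleep) are stable enough per
dog that fixed ordinal bins are meaningful; (iii) symptom patterns — not
whole behavioral profiles — are what associate with disease.

## Classification tables

Ordinal bins per behavior (level 0 = normal), shipped as a versioned JSON
resource (`caninescore/data/thresholds.json`) and overridable:

| behavior | level 0 | level 1 | level 2 | level 3 |
|---|---|---|---|---|
| scratch (events/h) | average 0–52 | sometimes 53–119 | often 120–299 | serious ≥ 300 |
| lick (events/h) | average 0–7 | sometimes 8–19 | often 20–43 | serious ≥ 44 |
| swallow (events/h) | average 31–59 | below average 0–30 | above average ≥ 60 | — |
| sleep (h/day) | deep sleep ≥ 12 | a little bit of trouble 3.6–12 | strikingly little < 3.6 | — |

Decisions embedded here:

* **Top-bin closure.** Printed open bins ("over N") would leave the single
  integer N unassigned; they are closed as ≥ N so the bins are total on the
  non-negative integers.
* **Swallowing is two-tailed.** Both the low tail (digestive/esophageal)
  and the high tail (water intake, kidney) are abnormal; "average" alone is
  level 0.
* **Sleep bands.** The short-sleep cutoffs are read as reductions relative
  to the 12 h deep-sleep floor: 30 % of 12 h = 3.6 h separates "a little
  bit of trouble" from "strikingly little". Three labels exist, so three
  bands are implemented (≥ 12 / [3.6, 12) / < 3.6); the alternative 20 %
  cutoff (9.6 h) is retained in the resource (`alt_trouble_cutoff_h`) for
  users preferring a four-band reading.
* **Weight classes.** Small < 7 kg, medium 7–15 kg (both boundaries
  inclusive to medium, as printed), large > 15 kg; life stages 0–2 / 3–7 /
  8–10 years, ages above 10 rejected (study inclusion criterion).

## Synthetic data generator

The generator emulates the *study conditions*, not biomechanics:

* **Events.** Scratch/lick/swallow starts follow a homogeneous Poisson
  process at the breed's hourly rate over awake time; episode durations are
  Gaussian (scratch 1.0 ± 0.3 s, lick 4.0 ± 1.0 s, swallow 0.5 ± 0.1 s,
  floored at 0.1 s). Episodes are rejection-thinned so no two overlap; at
  default rates the duty cycle stays below ~5 %, so the thinning bite is
  negligible at the scales the tests probe. One contiguous sleep block
  occupies the last `sleep_hours` of each 24 h day.
* **Rates.** Per-breed defaults are the study's published averages
  verbatim (e.g. retriever 122 scratches/h and 9.7 h sleep; husky 42/h and
  12.5 h), in `BREED_RATE_SPECS`.
* **Waveforms** (invented, config-exposed in `WaveformConfig`): scratch =
  4–6 Hz oscillation, 0.8 g on accelerometer plus 300 °/s on gyro; lick =
  2–3 Hz, 0.3 g; swallow = Gaussian pulse, 0.9 g, σ = 40 ms; sleep = noise
  damped to 10 %. Baseline noise is white Gaussian (default 0.05 g accel;
  gyro noise = 100 × accel noise in °/s). SNR here means waveform amplitude
  over baseline noise sd.
* **Labeled profiles** (`make_training_set`). Healthy instances sit in the
  normal envelope: scratch/lick level 0 (p = 0.7) or 1 (p = 0.3), swallow
  in its single normal band, sleep level 0 (p = 0.8) or 1 (p = 0.2).
  Disease instances carry the skin pattern (scratch and lick at level 2–3)
  or the digestive/kidney pattern (swallow at level 1–2) over an otherwise
  normal background. Numeric values are drawn uniformly from each bin's
  plateau (clear of the fuzzy crossover zones), since they stand for a
  category's representative observations. Note the healthy envelope keeps
  swallowing at level 0: its level 1 ("below average") is itself the
  digestive flag, so a generator that put healthy dogs there would make the
  two label classes overlap by construction.

What the generator does *not* emulate: real signal morphology, posture and
gait artifacts, fragmented sleep (a fragmentation of the single block can
be emulated by constructing event logs directly), breed-specific waveform
differences, sensor drift. Passing synthetic-recovery tests therefore shows
the pipeline is self-consistent and correctly wired — not that it matches
any particular hardware's field accuracy.

## Event detection

The study's own detector is undisclosed; this package uses the simplest
detector that is verifiable against the generator: a sliding-window
band-energy classifier (1 s windows, 50 % overlap). Per window, a cascade:

1. **stillness** — pooled accel sd < 0.02 g; contiguous still spans ≥ 20 min
   count as sleep (shorter naps are ignored; config `sleep_min_s`),
2. **energy gate** — window variance must exceed 3 × the stream's noise
   floor (median window variance over non-still windows),
3. **edge guard** — windows with > 70 % of their energy in the first or
   last fifth hold only the sliver of an episode that leaks over the window
   edge; the neighboring window covers it, so they are skipped,
4. **swallow** — impulsive windows: crest factor ≥ 3.2, a *single*
   contiguous above-half-peak run (an oscillation sliver shows several
   lobes), support ≤ 20 % of samples, peak ≥ 0.25 g located in the central
   70 % of the window,
5. **scratch / lick** — ≥ 40 % of non-DC spectral energy in 3.5–7 Hz or
   1.5–3.2 Hz respectively.

Same-label windows merge into events across gaps ≤ 0.6 s. Counts normalize
per hour of recording, rounded to the nearest integer with ties to even;
sleep sums per 24 h of recording. The cascade order matters: the spike test
precedes the band tests because a Gaussian pulse carries enough 1.5–3.2 Hz
energy to masquerade as licking, while the single-run and edge guards keep
oscillation slivers from masquerading as spikes.

Filtration (`filter_stream`) removes flat-line runs (all six channels
frozen ≥ 2 s — sensor non-response) and saturated samples, plus a one-window
guard margin before and after each anomalous run, and reports the surviving
fraction as coverage. An entirely filtered stream is flagged empty, not
raised. Detection requires the sample rate to be at least twice the highest
detection band (configuration error otherwise); noise sd must exceed the
stillness threshold or awake baseline would read as sleep.

## Fuzzy associative memory

* **Input fuzzification.** One Ruspini partition per behavior, aligned to
  the ordinal bins: trapezoidal sets whose plateaus span the bins, with
  linear crossovers of halfwidth 1 event/h (counts) or 0.25 h (sleep)
  centred on the bin boundaries. 14 components in all (4 + 4 + 3 + 3).
  Memberships of neighboring sets sum to 1 everywhere.
* **Storage.** Kosko correlation-minimum encoding:
  `M[i,j] = max over pairs of min(a_i, b_j)` — idempotent and monotone.
  Training pairs associate exemplars with a risk label (low/high output
  singleton). Disease-labeled profiles are stored with non-symptomatic
  components masked to zero: the stored pattern is the symptom pattern
  (scratch/lick ≥ *often*, swallow outside its normal band, sleep
  *strikingly little*). This mirrors how clinical records associate
  symptomatology — not the patient's unremarkable background behavior —
  with a disease, and it is what keeps a superimposed max–min memory
  discriminative: stored whole, every normal-band component would acquire a
  full-strength high-risk association from the disease exemplars'
  backgrounds, and recall would return the same output for every profile.
* **Recall.** Max–min composition `out_j = max_i min(v_i, M[i,j])`,
  defuzzified by the centroid of the output sets clipped at their recalled
  memberships (2001-point grid on [0, 1]). An all-zero input recalls risk 0
  with a `no_evidence` flag. Attribution reports each behavior's largest
  contribution to the winning output set, ties between sets resolving
  toward the higher-risk set.
* **Output partition.** Three triangular sets on [0, 1]: low (0, 0, 0.3),
  medium (0.1, 0.5, 0.9), high (0.5, 1, 1). The low set is deliberately
  narrower than the high set. Any profile containing a symptom *and* a
  normal background recalls both the healthy exemplar (low) and a symptom
  rule (high) at full strength; with symmetric supports that combination
  would defuzzify to exactly 0.5 — a knife-edge against the 0.5 decision
  threshold. The chosen supports give closed-form centroids ≈ 0.100 (low
  alone), ≈ 0.558 (low and high together) and ≈ 0.833 (high alone), so
  symptom-bearing profiles land strictly above threshold and clean profiles
  strictly below.
* **Reference model.** The shipped default memory is stated
  deterministically rather than sampled: one healthy exemplar (the full
  normal envelope) → low, plus one rule per symptom component → high. This
  is the fixed point that training on a large balanced clinical sample
  converges to. `train` builds the same structure from data; per-breed or
  per-size-class matrices are supported via the model's class-keyed matrix
  map (the breed-specific adaptation is structural only — published bins
  exist only as one global table).
* **Homogeneous layer.** `update_homogeneous` stores a profile associated
  with itself (min outer product, max-merged), so recurring normal patterns
  reinforce the dog's baseline; max-encoding makes the update idempotent
  and monotone.

## Health Score

The published scoring formulas are typographically garbled (summation
indices collide; the weight-update expression prints as a ratio of
near-identical sums). The implementation therefore declares an
interpretation (`ScoreConfig.interpretation`) that preserves every printed
ingredient — per-behavior weights `w_a..w_d`, sub-scores, a history
average, and an n over n−1 drift ratio — with coherent semantics, each
component separately testable:

* **Sub-scores** (config-exposed; chosen so all-normal → 10, all-worst ≤ 2):
  scratch/lick levels 0..3 → 10, 7, 4, 1; swallow 0..2 → 10, 5, 5; sleep
  0..2 → 10, 6, 2.
* **Base** = Σ w_k x_k with weights normalized to 1 (defaults 0.25 each —
  the study never states its weights).
* **Risk penalty**: base × (1 − 0.5 · risk), factor config-exposed.
* **History smoothing**: with history present, (penalized + previous
  unrounded score)/2; under constant input the sequence converges to the
  current input's own score (fixed point of the averaging).
* **Display**: clamped to [1, 10], rounded half-up; the unrounded value
  feeds a (⌊final−1⌋, ⌈final+1⌉) ∩ [1, 10] range, shown alongside the point
  value so fluctuating behavior is not over-read.
* **States**: ≤ 5 examination required, ≥ 6 healthy.
* **Weight drift** (`update_weights`): per behavior,
  r_k = mean(x_k over all n entries) / mean(x_k over the first n−1);
  weights divide by r_k and renormalize. The division is applied uniformly
  (not only to r < 1): worsening behaviors gain weight and improving ones
  shed it, which keeps the update scale-free and order-preserving.

## Agreement evaluation

Percent agreement = 100·(a+d)/(a+b+c+d) over a 2×2 table; permutation-
invariant and symmetric under swapping the positive convention. The
published comparison is evaluated at the breed-group level (8 units) — the
only reading under which the published total is arithmetically consistent,
the per-dog sub-rows of the published table being internally contradictory.
A per-dog mode is available for user data (`confusion` on any pair list).
Output is formatted to one decimal; the internal value is unrounded.

## Numerical choices and degenerate inputs

* Centroid defuzzification: 2001-point uniform grid; the independent test
  oracle integrates by trapezoid rule on its own 4001-point grid with its
  own membership formulas (agreement tolerance 5 × 10⁻³).
* Count rounding: nearest integer, ties to even (`round`).
* Score rounding: half-up (`floor(x + 0.5)`), after clamping.
* Empty training sets, empty pair lists, unnormalized weights, out-of-range
  sleep/ages/scores and unknown config keys raise `ValueError`; sleep
  passed to the count categorizer raises `TypeError`; an entirely filtered
  stream is flagged, not raised.
* All randomness flows through `numpy.random.default_rng(seed)`; compound
  commands derive child seeds deterministically from the master seed.

## Test and acceptance problem sizes

Synthetic-recovery checks use twenty 12-minute replicates at 50 Hz
(Poisson rates 120/60/90 events/h, noise 0.03 g ⇒ SNR ≥ 10 for every
template) for detection, and 600 training / 300 held-out labeled profiles
for the memory; the goodness-of-fit check uses 200 one-hour replicates at
30 events/h. These sizes give the statistics stable sub-percent standard
errors while keeping the whole suite fast.

## Known limitations

* The detector is tuned to the generator's waveform families; real collar
  data would need template re-estimation and validation.
* Thresholds are one global table; true breed-specific reference points
  would change the bins, not the machinery.
* The memory is a flat FAM; no gradient-trained neuro-fuzzy hybrid or
  hierarchical fuzzy structure is attempted.
* Sub-score values, the risk-penalty factor and the behavior weights are
  declared interpretations, config-exposed rather than clinically fitted.
* The Health Score monitors status; it does not diagnose or predict
  disease.
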