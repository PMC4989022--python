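# Methods

This note documents the models, estimators and design choices behind
`fattaste`, in the spirit of a statistical methods appendix.

## Dilution ladders and units

A ladder is a geometric concentration series: level *i* has
`c_i = c_0 · 10^(i·s)` with log step `s = 0.25` decades by default. Units
are dual: millimolar and mass-per-volume percent (g/100 mL), related by
`mM = %w/v · 10⁴ / MW`. The default molar mass 282.46 g/mol is oleic acid
(C₁₈H₃₄O₂); it is configurable for other fatty acids. Ladders are
canonical in the unit their bottom level was specified in; published
endpoint values that disagree in the last digit are treated as rounded
displays of the same series.

Built-in ladders: 9 levels from 0.0088 %w/v (0.31–31 mM, 2.0 decades) and
12 levels from 0.0028 %w/v (0.098–56 mM, 2.75 decades).

## The adaptive 3-AFC staircase

Each trial is a triad (one target, two controls); chance is 1/3. Rules
(`StaircaseConfig` defaults):

* start at the second-lowest level (`start_index = 1`);
* miss → up 2 levels (`pre_reversal_up = post_reversal_up = 2`);
* hit → down 1 level (`down_step = 1`);
* stop when at least 4 reversals (direction changes of the response
  sequence) have occurred *and* the current level has been answered
  correctly on its last 3 visits (`stop_correct_at_level = 3`);
* safety stops: 3 consecutive clamped trials at either ladder end
  (`boundary_patience`, recorded as `ceiling`/`floor`) or 60 trials
  (`max_trials`).

Two choices deserve justification because the verbal protocol they come
from is ambiguous:

**Up-step after the first reversal.** An up-Δ/down-1 staircase
equilibrates where the probability of descending equals the probability
of ascending × Δ, i.e. at P(correct) = Δ/(Δ+1). With Δ = 1 that is 0.5 —
uncomfortably close to the 1/3 guess rate, so a guessing assessor hovers
with weak restoring force and frequently satisfies the stopping rule near
the ladder bottom; in simulation this produced 15–25 % gross (>2-step)
threshold errors. With Δ = 2 the equilibrium is P = 2/3, exactly the
midpoint of the 3-AFC psychometric function, and guessing produces a net
upward drift of one level per trial. The package therefore keeps the
two-level ascent throughout; Δ = 1 remains available via
`post_reversal_up=1`.

**"Repeatedly selected the correct sample at one concentration."** In a
descending staircase two corrects are never consecutive *trials* at one
level, so the rule is read as consecutive *visits*. Two correct visits
(chance 1/9) terminate too easily by luck and can never constitute a
significant true positive under the α = 0.05 tail rule (P(2/2 | guessing)
= 1/9 > 0.05); three correct visits (1/27 ≤ 0.05) make the stopping rule
exactly as strict as the level classification, so a criterion stop always
leaves a classifiable anchor. Both readings are supported; 3 is the
default.

The engine is deterministic given the response sequence; all randomness
lives in observer callables.

## Threshold estimation

Per-level tallies (sets presented `n`, correct `k`) are classified:

* `tail` (default): true positive iff the exact binomial tail
  P(X ≥ k | n, 1/3) ≤ α (default 0.05) — the operational meaning of
  "significantly greater than expected by chance";
* `fraction` (alternative): true positive iff percent correct exceeds the
  chance percentage 100/3. This rule admits single lucky answers
  (1 of 1 = 100 %) as true positives and is kept only for comparison;
* levels with `k = 0` are `incorrect`; correct-but-not-significant levels
  are `false_positive` and are ignored as threshold anchors.

The detection threshold is the geometric mean of the lowest true-positive
concentration and the highest concentration below it classified
incorrect/false-positive (`incorrect_scope="below_tp"`; a `"global"`
variant anchors above the highest miss anywhere). Censoring: a true
positive at the bottom with nothing below → `censored="low"`, imputed
`c_bottom · 10^(−s/2)`; no true positive anywhere → `censored="high"`,
imputed `c_top · 10^(+s/2)`. Imputation half a step beyond the ladder
keeps censored participants groupable; the flag is always propagated.

Estimator properties (enforced by tests): flipping any miss to a hit
never raises the estimate; uncensored estimates lie strictly between
their anchors; on 500 simulated observers (study-sized ladder, σ = 0.25,
lapse 0.01) the median |log₁₀ error| is ≈ 0.16 ≤ 0.25 (one ladder step)
with < 5 % gross errors (>2 steps) among uncensored estimates.

## Sensitivity grouping

The ladder's log span is split into three equal parts; cuts are computed
on the %w/v scale and converted to mM with the ladder's molar mass
(mathematically identical to computing them in mM). Assignment uses the
exact cuts. Reported boundaries additionally follow the display
convention of rounding the %w/v cut to two significant figures before
conversion — on the nine-level ladder 0.041 %w/v → 1.45 mM and
0.19 %w/v → 6.73 mM (exact values 1.446 and 6.712 mM). Thresholds below
the lower cut are `high` sensitivity, above the upper cut `low`, else
`medium`. A quartile-based alternative exists but is unstable for small
cohorts and is not the primary method.

## Discrimination statistics

For k of N correct with guess rate g (1/2 for 2-AFC, 1/3 for 3-AFC):

* p value: one-sided exact binomial tail P(X ≥ k | N, g). Forced-choice
  tests are inherently one-sided;
* proportion of discriminators: pd = (pc − g)/(1 − g), reported as-is
  (may be negative below chance; optional floor at zero for display);
* Thurstonian d′ (2-AFC only): pc = Φ(d′/√2); pc ∈ {0, 1} maps to ±∞ as
  an explicit infinite-sensitivity signal. d′ for other protocols is out
  of scope;
* post-hoc power: exact-binomial critical value c = min{c : P(X ≥ c | N,
  g) ≤ α}, power = P(X ≥ c | N, pc). A normal-approximation mode exists
  for cross-checking but the exact form is authoritative;
* sample size: smallest N whose exact power at
  pc = g + pd·(1 − g) reaches the target (the exact power curve is
  sawtoothed in N; the first crossing is returned).

Published tables of this kind often carry ±1 rounding in their last digit
(legacy software used tabulated d′); comparisons in the test suite allow
exactly that.

## Ratings model and inference

Records are long-format (participant, modality condition, fat level,
score ∈ [0, 100]). Conditions: `taste` (mouthfeel + odour masked),
`taste_odour` (mouthfeel masked), `taste_mouthfeel` (nose clip),
`overall` (no masking).

* `cell_summary`: n, mean, SEM (= sd/√n; undefined and flagged at n = 1);
* `rm_anova`: one- or two-way repeated-measures ANOVA via pingouin with
  the Greenhouse–Geisser correction **always** applied (no sphericity
  pre-test — the conservative fallback is used unconditionally); reported
  df are ε-corrected. With a between-subjects factor, a mixed design with
  one within factor is fitted; fuller mixed-factorial machinery is out of
  scope. Incomplete participants are removed listwise with a warning;
* `bonferroni_pairwise`: paired t tests on all level pairs, p × m capped
  at 1; all-zero differences give p = 1 exactly.

Verification is by oracle equivalence (a hand-computed sums-of-squares
decomposition on a 3-subject 2×2 toy dataset) and by simulation
calibration: under a null fat effect the GG-corrected fat test's
empirical type-I error over 1000 replicates of a 51 × 7 design is 0.039,
inside [0.035, 0.065] at nominal 0.05.

## Synthetic observers

The generator encodes the assumptions the analysis makes:

* detection: P(correct | c) = (1 − λ)·[g + (1 − g)·Φ((log₁₀c − μ)/σ)] +
  λ·g — a cumulative-normal psychometric function in log concentration
  (standard for chemosensory thresholds and matched to the log-spaced
  ladder; logistic link available), guess rate g = 1/3, lapse λ answered
  at chance. Defaults σ = 0.25 log units (one ladder step) and λ = 0.01
  (nonzero so false-positive classification paths are exercised). Cohort
  locations μ default to uniform over the middle six ladder levels —
  thresholds measurable without immediate censoring;
* 2-AFC panels: n_correct ~ Binomial(N, Φ(d′/√2)) from a true d′ ladder;
* ratings: score = clip(b₀ + b_fat·log1p(fat %) + modality offset +
  subject effect + noise, 0, 100). Defaults (b₀ = 8, b_fat = 5, offsets
  0/4/6/10 for taste/taste+odour/taste+mouthfeel/overall, subject sd 6,
  noise sd 8) put the no-fat baseline near "weak", add ≈ 15 points from
  0 % to 20 % fat, and make unmasked mouthfeel/odour cues additive
  enhancements — the qualitative structure the rating analysis assumes;
* covariates (BMI, energy, fat intake) default to **zero** association
  with sensitivity, with a configurable slope for power exploration.

Every generator is a pure function of its parameters and an explicit
seed. What the simulations do *not* emulate: sequential context/fatigue
effects, scale-use idiosyncrasies beyond an additive subject effect,
correlated lapses, or real threshold population shapes — passing recovery
tests therefore demonstrates internal consistency of procedure +
estimator, not field validity on human data.

## Numerical choices and problem sizes

Exact binomial tails use scipy's survival function (no normal
approximation anywhere in the primary path). Staircase clamping absorbs
ladder overflow; clamp persistence (3 trials) triggers censoring-aware
termination. Geometric means are computed in linear concentration space;
group cuts in log space. Simulation-based checks use 500 observers
(threshold recovery), 1000 replicates (ANOVA calibration) and 10⁴
assessors (panel consistency) — sizes at which Monte-Carlo error is well
below the tolerances asserted.

## Known limitations

* The threshold estimator inherits the short-run noise of the rapid
  staircase: ≈ 3–5 % of uncensored estimates err by more than two ladder
  steps, and estimates carry a small downward bias (the lowest
  true-positive anchor sits at or below the oscillation zone).
* Censored-high runs (~10 % at default settings) are reported, not
  recovered; there is no latent-variable model for them.
* d′ is implemented for the 2-AFC identity only.
* The mixed ANOVA handles one within × one between factor; no
  mixed-effects (multilevel) machinery.
* The 0–100 truncation of simulated ratings slightly compresses variance
  near the scale ends; null-calibration uses mid-scale baselines where
  truncation is inert.
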