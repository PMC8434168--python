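# Methods

`exerscreen` re-creates, end to end, a stealth-assessment analysis of
exergame telemetry: the idea that the raw performance measures a physical
training game already records (distances, counts, completion times,
remaining lives) carry a cognitive signal that can screen older adults for
mild cognitive impairment without administering a test. Because the
original trial data are not publicly deposited, the package couples the
analysis pipeline to a synthetic-cohort generator calibrated to the
published group-level summary statistics. Passing tests therefore
demonstrate that the pipeline's statistics and algorithms are correct and
that, under the published group structure, the analyses behave as reported
— not that any real cohort would reproduce the published effect sizes.

## Cohort model

Three diagnostic groups — cognitively normal (CN, n = 38), mild cognitive
impairment (MCI, n = 64) and mild dementia (MD, n = 14) — are simulated
with group-specific mean ± SD for age, education, MMSE, MoCA, Trail Making
A/B, baseline in-game domain scores (strength, aerobic, HRMG,
flexibility), heart rate and Borg exertion rating.

**Truncated-normal calibration.** Every continuous quantity is a truncated
normal at its instrument bounds (MMSE/MoCA in [0, 30], game scores in
[0, 10], Borg in [6, 20], age ≥ 55). Naive truncation shifts the mean —
noticeably so for Borg (target 6.9, floor 6) and MMSE near its ceiling —
so the generator solves (Brent's method) for the location parameter whose
*truncated* mean equals the target, keeping group sample means calibrated
to the published values. The printed SD is used as the (pre-truncation)
scale; the post-truncation SD is consequently slightly smaller near a
bound, a deliberate trade: the downstream acceptance checks compare means.
MMSE, MoCA, age and education are rounded to integers (instrument
resolution); the rounding bias is negligible at the configured SDs.

**Latent cognitive factor.** Within a group, MMSE, MoCA (positively),
TMT-A/B (negatively) and the HRMG baseline (positively) load on one shared
standard-normal factor per participant with loading ρ = 0.6, combined
through a Gaussian copula so the calibrated marginals are untouched. The
published report gives no within-group covariances; a single shared factor
is the simplest structure that produces the reported moderate
game–neuropsychology correlations, and ρ is configurable. Physical-only
domains and vitals do not load on the factor.

**Balance domain.** The published baseline table omits balance; the
generator defaults it to 7.5-8.1 ± ~1 (between strength and flexibility)
per group, and the default feature set excludes it (the published
aggregate lists aerobic, resistance, flexibility and HRMG).

**Reproducibility.** Every participant draws from an RNG substream keyed
by the root seed and a SHA-256 hash of the participant id; cohorts are
byte-identical across runs and independent of generation order or of
which other groups are generated.

## Session and telemetry model

The default schedule is 3 sessions/week for 8 weeks (24 sessions; both
knobs configurable in the trial's reported 3-4 × 7-8 range — the fixed
default keeps runs deterministic). Difficulty is promoted at sessions 7,
13 and 19, giving six sessions at each of the four levels so every
per-level trend fit has equal support. The latent expected score of domain
d at within-level session t is

    score_d(t) = clip(baseline_d + slope_group · (t − 1) + N(0, σ_d), 0, 10)

with small default slopes (0.02-0.05 points/session; the published
analysis found no significant slope differences between groups, and the
defaults preserve that null structure) and session noise σ_d = 0.75 score
points for game domains. Session 1 expectation equals the baseline, i.e.
the published baselines are treated as session-1 expectations (the
plausible alternative — early-period means — would shift baselines by at
most a few hundredths of a point at the default slopes).

Raw telemetry is emitted so that the expected unit score under the scoring
equations equals the latent ability a = score/10: count achievements are
Binomial(total, a) and continuous ratio terms are Beta with mean a
(concentration 12). Mini Golf mixes a path term (weight 0.7), a scored
flag (0.2) and a time bonus (0.1) that is zero when the ball is missed;
the path-term mean is set to a(8 − a)/7 so the play's total expectation is
exactly a. Heart rate (3 readings/session), blood pressure and Borg are
i.i.d. around participant-level means; no intra-session dynamics are
modelled. Borg session values are kept continuous rather than integer —
a simplification that preserves exact mean calibration.

What the generator does **not** emulate: dropout and adherence patterns,
practice/fatigue nonlinearity, heteroscedastic noise, covariance between
domains beyond the shared factor, or any game-mechanical detail beyond the
scored symbols. Results on real telemetry can differ accordingly.

## Scoring

Unit scores implement the weighted equations listed in the module
docstring of `exerscreen.scoring`; two printed terms require an
interpretation to live in [0, 1]: time terms are taken as remaining-time
fractions (finishing faster scores higher) and the golf path term as
optimal/max(travelled, optimal) (deviation from the optimal path
penalizes). All weights of multi-term equations sum to 1, unit scores are
clipped to [0, 1] (out-of-range telemetry is clipped, not rejected) and
scaled by 10. A session's domain score is the unweighted mean over that
domain's games — the roster per session is a configuration choice —
and vitals/Borg are session means. Domains without plays are absent from
the output, never zero.

## Trend features

Each domain's score series is reduced to mean, OLS slope and OLS intercept
(`y = ax + b`) for the total period and per difficulty level. Per-level
fits use the within-level ordinal (1, 2, …) as x, so each level's
intercept estimates performance at level entry and intercepts are
comparable across levels; the total fit uses the global session index.
Single-observation periods have undefined slope/intercept; unplayed levels
yield explicit NaNs, which the classification stage mean-imputes within
each training fold. Feature names follow the `"<Domain> <Stat><Period>"`
convention (`"HRMG MeanTotal"`, `"HeartRate SlopeLevel3"`).

## Group statistics

Features are screened with the tie-corrected Kruskal–Wallis H
(chi-square approximation, df = k − 1) and the rank effect size
ε² = H/(n − 1) ∈ [0, 1] — the standard choice that reproduces the scale of
the published effect sizes. Pairwise comparisons are Dunn's z-tests on the
pooled mid-ranks with tie-corrected variance, two-sided, Bonferroni-
multiplied by the number of pairs and capped at 1 (the procedure the
"pairwise comparisons with Bonferroni adjustment" phrasing conventionally
denotes). All-identical samples return H = 0, p = 1 rather than an error.
Pearson correlations use the exact t-based two-sided p; zero-variance
input is a hard error. Normality annotations delegate to Shapiro–Wilk and
the Lilliefors KS test against a fitted normal; they only label the
parametric/non-parametric branch and never gate the analysis.

## Feature selection and classification

CFS merit k·r̄_cf/√(k + k(k−1)·r̄_ff) uses symmetric uncertainty after
equal-frequency discretization into 5 bins (class kept categorical) —
deterministic and scale-free. Subset search is forward best-first: a
priority queue over subsets ordered by merit (ties broken
lexicographically), expanding the best unexpanded node by single-feature
additions and stopping after 5 consecutive non-improving expansions. On
association structures derived from actual data the search matches
exhaustive enumeration for ≤ 8 features; it is a heuristic, and
adversarial association tables that no dataset can realize can defeat any
finite stale limit.

The classifier is a one-hidden-layer feedforward network with logistic
units (hidden size ⌈(n_features + n_classes)/2⌉), trained by seeded SGD
with momentum (learning rate 0.3, momentum 0.2, 500 epochs, no weight
decay) on fold-internally z-standardized, mean-imputed inputs — the
default hyperparameters of the standard workbench family such analyses
conventionally use. Evaluation is stratified 10-fold cross-validation with
pooled out-of-fold predictions; per-class ROC areas are one-vs-rest
trapezoidal AUCs of the out-of-fold probabilities. Two selection
protocols are provided and labelled: `pooled` (selection once on all data,
comparable to a single published feature ranking, optimistic) and `nested`
(selection re-run inside every training fold; leakage-free, the default).

## MCI screening

The MCI-vs-CN screen sweeps a score over every distinct threshold; the
trapezoidal AUC equals the tie-corrected rank-sum concordance
U/(n_pos·n_neg) (property-tested to 1e-12). Game and clinical scores use
the lower-is-positive direction (impairment lowers the score). Cut-off
screening defaults to the conventional clinical thresholds MoCA < 26 and
MMSE < 27, both overridable; accuracy is reported raw, (TP+TN)/N. Two
"game algorithm" scores are offered: the HRMG MeanTotal feature directly,
and the classifier's out-of-fold P(MCI) restricted to the two groups.

## Numerical notes and limitations

- Degenerate inputs: SD = 0 collapses a sampled quantity to its mean;
  ability 0/1 makes play telemetry deterministic; empty series, empty
  groups, constant vectors and single-class folds raise typed errors.
- The chi-square approximation for H is accurate at the default group
  sizes (type-I error 4.7% at α = 0.05 over 10,000 null simulations) but
  is an approximation; no exact permutation p is computed outside tests.
- Problem sizes in the test suite (replicate counts, simulation lengths,
  Monte-Carlo draws) are chosen to bound each statistical check's standard
  error well below its assertion band while keeping the default run fast.
- Three-class accuracy around the mid-60s to low-70s percent and
  MCI-vs-CN classifier AUC around 0.7 on the default synthetic cohort are
  properties of the generator's calibration (group separation ~0.4-2 SD
  per feature), not evidence about any real cohort.
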