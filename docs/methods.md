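# Methods

## The analysis pipeline

The pipeline consumes a long-format judgment table — one row per
(rater, trial) with the rater's group, the trial's ground-truth type
(same or different identity), an identity judgment on the signed 7-point
scale and a difficulty rating on the 5-point scale — and produces four
families of statistics. Everything downstream treats the judgment scale
as ordinal; no numeric distance between scale points is assumed except
where a method is explicitly distance-weighted (weighted kappa).

### Accuracy (AUC)

Per-rater accuracy is the area under the ROC curve computed directly from
the ordinal judgments labelled by trial type, via the midrank form of the
Mann–Whitney functional: over all (same, different) trial pairs, the
proportion in which the same-identity trial received the strictly higher
judgment, plus half the proportion of ties. This equals trapezoidal
integration of the ROC swept across the seven judgment thresholds, and is
invariant under any strictly increasing transform of the scale. Ties get
0.5 credit (the midrank convention); whether the original analyses of
this task used the same tie rule is not stated anywhere we know of, so
the convention is documented here rather than guessed at — it is the
standard correspondence between AUC and the rank-sum statistic. Raters
exposed to only one trial type have undefined AUC; they are flagged,
logged, and excluded from group medians and participant-level
correlations.

Group AUC comparisons use the two-sided Mann–Whitney U test in its
normal approximation with midranks, tie-corrected variance and a 0.5
continuity correction, reporting the effect size r = Z/√N (N = total
observations). The approximation is used at all sample sizes for
cross-platform reproducibility; below ~10 per group its p-values are
approximate, which the package accepts rather than switching methods by
sample size.

### Scale use

Pooled judgment distributions count every judgment of a group × trial
type as one observation over the seven scale points (zero-filled where a
point is unused). Different-identity judgments can be *mirrored*
(elementwise sign flip) onto the same-identity axis, so that a group that
treats the two trial types symmetrically produces overlapping same and
mirrored-different distributions. Four two-sample Kolmogorov–Smirnov
comparisons are run: between groups on same-identity judgments, between
groups on different-identity judgments, and same vs mirrored-different
within each group.

The K-S statistic D is the largest absolute ECDF difference over the
pooled support; the default p-value is the two-sided asymptotic one.
Two caveats are deliberate and documented rather than patched:

- pooling makes observations of the same rater non-independent, so the
  nominal p-values are approximate descriptions, not exact tests;
- on 7-point support the asymptotic p is conservative under heavy ties.

A permutation p-value (label reshuffling of the pooled sample) is
available as a sensitivity analysis and is exact under exchangeability
even with ties; the calibration test of the simulator's mirror symmetry
uses it for precisely that reason.

Per-rater scale-use summaries report each rater's proportion of extreme
(±3) and midpoint (0) judgments and the modal judgment per trial type
(ties reported as the full tied set — with 20 trials ties are common).
Group differences in the proportions are tested with the same
Mann–Whitney machinery as accuracy.

### Agreement

Inter-rater reliability is Cohen's kappa weighted for ordinal data,
computed between **all unique pairs** of raters within a group
(C(n,2) pairs: 1596 for a 57-rater group, 78 for 13). Agreement weights
are w_ij = 1 − (|i−j|/6)^q over the full seven-category set; q = 1
(linear) by default, q = 2 (quadratic) by flag, and every report names
the weighting used. Linear is the conservative reading of "weighted for
ordinal data"; the choice is configurable because the original analyses
do not name an exponent. Marginals always span all seven categories:
absent categories carry zero mass, so kappa remains well-defined for
raters who use only part of the scale. A pair in which both raters are
constant at the same category has P_e = 1 and therefore undefined kappa;
such pairs are counted and excluded from group means, never imputed.
Rule-of-thumb labels: κ ≥ 0.75 excellent, 0.40 < κ < 0.75 fair,
κ ≤ 0.40 poor.

Because every rater contributes to n−1 pairs, pair kappas are mutually
dependent and the variance of their mean has no standard form. The group
comparison therefore bootstraps **trials**: each iteration draws 20 trial
ids with replacement from the trial set (unstratified by trial type, the
default; a stratified option exists for sensitivity analysis), recomputes
every pairwise kappa in both groups on the resampled multiset (repeated
trials contribute repeated observations; both groups see the same
resample), and records the difference of group mean kappas. The 2.5th
and 97.5th percentiles of 1000 iterations form the 95% CI; the groups are
called significantly different when the CI excludes 0. Iterations where a
group has no defined pairs are discarded, re-drawn and counted. The CI is
a simple percentile interval, not BCa.

**Calibration, measured.** Under the null (both groups drawn from a
single rater profile, 15 + 15 raters, 20 trials, 1000 iterations), the
CI contains 0 in ≈93.5% of replicate studies. The ~1.5-point shortfall
from nominal is the familiar small-sample behavior of a percentile
bootstrap over 20 resampling units. A second, larger shortfall appears
when raters vary (sensitivity sd 0.3, threshold jitter 0.15): coverage
drops to ≈86%, because resampling trials can never capture
rater-*sampling* variance — each bootstrap iteration reuses the same
raters. This is an inherent property of trial-only resampling, shared
with the procedure this package reproduces: the CI quantifies stability
of the agreement difference across facial comparisons for *these* raters,
not across hypothetical replications with new raters.
`scripts/acceptance.py` recomputes both coverages.

### Metacognition

Confidence is the absolute value of the identity judgment (0–3),
direction-free by construction; incorrect high-confidence responses are
kept as-is, since the confidence–difficulty analysis says nothing about
accuracy. Trial-level analysis pools every (confidence, difficulty)
response pair within a group; participant-level analysis correlates
per-rater mean confidence, mean difficulty, and AUC, per group (a pooled
mode across groups is available). All correlations are Kendall tau-b —
tie-corrected, the appropriate variant for two coarse ordinal scales; the
asymptotic two-sided p-value is reported. The within-rater dependence
caveat of trial-level pooling is recorded in the report metadata.

## The synthetic-rater simulator

Real data for this design is restricted, so the package generates
judgment tables from an explicit ordinal signal-detection model that
serves as ground truth for parameter-recovery and calibration testing.

Latent evidence for rater *i* on trial *t* is

    e = ±(d_i/2 + s_t) + a_i·1[different] + ε,   ε ~ N(0, 1)

with the sign positive on same-identity trials; d_i > 0 is the rater's
sensitivity (separation of the two evidence distributions, in latent sd
units), s_t ~ N(0, σ_trial) a trial-easiness component shared by all
raters (σ_trial = 0.5 by default; the original task reports no item-level
statistics, so this spread is a free, documented choice), and a_i an
asymmetry applied only on different-identity trials, modelling raters
whose caution differs between "same" and "different" conclusions. The
judgment is the category of e under the rater's six ordered thresholds.

Thresholds are built from a baseline equal-width partition
(±0.5, ±1.5, ±2.5), per rater:

1. add a whole-partition shift (criterion **bias**, N(0, bias_sd)) —
   the rater leans "same" or "different" overall;
2. add independent per-cut jitter (N(0, jitter_sd)); non-monotone draws
   are re-drawn, with a logged sort-projection fallback;
3. divide by (1 + extremity): **compression** shrinks inner categories
   (the judgment-0 band most) and widens the outer two, pushing mass to
   ±3 and away from 0.

Compression acts on thresholds, not evidence, so a rater's accuracy is
essentially invariant to extremity (only tie structure at the scale ends
changes AUC, and negligibly): style and skill are separated by
construction, which is the core contrast the pipeline is meant to
exhibit. By default thresholds are *absolute* (shared criterion
placement): a more sensitive rater's evidence lands in outer categories
more often, so mean confidence rises and mean rated difficulty falls with
accuracy — the mechanism behind the metacognitive-insight pattern. An
optional mode rescales thresholds with sensitivity, which removes that
coupling; it exists to show the pattern is a modelling consequence, not
an artifact of the statistics.

Difficulty is generated from the **same** latent evidence:
raw = 5 − 1.2·|e| + N(0, difficulty_noise), rounded and clamped to 1–5.
This makes difficulty a noisy, decreasing function of evidence extremity
and yields the strong negative confidence–difficulty coupling the
pipeline should recover (pooled tau-b ≈ −0.7 at the default
difficulty_noise of 0.5; the coupling stays negative for any
difficulty_noise below about 3, far above any plausible setting). The
intercept 5 and slope 1.2 map the typical evidence range (|e| ≈ 0–3.5)
onto the full difficulty scale.

Randomness is split hierarchically from a single seed (one child stream
per rater, indexed by group and position; a separate stream for trial
strengths), so adding a rater never perturbs existing raters' data and
identical configs reproduce tables bit-identically.

### Default conditions

The study-shaped default (`default_study_config`) is 57 + 13 raters on
12 same + 8 different trials. Both groups share sensitivity
N(2.5, 0.3) — the two specialist populations are equally accurate, and
d' = 2.5 lands median AUC near 0.9 on this 20-trial design. The
examiner-like group uses the full scale (extremity 0, asymmetry 0,
jitter 0.15); the super-recognizer-like group prefers the extremes and
avoids the midpoint (extremity N(1.5, 0.3)), is more cautious on
different-identity trials (asymmetry N(0.4, 0.1)) and is less
threshold-homogeneous (jitter 0.30). bias_sd defaults to 0.

Two further documented configurations exist for specific demonstrations:

- **Heterogeneous skill** (`heterogeneous_skill_style`): sensitivity
  N(2.2, 0.8) with absolute thresholds; used to recover the
  metacognitive sign pattern (confidence↔AUC τ > 0,
  difficulty↔AUC τ < 0) at the participant level.
- **Homogeneity gap** (tests and acceptance script): threshold
  bias/jitter sd 0.05/0.05 vs 1.2/0.5 at equal sensitivity. Criterion
  *bias* is the dominant driver of disagreement — independent per-cut
  jitter largely averages out (0.05 vs 0.7 jitter shifts mean kappa by
  only ~0.03), whereas a whole-partition shift displaces every judgment
  of a rater the same way. The documented gap produces mean kappa ≈0.39
  vs ≈0.26 and a bootstrap CI excluding 0 in the large majority of
  replicate studies. Notably, *extremity* heterogeneity does not lower
  agreement — compression concentrates everyone at ±3, which raises it.

### What the simulator does and does not emulate

It reproduces the structural features the analyses need: the trial
design, two groups with distinct response styles at matched accuracy,
trial-level easiness shared across raters, and difficulty ratings coupled
to judgment confidence. It does not model tool use, untimed completion,
order effects, learning across trials, face-specific image properties, or
any dependence between trials beyond the shared easiness scalar.
Passing tests therefore show the pipeline's statistics behave correctly
on data with this covariance structure — they do not validate the model
as a psychological account of real examiners, and real-data effect sizes
need not match the simulator's.

## Numerical and design choices

- AUC, Mann–Whitney Z, the K-S D and weighted kappa are computed with
  midranks/closed-form count arithmetic — no stochastic steps; the
  bootstrap and the simulator are the only consumers of seeds, and every
  stage seed derives from one top-level seed via a fixed splitting rule.
- Undefined statistics raise typed signals (`UndefinedKappaError`,
  `UndefinedCorrelationError`, `SingleClassError`) rather than returning
  NaN from the scalar APIs; vectorized internals carry NaN and count it.
- Kappa's P_e = 1 degeneracy is detected at 1e−12; proportions must sum
  to 1 within 1e−12.
- Pair enumeration is vectorized (an n×n weight-lookup mean over trials
  plus a marginal outer product); the scalar `weighted_kappa` and the
  vectorized path are cross-checked in tests, and both are checked
  against an independent double-sum oracle.
- Mode ties are reported as tied sets; boundary labels for agreement are
  excellent at exactly 0.75 and poor at exactly 0.40.
- Problem sizes in the test suite (e.g., 400 replicate studies for
  bootstrap calibration, 15 + 15 raters, 1000 bootstrap iterations;
  20 seeds for sign-pattern recovery) were chosen to bound Monte-Carlo
  error well below the margins being asserted while keeping the default
  suite around two minutes on one CPU.

## Known limitations

- Trial-only bootstrap undercoverage under rater heterogeneity (measured
  above) — a property of the procedure itself.
- Asymptotic K-S p-values are conservative on 7-point support; use the
  permutation option when calibrated p-values matter.
- Trial-level pooling (K-S and tau) ignores within-rater dependence.
- The Mann–Whitney normal approximation is inexact for very small groups.
- The simulator's difficulty mapping is a single affine family; real
  difficulty ratings may depend on features other than evidence
  extremity.
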