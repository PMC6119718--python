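# Methods

## Data model

A rating curve is one participant's continuous report of one affect
dimension (valence or arousal) for one stimulus, sampled on a uniform 1 Hz
grid starting at 0 s and normalized to [-1, 1] with 0 as the neutral
point; the value at t is the rating prevailing during the second
[t, t+1). The normalization is the affine map
v' = 2 (v − raw_min) / (raw_max − raw_min) − 1, so the raw midpoint lands
on 0 and the endpoints on ±1. When long-format CSVs are read, missing
seconds inside a series are filled by last observation carried forward
(the rating device's position persists between movements) and a leading
gap is filled with the neutral value 0; these are conventions, not
inferences, and both are confined to file ingestion.

Quadrants of the valence/arousal plane are labelled by strict sign:
Q1 (+,+), Q2 (−,+), Q3 (−,−), Q4 (+,−). A point with either coordinate
exactly 0 is labelled `neutral` rather than silently assigned — boundary
points carry no quadrant information.

## Reliability screen

Panel reliability of the curves for one stimulus x dimension cell is
Cronbach's alpha with raters as the "items" and the T per-second ratings
as cases:

    alpha = k/(k−1) * (1 − Σ_i Var(rater_i) / Var(row sums)),

sample variances with denominator T−1. Alpha may be negative (systematic
disagreement) and is reported as-is, never clamped. When the row sums are
(numerically) constant — e.g. two exactly mirrored raters — the ratio is
undefined and the function raises instead of returning ±infinity.

Cells with alpha below a threshold are excluded from testing. The default
threshold is 0.75: published reliability panels for this kind of study
retain per-stimulus alphas in the high 0.7s and above while dropping
values in the low 0.7s and below, and 0.75 reproduces that keep/drop
boundary. It is a configuration knob, not a constant. One published panel
prints the same cell as 0.73 in its table but −0.73 in the running text;
the screen works from the tabulated value (the sign does not change the
keep/drop decision at this threshold).

## Grouping factors

Trait scores: each Big-Five dimension is the mean of one direct TIPI item
and one reverse-keyed item recoded as 8 − x; trait EI is the mean of the
30 TEIQue-SF items after reverse-keying. The instruments' standard keys
ship as defaults and are configurable, since studies occasionally permute
item order. Mean splits assign participants by the sign of the
within-sample z-score; an exact tie at the mean goes to "low" by default
(deterministic, configurable). The split is invariant under positive
affine transforms of the scores. Musical training contrasts ≥ 10 years
against < 1 year of formal training, the middle band being excluded from
that factor only; age splits strictly above 40 years; gender uses the
recorded binary variable.

## The functional test

For one stimulus x dimension cell and one dichotomous factor, the null
hypothesis is equality of the group mean functions over the whole time
course.

**Smoothing.** Each raw curve is smoothed by local polynomial regression
(default: local linear, Epanechnikov kernel). The smoother is a linear
operator on the common grid, built once per bandwidth and applied to all
curves. Local linear fits reproduce globally linear curves exactly and
have the usual boundary-bias advantage over kernel averages.

**Bandwidth.** One bandwidth is shared by all curves of a stimulus x
dimension cell so the group means are comparable. Candidates are
log-spaced from 2 grid steps to a quarter of the span (10 values). Each
curve is scored by leave-block-out cross-validation: the prediction at t
omits all observations within 2 grid steps of t, re-solving the local
least squares without them. The gap matters because rating noise is
serially correlated — with AR(1)-type errors, classical leave-one-out
tracks the correlated noise and systematically undersmooths, which not
only roughens the mean estimates but measurably degrades the calibration
of the bootstrap test (empirical size at nominal 0.05 fell to ~0.02–0.04
with leave-one-out, against ~0.05 with the gapped criterion, in null
simulations with AR(1) noise of coefficient 0.5). Gap 0 recovers
classical LOOCV. Per-curve optima break ties toward the smallest feasible
candidate (with a compact kernel, candidates whose support lies inside
the gap window are infeasible and skipped); the shared bandwidth is the
lower median of the per-curve optima — the median resists the occasional
curve whose optimum runs away, and the lower median keeps the result on
the candidate grid.

**Statistic.** Smoothed curves are averaged within groups and compared by
the Cramér-von Mises-type statistic

    C = Σ_{i<j} (n_i n_j / (n_i + n_j)) ∫_T ( m̂_i(t) − m̂_j(t) )² dt,

with the integral by the trapezoid rule on the 1 Hz grid (grids are never
interpolated to a finer mesh). All factors of interest are dichotomous,
so the sum has a single term in practice, but the implementation accepts
k ≥ 2 groups. C is symmetric in the groups, zero iff the smoothed means
coincide, and invariant to adding a common function of time to every
curve.

**Bootstrap calibration.** The null distribution of C is approximated by
a functional bootstrap of whole residual curves:

1. residual curves r = smoothed curve − own-group mean of smoothed
   curves, rescaled by sqrt(n_g/(n_g−1)) — within-group centering
   deflates the variance of a resampled mean by (n_g−1)/n_g, and the
   rescaling undoes exactly that;
2. for each of B resamples, residual curves are drawn with replacement
   *within each group* (preserving each group's dispersion — the
   heteroscedasticity contract — and, because whole curves are drawn,
   each curve's autocorrelation) and treated as a null-mean sample;
3. C\* is recomputed for each resample, and

       p = (1 + #{C* ≥ C}) / (B + 1),

   so p-values are positive multiples of 1/(B+1) and never zero.

The test is deterministic given the bootstrap seed. Resample indices are
drawn per group in a canonical content-based order (groups sorted by
their data bytes), so relabelling or reordering the two levels reproduces
the identical p-value. By default the bootstrap reuses the originally
selected bandwidth; re-selecting per resample is disabled for speed and
stability.

This curve-resampling calibration is asymptotically valid but known to
lean conservative when the effective dimension of the smoothed noise is
comparable to the group size (the empirical covariance's eigenvalue
spread fattens the bootstrap distribution). With the gapped-CV bandwidths
the empirical size in this package's null simulations sits at 0.04–0.06
at nominal 0.05, both with equal noise scales and with a fourfold scale
difference between groups.

## The battery and multiplicity

The battery enumerates the full ordered cross product of stimuli,
dimensions and factors; reliability-excluded cells remain in the
enumeration (they count toward the battery size) but are skipped at
execution and rendered blank — not "non-significant" — in reports. Each
test's bootstrap seed derives from the master seed and the test's ordinal
index in the canonical enumeration (`SeedSequence(master, spawn_key=(index,))`),
making results independent of execution order. One bandwidth is selected
per stimulus x dimension and shared by that cell's nine factor tests.
Individual test failures are recorded and the battery continues; if more
than 10% of runnable tests fail, the whole battery errors out.

Benjamini-Hochberg step-up correction is applied within families —
per stimulus by default, or globally — via the standard step-up adjusted
p-values; the rejection set equals the largest-k rule. The per-stimulus
default mirrors the convention of correcting each stimulus's tests as one
family; since the family definition for this design is genuinely
ambiguous (a stimulus contributes 2 dimensions x 9 factors = 18 tests,
but published analyses have used smaller per-stimulus family sizes), the
family mode is configuration, and Bonferroni adjustment is provided as
the conservative baseline (its rejections are always a subset of BH's at
the same level).

Note an interaction between B and BH: at B = 199 the smallest attainable
p-value is 1/200 = 0.005, which can never clear a per-stimulus BH
threshold of 0.05/18 for a lone discovery. Batteries intended to declare
individual cells significant should use B ≥ 999 (the default is 1000);
B = 199 remains adequate for calibration studies and for ranking cells.

## The synthetic-data generator

The generator emulates a 2DES listening study: by default 52 raters and
17 stimuli (8 music, 9 speech) whose durations span 45–156 s, each with a
smooth latent trajectory through its designated quadrants (shape-
preserving cubic interpolation through waypoints, clipped to [-1, 1]).
Participant i rates stimulus mean μ(t) as

    X(t) = clip( a_i · μ(t) + b_i + e(t) ),   e stationary AR(1),

with amplitude a_i ~ LogNormal(0, 0.1²) (median 1), offset
b_i ~ N(0, 0.05²), AR coefficient ρ = 0.5 and innovation scale σ = 0.15
by default; σ may differ by factor level to produce the heteroscedastic
regime the test claims to handle. No study of this kind publishes
participant-level noise magnitudes, so the defaults were chosen once to
reproduce the qualitative reliability regime of published panels:
per-stimulus alphas mostly above 0.9 at the default σ, declining
monotonically as σ grows (the sweep is part of the test suite). Group
effects are injected as Gaussian bumps A·exp(−(t−t₀)²/(2w²)) added to the
mean function of one factor level for one stimulus x dimension cell —
group-specific mean functions, not per-participant perturbations,
matching the null/alternative structure the test addresses. Clipping is
applied after noise, accepting mild boundary censoring as in real
bounded-slider data.

Covariates are generated as dimension scores first and back-filled to
item responses consistent with the configured reverse keys, so
questionnaire scoring round-trips. Every simulated study ships a truth
manifest (seed, injected effects, factor memberships) for recovery tests.

What the generator does *not* emulate: mouse kinematics and reaction lag,
rating drift or fatigue, acoustic-feature-driven structure in the mean
trajectories, non-stationary or heavy-tailed noise, and missing-data
patterns. Passing tests therefore demonstrate that the pipeline is
correct and calibrated under a bounded, autocorrelated, possibly
heteroscedastic noise model with multiplicative rater effects — not that
any particular real dataset satisfies those assumptions.

## Numerical choices and degenerate inputs

* Trapezoid quadrature on the native 1 Hz grid; exact for the constant
  integrands used in the closed-form checks.
* Local designs with fewer than degree+1 kernel-weighted points raise a
  bandwidth error rather than extrapolating; bandwidths below the grid
  step are rejected.
* Mean splits on constant scores, reliability on constant panels, and
  groups with fewer than 2 curves raise typed errors.
* Bootstrap specifications require B ≥ 99 so the minimum attainable
  p-value is at most 0.01.
* Exact ties at a mean split go to "low"; exact zeros in quadrant
  classification go to "neutral"; CV ties go to the smallest feasible
  bandwidth. All tie rules are deterministic and documented.

## Problem sizes used in the shipped studies

The calibration study in `scripts/acceptance.py` uses 500 null
replications of a 26 + 26 panel on a 120 s grid with B = 199 — large
enough that the binomial 95% band around 0.05 is ±0.019 — and runs in
under a minute. The power and battery-recovery studies in the test suite
use 20 replicates of the full 52-participant, 17-stimulus design at
B = 199, where a bump of amplitude 0.3 and width 10 s is essentially
always detected and ranks first among the 306 adjusted p-values in the
large majority of replicates.

## Known limitations

* The bootstrap calibration leans conservative when group sizes are small
  relative to the smoothed noise dimension (see above); it does not
  anti-conservatively inflate discoveries.
* The pipeline tests whole-curve equality only; it does not localize
  *where* two mean curves differ.
* No asymptotic/χ² calibration is offered; the bootstrap is the only
  calibration path.
* Only global trait-EI scoring is provided (no TEIQue facets), and mood
  analysis stops at pre/post difference scores.
* The exact resampling and weighting conventions of functional ANOVA
  bootstraps vary across the literature; the forms used here are declared
  above for anyone reconciling results against other implementations.
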