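# Methods

This note documents the models and procedures implemented in `profilesim`,
the parameter choices that matter, and what the bundled synthetic data can
and cannot show.

## Profile pairs and evaluation contexts

The unit of analysis is a `ProfilePair`: two aligned vectors of ratings on
the same `p ≥ 2` variables, one per dyad member.  Missingness is resolved
before pairing — an occasion answered by one partner yields no pair — so a
pair never contains missing entries.  Context-dependent measures draw their
constants from a `MeasureContext` computed on a reference dataset:

* **ranges `R_i`** (Gower, scaled-Euclidean, half-range, max-scaled
  variants): the observed per-variable range of the reference data.  The
  theoretical scale range is an equally defensible choice and can be passed
  explicitly; the observed range has the advantage of always existing, in
  particular for centered data, where the theoretical scale no longer
  applies.  A degenerate (zero) observed range is stored as NaN so that
  measures consuming it return the missing marker instead of dividing by
  zero.
* **standardization statistics** (Burrows's Delta, McCrae's measures):
  per-variable mean and SD (ddof = 1) of the reference data.
* **scale midpoints** (Cohen's r_c): Cohen's coefficient is the cosine of
  midpoint-deviation scores, designed for scales whose reversed scores are
  meaningful.  On centered data the pipeline expresses the midpoint in
  centered coordinates — the raw scale midpoint minus the per-variable raw
  grand mean — so the measure keeps its "deviation from the scale midpoint"
  semantics rather than silently degenerating into the plain cosine.
* **Cattell's K**: defaults to the median of the chi-square distribution
  with `p` degrees of freedom, Cattell's convention for standardized
  profiles, overridable.

**Missing-value policy.**  Any data-driven degeneracy — division by zero,
log of zero, square root of a negative value, zero variance — yields the
missing marker (IEEE NaN), never a silent zero and never an exception.
This matters because the screening stage *counts* missing values; imputing
or erroring would bias the count.  Genuine misuse (length mismatch, unknown
measure id, missing required context, τ* on fewer than four variables)
raises.  The Canberra distance uses a strict 0/0 policy by default (one 0/0
term poisons the value), which reproduces the high failure rates this
measure shows on zero-inflated rating data; a term-skipping policy is
available as an option.

## Measure formulas: choices where sources are ambiguous

* **Kendall "covariance"**: implemented as the tau-a form `(C − D)/n₀`
  (concordant minus discordant pairs over all `p(p−1)/2` index pairs) — the
  unnormalized counterpart of tau-b.  The Spearman covariance uses the
  sample convention (divisor `p − 1`) on mid-ranks.
* **Kohonen similarity**: the Tanimoto-type scaling
  `Σx_iy_i / (Σx_i² + Σy_i² − Σx_iy_i)`, a product numerator with a scaled
  denominator, bounded in [0, 1] on nonnegative scores.
* **Intersection similarity**: the unnormalized histogram intersection
  `Σ min(x_i, y_i)`; consequently it carries no bounds entry in the
  catalog.
* **McCrae's measures**: operationalized on z-scored profiles as
  `I_pa = (k + 2ΣM_i² − ΣD_i²/2)/k` with `M = (x+y)/2`, `D = x − y`, and
  the coefficient as the bounded monotone transform
  `r_pa = I_pa/√(1 + I_pa²)`.  These satisfy the defining qualitative
  properties of the originals — symmetry, a bounded coefficient, and a
  reward for agreement on *extreme* scores (identical extreme profiles
  score higher than identical mild ones) — and are documented here as this
  package's transcription.
* **Distance correlation** is the sample statistic over the `p` profile
  entries: double-center the pairwise |difference| matrices, then
  `dCov² = mean(A∘B)`, `dCor = dCov/√(dVar_x dVar_y)`, defined as 0 when a
  dVar vanishes.  An independent implementation (pingouin) is used as a
  cross-check in the tests, never as the implementation.
* **Bergsma–Dassios τ\***: the sign-covariance U-statistic, computed by
  exhaustive enumeration over all quadruples of profile entries (O(p⁴),
  intended for p ≤ 20).  The 24 orderings of a quadruple collapse to 6
  distinct kernel evaluations (3 pairings × 2 cross-matchings), which the
  implementation averages.  Numerical note: the sign kernel is a function
  of the quadruple's order pattern only, but evaluating it on raw values is
  float-fragile (for some patterns the kernel expression is identically
  zero and cancellation noise decides the sign), so profiles are mid-rank
  transformed first — rank arithmetic keeps every sign exact.  The test
  oracle is a separately written full 24-permutation enumeration.

## Centering and pairing

Person-mean centering subtracts each person's per-variable mean across
occasions (longitudinal designs only; a person-variable cell with a single
observation centers to 0, an all-missing cell stays missing).  Variable
centering by role subtracts per-role per-variable means — "separately for
men and women" generalized to the role field, so the package is agnostic to
gender labels.  Grand-mean centering subtracts each variable's overall mean
over all observations (not over culture means; with unequal culture sizes
the two differ only by a reweighting), which removes stereotype responding
shared by all cultures while preserving between-culture differences — and
therefore the cultural norms, which are per-culture per-variable means
computed *after* centering.  All means exclude missing values; centering
never changes the missingness pattern, hence never the pair count.  All
three schemes are idempotent.

## Screening

Phase 1 (duplicates/complements) runs on a probe set: the first dataset's
centered pairs plus 100 seeded random probe pairs drawn on a nonnegative
integer grid (0..6).  Integer probes are deliberate: they carry ties, and
tie-free probes would make tau-b coincide with the tau-a covariance
everywhere and falsely merge them; nonnegative probes exercise the
complement identities that hold on positive scores.  Detection flags
measure pairs whose columns are equal (or sum to 1) within relative
tolerance 1e−9 on at least 10 shared observations.  *Removal* additionally
requires the equivalence to be confirmed at the formula level, recorded in
the catalog (`duplicate_of`/`complement_of`): numerically coincident values
are evidence, not proof, and the detector also flags pairs (Ruzicka/Soergel,
which satisfy `soergel = 1 − ruzicka` identically) that the published
retained list deliberately keeps as separate entries; these are reported as
warnings.  When a complement pair is removed, the similarity member is kept.

Phase 2 excludes a measure when its column has ≥ 5% missing values or an
(almost) infinite mean — operationalized as overflow or |mean| > 1e12,
since no cutoff is canonical — in ≥ 2 of the screening datasets, where each
dataset contributes both its raw and its centered table and either may trip
the rule.  Phase 3 excludes measures whose single most frequent value
(after rounding to 9 decimals) covers more than half of the non-missing
observations; it runs on the centered tables, the tables the downstream
clustering consumes.  Surviving measures are re-checked on the held-out
cultural datasets with the same criteria, warn-only.

## Clustering

The association between two measures is a multilevel Spearman correlation:
mid-rank both value columns over their jointly non-missing observations
(pairwise-complete handling, so one measure's missingness does not infect
another's), residualize each rank vector on the grouping indicator by
subtracting group means (fixed-effects dummy regression — deterministic,
and exactly the partial-correlation definition `r_xy·z = r(e_x·z, e_y·z)`),
and correlate the residuals.  Grouping is the couple for longitudinal
dyadic data, the culture for cultural data, and a single constant group for
the single-occasion lab design (no nesting; the coefficient then reduces to
the ordinary Spearman correlation).  The measure distance is `1 − |ρ|`,
absolute so that similarity and dissimilarity measures carrying the same
information cluster together; an undefined ρ (degenerate column on the
joint support) is imputed as the maximum distance 1 with a warning.

Ward clustering uses the Lance–Williams recurrence on squared
dissimilarities with square-root back-transform of the heights (the
convention appropriate to a precomputed dissimilarity matrix; the
alternative dialect that applies the recurrence to the raw dissimilarities
is a config switch).  The main-cluster partition cuts the dendrogram inside
the largest gap between consecutive merge heights, excluding the gap above
the final merge (which always yields one cluster); ties break toward fewer
clusters.  Fixed-k cuts are also exposed.

Cross-dataset consistency is this package's operationalization of "the
clusters are almost the same across datasets" (the published subgroup
labels were assigned by inspection, not by a stated algorithm): two
measures are consistently co-grouped when they share a cluster in at least
`min_agree` of the partitions (default: all but one dataset); consistent
groups are the connected components of that relation, and a measure in no
component of size ≥ 2 is labeled inconsistent.

## Synthetic data

The generator emulates the *structure* of five study designs — couple
counts 94/133/101 and culture counts 48/12, variable counts 6/12/6/14/20,
scales 0–100 (continuous slider), 0–6, 1–7, 1–9, 1–7 (rounded Likert),
longitudinal versus cross-sectional — via the simplest latent model with
one interpretable similarity knob: a shared dyadic state `s_gt ~ N(0,1)`
mixed into each member's latent state with weight `√ρ` (`dyad_similarity`,
default 0.4, the latent within-couple correlation), plus person trait
offsets, occasion noise, clipping and rounding.  Valence drives normative
similarity: positive-valence variables sit `normative_effect` (default half
the scale width) above negative-valence ones for everybody — the stereotype
pattern that inflates raw-data similarity and that centering removes.
Scale-unit defaults are proportional to scale width: latent loading 12%,
trait SD 8%, noise SD 10%, chosen as magnitudes typical of momentary
emotion ratings.

Realistic failure modes are built in.  Negative-valence ratings floor to
the scale minimum with probability 0.25 (ESM-like), 0.35 (VMR-like, the
design dominated by zero ratings), 0.05 (lab, whose scale starts at 1);
this zero inflation is what drives the Canberra distance's 0/0 failures on
the raw longitudinal data.  Whole occasions are jointly missing: both
partners answer with probability `joint_response_rate` (ESM default 0.88,
the emulated design's reported rate and the calibration target of
`scripts/acceptance.py`; otherwise a random single partner answers, so the
parameter is measured directly as the fraction of two-role occasions).
One percent of persons are careless responders (per-person constant plus
tiny jitter) — a minority, consistent with screening data in which all
retained measures stay below the 5% missingness bar.  Cultural designs
replace the dyadic state with per-culture mean offsets (SD 8% of width) and
are scaled to 30 members per culture, which exercises the
individual-versus-norm route at desk scale; group counts match the emulated
designs exactly.

All randomness flows from one integer seed through `numpy` seed sequences;
identical configurations reproduce identical datasets bit for bit.

**What the generator does not emulate**: substantive effect sizes, cultural
content, serial dependence within persons, item covariance structure beyond
the single valence factor, and systematic responder drift.  Passing the
bundled tests therefore shows that the screening and clustering machinery
behaves correctly on data with the right *structure* (nesting, scales,
missingness, zero inflation, normative similarity), not that the empirical
cluster composition of any real dataset is reproduced.

## Numerical choices

* Duplicate/complement tolerance 1e−9 (relative); symmetry and identity
  tests at 1e−12; centering post-conditions at 1e−10.
* Correlations are clipped to [−1, 1] and dCor to [0, 1] against rounding
  spill; dCov² is clamped at 0.
* Degeneracy screening rounds to 9 decimals before mode counting.
* Ward input validation requires symmetry, nonnegativity and a zero
  diagonal; heights are checked nondecreasing in the tests.

## Known limitations

* The 43-measure retained list and the three excluded exemplars are
  implemented; the several dozen other excluded measures from the original
  88-measure pool are out of scope, so the full 88→43 trajectory is not
  reproduced (it also requires the original empirical datasets).
* Statistical inference on measure values — confidence intervals,
  reliability — is out of scope.
* The McCrae and Kohonen formulas are the transcriptions documented above;
  reconciling them against the original sources' exact algebra is an open
  item.
* `cut_longest` can legitimately return two main clusters on datasets
  where the difference and product families are strongly anticorrelated
  (their `1 − |ρ|` distance is small); the modal count across the five
  datasets is the robust summary.
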