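# Methods

This note records the models behind each stage, the parameters that matter,
what the synthetic generators do and do not emulate, and the numerical and
design choices made where more than one reasonable option existed.

## Droplet occupancy and pairing efficiency

Beads and semibulks are loaded into droplets independently, each at a
concentration summarised by λ, the mean number of objects per droplet. The
number of objects of one kind in a droplet is Poisson:
p(k, λ) = λ^k e^{−λ} / k!, evaluated in log space (via `gammaln`) so large k
cannot overflow.

`fit_lambda` offers two estimators because occupancy data are reported as
category fractions (droplets with k = 0, 1, 2, 3 objects):

- `mean` (default): the occupancy-weighted sample mean Σ k·c_k / n, which is
  the Poisson MLE when the top category is not truncated. When droplets with
  k ≥ kmax are binned, this estimator carries a small downward bias —
  negligible for λ ≤ 1, which is the regime the device is run in.
- `least_squares`: minimises the squared error between observed category
  fractions and the model fractions over k = 0..kmax, treating the top
  category as "kmax or more". This matches fitting a curve to the plotted
  category ratios and is truncation-aware.

On simulated tables with λ ≤ 1 and n ≥ 10,000 the two agree within 5%. An
all-empty table yields λ = 0 with a warning flag rather than an error.

Pairing efficiency is reported two ways: the small-λ product λ_s·λ_b (the
design heuristic — for λ_s = 0.03, λ_b = 0.66 it gives 0.0198 ≈ 0.020 at
two significant figures, the report precision used throughout), and the
exact probability of exactly one bead and one semibulk,
p(1, λ_s)·p(1, λ_b), which is lower by the factor e^{−(λ_s+λ_b)}.

## Barnyard multiplet calling

Units are called from dual-genome UMI counts with two thresholds, both
strict inequalities: a unit is kept when total UMIs exceed `umi_min`
(default 1000), and a kept unit is a multiplet when both genome fractions
exceed `multiplet_fraction` (default 0.25). "Fraction" means the unit's UMI
share per genome; raw read counts are not used. A 50/50 unit is a multiplet
by the rule (both fractions exceed any threshold below 0.5); exact-threshold
fractions fall on the singlet side, a convention the calling rule's wording
("more than") implies but does not spell out. Percentages are reported over
non-filtered units at one decimal place.

The synthetic barnyard mixture labels each unit multiplet with the requested
rate, otherwise species A/B with equal probability; singlets draw UMIs
binomially with own-genome probability `purity` (default 0.99, standing in
for ambient cross-contamination, which is not modelled further) and
multiplets with probability 0.5, the expectation for a 1:1 mixture. Only
cross-species collisions are observable; same-species collisions are
invisible to this assay by construction.

## QC

A unit passes QC when it expresses at least `min_genes` genes (count > 0 —
no per-gene minimum) and its mitochondrial UMI fraction is at most
`max_mito` (default 0.25). Named profiles carry the floors appropriate to
different material: 1000 genes for deeply sequenced tissue, 200/500 for
shallow clinical samples. Mitochondrial genes are identified by an explicit
mask when available, else by id prefix (`mt-`/`MT-`), configurable because
reference annotations differ. The discard report assigns each removed unit
its first failing rule, gene floor checked first, so reasons partition the
discards. Medians (summary statistics) use the mean-of-central-pair
convention for even n. Normalisation scales each unit to 10,000 total
counts, optionally log1p — but see below: deconvolution never uses the log
scale.

## Signature construction

Reference units are normalised to 10,000 counts before averaging so cluster
depth differences cannot bias profiles; per-type means are the candidate
signature columns. Markers are chosen per type by fold change: (type mean) /
(max other-type mean), requiring fold ≥ `min_fold` (default 2) and keeping
the top `markers_per_type` (default 50) by fold, ties broken by expression
then gene order — a transparent criterion chosen over more elaborate
differential-expression machinery because the downstream solve only needs
columns that are mutually discriminable. A type with no qualifying gene is
an error naming the type. The signature is restricted to the union of
markers. The number of cell types is an input property throughout, never
hard-coded.

## Deconvolution

UMI counts mix linearly in the cell-type fractions, so each unit is solved
on the linear scale: both the unit vector and the signature columns are
scaled to a common total, the nonnegative least-squares problem
min_{w≥0} ‖S w − x‖ is solved (Lawson–Hanson NNLS), and the coefficients
are renormalised to sum to one. Log-space solving is deliberately not
offered — log1p distorts the mixing identity. The reported residual is the
relative L2 misfit of the unnormalised solution. A pathological all-zero
solution yields a uniform composition flagged `uniform_fallback` rather
than an error, so one degenerate unit cannot abort a matrix run. Scale
invariance (composition independent of unit depth) follows from the
normalisation and is tested.

Widely used reference-based tools solve this same estimation problem with
support-vector regression; NNLS with sum-to-one renormalisation was chosen
as a transparent, deterministic formulation adequate for the downstream
presence/absence statistics. The composition TSV format is tool-agnostic,
so externally produced composition matrices can be imported and analysed
with the co-occurrence and comparison stages directly.

Presence reporting uses a strict 3% fraction cut by default
(`presence_threshold`, `presence_overlap`), the conventional cut for
quoting which units "contain" a minor cell type.

## Co-occurrence statistic

Per cell type, units are classified present when their fraction strictly
exceeds the across-unit median for that type (ties therefore fall to
absent; a constant column is all-absent and its pairs are untestable). For
each unordered pair the 2×2 present/absent table is tested for independence
with the closed-form 1-df chi-square n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)).
Choices worth recording:

- **Continuity correction** off by default, available by flag; library
  defaults for 2×2 tables differ and the correction is conservative at
  these sample sizes. Both paths are tested against an independent
  implementation.
- **Direction filter**: only positive associations are kept — each type's
  presence probability conditional on the other's presence must reach its
  marginal. The rule is applied symmetrically by default; for a 2×2 table
  positive dependence is symmetric, so the one-directional variant (kept
  for the literal reading) differs only on degenerate tables.
- **Degenerate margins** (a type never/always present) make a pair
  untestable: p = 1, flagged, excluded from ranking.
- **No multiple-testing correction** enters the ranking — pairs are ranked
  by raw p (ties: χ² descending, then pair name) and reported as −log₁₀P; a
  Benjamini–Hochberg q-value column is emitted as supplementary output.
- **Small expected counts** (< 5) flag the pair `low_expected` but do not
  suppress it.
- p-values are floored at 1e−300 so −log₁₀P stays finite.

Under the independence null (independently generated presence columns) the
test's type-I error at α = 0.05 is nominal within Monte-Carlo error; note
that the columns of one composition matrix are *not* such a null — the
simplex constraint induces negative cross-type dependence, which is exactly
why the positive-direction filter discards most pairs of a featureless
Dirichlet composition set.

## Planted colocalization: mechanism

The generator plants a positive association between a chosen pair by
giving each affected unit (probability = `strength`) a single shared
co-abundance mass z ~ Exponential(mean (boost−1)·E[fraction]) added to
both types' fractions before renormalisation; `boost` (default 3) is the
expected multiplicative lift of each planted fraction.

The obvious alternative — multiplying both fractions by a constant and
renormalising — was implemented first and rejected after simulation: on the
simplex the boosted pair competes for bounded mass (A′+B′ ≤ 1), so within
boosted units the two fractions are *negatively* coupled, and once the
planting probability exceeds one half the median split falls inside the
boosted majority, where only that negative coupling is visible. The planted
pair then shows the *smallest* p-value with the *wrong* sign and is
correctly discarded by the direction filter. No multiplicative variant
(larger constant, shared random multiplier, tighter Dirichlet) survives
this at high strength, because the mechanism saturates at A′ + B′ → 1 with
A′ anti-correlated to B′. The additive shared mass instead drives both
fractions up *together* (toward 0.5 each in the limit), so the planted pair
is a genuine positive presence association at any strength; recovery is
essentially certain at strength 0.9 with 2000 units.

## Synthetic generators: what they emulate and what they do not

Compositions are Dirichlet (symmetric concentration 1 by default; an
archetype-mixture generator models platforms sampling discrete anatomical
niches), and counts are depth-limited multinomial draws from the
composition-weighted mixture of reference columns, with an optional
Dirichlet-multinomial overdispersion knob (`dirichlet_multinomial_phi`).
Reference profiles share one baseline expression level across types, with
per-type marker genes planted at 6–12-fold enrichment; marker block masses
are equalised across types so the ≥ 5-fold guarantee survives column
normalisation exactly, and marker baselines are drawn bounded away from
zero because a marker that cannot be detected at realistic depth is not a
marker. Unit depth is a constant, a uniform range, or per-unit values — the
fragment-size (cell-count) distribution of real material is not asserted,
only its consequence, variable depth.

Not emulated: batch effects, ambient RNA in the expression matrices,
cell-level spatial coordinates, gene–gene correlation beyond the mixture
structure, and read-level artefacts (the package starts at count matrices).
Passing tests therefore demonstrate correct statistical machinery under a
known generative model, not robustness to those real-data complications.

## Platform comparison

Pooled compositions (cell-type intersection, rows renormalised) are
clustered agglomeratively — Euclidean distance, complete linkage, cut at
k = 3 by default, mirroring the R heatmap-clustering conventions this
analysis is usually paired with; metric, linkage and k are configurable
(Ward requires Euclidean). The mixing fraction is the share of semibulk
units in clusters containing at least one spot — "clustered with" has no
sharper standard definition. It equals 1 at k = 1 by construction and is
meaningful only relative to a null band: in simulations where both
platforms sample the same niches it sits at ~1, and a platform-private
niche depresses it by roughly that niche's prevalence. Published mixing
percentages from real tissue depend on the k and linkage used there and on
the tissue itself; only the statistic's definition is reproduced here.
Expression correlation between a semibulk and a spot is Pearson on log1p of
10,000-scaled expression over shared genes expressed in at least one of the
two units.

## Pipeline

`run_pipeline` executes simulate → qc → signature → deconvolve →
co-occurrence → compare from one validated config with a mandatory seed;
all stage randomness derives from spawned child seeds. Every artifact is
written with fixed float formatting and hashed (SHA-256) into a manifest,
making nondeterminism detectable by hash comparison; reruns with the same
config are byte-identical. Stage failures halt the run naming the stage
(and, for unit-level failures, the unit).

## Problem sizes

Simulation-backed checks run at sizes chosen to give comfortable
Monte-Carlo margins while staying quick on one CPU: 100,000 droplets for λ
recovery, 3000 units for barnyard rate recovery, 200 units × 4 types at
depth 5000 for deconvolution recovery, 500 null pairs of 1000 units for
test calibration, 100 runs of 2000 units for planted-pair power, 20 seeds
of 200 + 200 units for the mixing-fraction bands, and a 500-unit end-to-end
run. The full suite completes in well under a minute.

## Known limitations

- NNLS composition estimates are biased toward sparse solutions at low
  depth; residuals are reported but not propagated into the co-occurrence
  stage.
- The chi-square test is asymptotic; heavily imbalanced presence margins
  yield `low_expected` flags and should be read with care.
- The mean λ estimator ignores top-category binning (use `least_squares`
  when truncation matters).
- Median dichotomization discards magnitude information by design; weak
  but broad colocalization may rank below strong niche effects.
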