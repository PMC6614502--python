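# Methods

`blankqc` quantifies what a blank injection does to an LC-MS system and
whether the system has re-equilibrated before the next samples are used.
This note records the models and procedures implemented, the assumptions
they make, the defaults and why, and what the synthetic validation does and
does not demonstrate.

## Batch model

A batch is an ordered injection sequence: a leading block of conditioning
QC injections, then repeated *cycles*, each opened by a group of extraction
blanks (three consecutive blanks for an intense deconditioning, a single
blank for a mild one) and followed by eight replicate sample injections
that recondition the system. `annotate_sequence` derives this structure
from the ordered class list alone: a maximal run of consecutive blanks
opens a cycle, the k-th subsequent sample gets post-blank position k, and
everything before the first blank belongs to cycle 0. Positions beyond 8
are annotated with a warning rather than rejected, since the design never
uses more but real worklists can deviate.

## Within-batch drift correction (QC-SVRC)

Each feature's intensity trend over run order is modelled by
ε-insensitive support vector regression with an RBF kernel, trained on
*reference* injections — the leading QCs plus the last sample of each
cycle, i.e. the samples injected immediately before a blank, which are in
the fully conditioned state. Corrected areas are

    corrected(f, t) = area(f, t) · median(ref areas of f) / trend(f, t).

Multiplicative correction is used because intensity drift acts as a gain
change and division preserves non-negativity; the trend is floored at
1e-6 of its own median magnitude before division. Only areas are
corrected; RT and peak width are never drift-corrected.

Hyperparameters per feature:

* `C` — fixed at the median reference intensity (no search).
* `ε` — grid over 3–10 % of the median reference intensity, the expected
  instrumental precision band (8 values by default).
* `γ` — log-uniform grid over [1, 1e5], 26 values by default. The kernel
  is defined on run order **normalised to the span of the references**, so
  γ = 1 corresponds to a kernel as wide as the batch (near-constant trend)
  and γ = 1e5 bends at the scale of a single injection. On raw
  injection-number units every value in [1, 1e5] would be narrower than
  the spacing between references and the trend would collapse to the SVR
  intercept between them; normalising makes the interval span the
  smooth-to-wiggly range the search is meant to cover.

(ε, γ) minimise the leave-one-out RMSECV over the grid; exact ties break
toward smaller γ (smoother trend), then larger ε (flatter fit) — a
conservative-correction preference. Features with fewer than four positive
references, or with a failed fit, pass through uncorrected and flagged.
Constant reference intensities short-circuit to a constant trend with
RMSECV 0. `correct_table` also accepts externally supplied trend curves
(e.g. from a different smoother, or known generating curves in
simulations), in which case the SVR step is skipped and only the division
is applied.

Note a structural limit: because ε is at least 3 % of the reference
median, the SVR trend tracks any drift only to within a few percent
(support vectors sit on the ±ε tube). Exact flattening of a known drift is
therefore only achievable with the true trend supplied; the SVR route is
instead held to a precision criterion (corrected reference RSD below raw
reference RSD for ≥ 95 % of drifting features at 5 % noise).

## Feature screening

On the corrected table, a feature is **informative** iff all of

1. min(area in biological samples) / max(area in blanks) > 9 — strictly;
   a zero blank maximum counts as an infinite ratio;
2. more than 90 % (strictly) of biological replicates exceed 9 × the blank
   maximum;
3. RSD of the corrected reference injections < 20 %.

"Biological samples" are the sample-class injections; leading QCs are
excluded from coverage by default (configurable). **Column carry-over +k**
(k = 1..3) is a detection pattern evaluated per intense cycle on the
pre-gap-filling detection mask: present in blanks 1..k, absent from blanks
k+1..3, absent from post-blank samples 1..k, present from sample k+1
onward. By default the pattern must hold in every intense cycle
(`match_fraction = 1.0`); mild cycles carry no information about blanks
2–3 and are ignored for patterning. Features shared between samples and
blanks without a carry-over pattern are **contaminants**; the residual
class is **excluded**. Precedence is informative > carry-over >
contaminant. When no explicit detection matrix is available, detection
falls back to `area > threshold` (default 0) on the gap-filled areas,
documented as a weaker surrogate.

## Conditioning assessment (guided PCA)

For each deconditioning type and each post-blank position n = 1..7, the
*conditioning set* (samples at position n, pooled over cycles) is compared
with the *reference set* (samples at position 8). With X the
column-centered stacked area matrix and Y the n×2 group-indicator matrix
with unit-length columns, the guided direction v_g is the first right
singular vector of YᵀX and

    δ = var(X v_g) / var(X v_1),   v_1 = first right singular vector of X.

Since v_1 maximises var(Xv) over unit vectors, δ ∈ (0, 1]; δ near 1 means
the split between the two sets dominates the data's variance. Significance
is a label-permutation test: p = #{δ̂ < δ̂_p}/m with strict inequality and
no add-one correction (m = 1000 by default; a conservative
(count+1)/(m+1) variant is available but off by default). Labels are
permuted over the pooled two-set rows without preserving cycle structure.
Columns are centered only; autoscaling is available behind a flag but off,
as centering is the minimal preprocessing under which the δ ≤ 1 bound and
its interpretation hold.

Per position the module also runs per-feature Welch (unequal-variance)
t-tests on area, RT and width against the reference set, adjusts p-values
by Benjamini–Hochberg separately within each metric and position (the
narrowest consistent family), and counts adjusted p < 0.05. The summary
reports a *recovery position*: the smallest n from which the significant-
area count stays at or below the false-positive level (α × n informative)
for all later positions.

Each position draws its permutations from a seed spawned deterministically
from (seed, n); the whole module is bit-reproducible given (m, seed).

## Blank PCA

PCA (SVD of the column-centered matrix; component signs fixed so the
largest-magnitude loading is positive) of the blanks restricted to
non-informative features, annotated by within-group blank position.
Carry-over features load on the blanks injected immediately after a sample
run, separating first-position blanks from later ones along the leading
component.

## Profile clustering

Per feature, corrected areas are averaged per relative position within a
cycle (blank positions, then sample positions 1..8) over all cycles of one
type, then z-scored per feature; constant rows are flagged and excluded.
Hierarchical clustering uses d = 1 − Pearson correlation with average
linkage (complete/single configurable; average is the standard choice with
correlation distances), cut at k = 2 because two main response families
are of interest; the full linkage matrix and a Newick rendering are
emitted so other cuts remain possible. Cluster 1 is the larger cluster
(ties break toward lower median RT). Because 1 − r is invariant to
positive affine maps of rows, the z-scoring affects only displayed
profiles, not the clustering itself. Each cluster's member submatrix can
be fed back through the δ-curve machinery for per-cluster assessment.

## Synthetic batches and planted truth

The generator emulates the study design: 10 leading QCs, 8 intense plus 8
mild cycles (170 injections) by default, with every feature planted in one
of seven classes. Intensities are baseline (log-uniform over 4 decades,
1e4–1e8) × smooth multiplicative drift (random cubic spline through 5
knots, peak deviation `drift_amplitude`, default 15 %) × deconditioning
response × multiplicative log-normal noise (`noise_rsd`, default 5 %,
matching the injection-standard precision scale of well-behaved batches).

The post-blank response is piecewise linear through (0, 1),
(p_max, 1 + max_dev), (k, 1): the simplest shape consistent with a
response that peaks a few injections after the blank and recovers at
position k. Defaults: cluster 1 — p_max 1, k 4, max_dev 0.10 (small
immediate deviation, gone by position 4); cluster 2 — p_max 3, k 6,
max_dev 0.50 (gradual rise to a maximum at position 3, recovery at 6).
The magnitudes are assumptions (only profile shapes are constrained by
observation) and are configurable. Mild cycles apply the same shape with
deviations attenuated by `mild_attenuation` (default 0.5). Cluster-2
features are planted late-eluting (RT 4.6–6 min) and additionally shift in
RT (0.04 min, the magnitude seen for late-eluting lysophospholipids) and
peak width (15 % relative), both decaying with the same response shape.

Informative features carry zero area and `detected = False` in blanks
(extraction blanks contain no matrix), so the blank-ratio condition holds
for them by construction. Contaminants appear everywhere at
sample-comparable intensity. Carry-over +k features follow their detection
pattern exactly, with blank intensity halving per blank position.
Every feature draws from its own seeded sub-stream, so adding features
leaves existing ones bit-identical.

The urine-like preset removes deconditioning, carry-over and RT/width
shifts entirely (blanks and matrix alike in polarity) and keeps
contaminants — a pure null for the conditioning statistics.

What the generator does **not** emulate: raw chromatographic peak shapes,
co-elution and ion suppression, correlated noise across features,
between-batch effects, missing-at-random gaps, heteroscedastic detector
saturation, or carry-over intensity dynamics beyond a geometric decay.
Passing the planted-truth tests therefore shows the pipeline recovers the
structure it models, not that real batches are this clean; on real data
the screening counts and recovery positions should be read as estimates,
not ground truth.

## Numerical choices

* All thresholds are strict inequalities exactly as specified (ratio > 9,
  coverage > 0.90, RSD < 20, permutation p without +1).
* PCA/δ use dense `numpy.linalg.svd`; the δ test oracle is an independent
  eigendecomposition of the cross-product matrices (agreement ≤ 1e-10).
* The LOO grid search calls scikit-learn's bundled libsvm solver directly
  (tiny fits dominated by Python validation otherwise); predictions are
  asserted identical to public `sklearn.svm.SVR`.
* Degenerate Welch inputs (zero variance in both groups) give t = 0,
  p = 1 on equal means, p = 0 otherwise.
* Text outputs are written with `%.17g` and read with round-trip float
  parsing, so write/read cycles are bit-exact.

## Problem sizes used in the test suite and acceptance script

Synthetic presets use 260 (plasma-like) / 250 (urine-like) features —
about one-fifteenth of the real batches — with the full 170-injection
design; heavy tests and the acceptance script use a 4 × 9 (ε × γ) grid
and m = 200 permutations, while library defaults remain 8 × 26 and
m = 1000. These sizes are the package's own desk-scale choices; all
statistical conclusions (recovery at the planted position, null
calibration, label recovery) are insensitive to them in the seeds
exercised.

## Known limitations

* Reference samples double as the position-8 comparison set, mirroring the
  design ("samples injected before a blank were used as QCs"); correction
  residuals at references are therefore slightly ε-tube-shaped.
* Carry-over patterning requires at least one intense (3-blank) cycle;
  batches with only mild cycles get contaminant/informative labels only.
* δ's permutation null permutes pooled labels freely; if cycle-level
  autocorrelation is strong, the null is mildly liberal.
* The detection fallback (`area > 0` after gap-filling) can miss the
  carry-over absences that define the +k patterns; supply the pre-fill
  detection matrix whenever available.
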