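# Methods

This note documents the statistical models and procedures `cytorisk`
implements, the defaults it ships, and the design choices made where the
procedure admitted more than one reasonable reading.

## Endpoint and data model

The endpoint throughout is distant (metastatic) recurrence: per sample a
follow-up time in years (> 0) and an event indicator (1 = distant
recurrence observed, 0 = censored), with optional clinical covariates
(nodal status LN−/LN+, tumor grade I/II/III, source site).  Expression
travels as a samples × genes matrix with explicit missing values and a
platform tag: `rtpcr` for ΔΔCT-scale values, `microarray` for
log-expression.  These two scales run in opposite directions (a higher
ΔΔCT means more amplification cycles, i.e. *less* transcript), which
matters for signature orientation — see below.

## ΔΔCT normalization

For sample *s* and gene *g*:

    ΔCt(s, g)  = Ct(s, g) − mean(Ct(s, reference genes))
    ΔΔCt(s, g) = ΔCt(s, g) − ΔCt(calibrator, g)

Defaults: reference genes NUP214 and PPIG aggregated by arithmetic mean
(standard ΔΔCT practice; the two reference probes are measured jointly in
one mix, and no weighting is specified anywhere, so the mean is the
natural choice); amplification cycle cap 40 (configurable) — a Ct at or
beyond the cap is treated as failed amplification and propagates to a
missing ΔΔCT.  A sample missing a reference-gene Ct loses all its values
(warning); a gene missing from the calibrator loses its column.

Multi-site pooling: each gene is median-centered within source site over
the analysis set before cohorts are combined.  Centering is computed on
the analysis set only (whether the original analysis centered before or
after excluding non-evaluable samples is not documented; centering on the
analysis set is the self-consistent choice).  The operation is idempotent
and leaves missing entries missing.

Source-bias QC: samples are clustered hierarchically (complete linkage)
on pairwise-complete Euclidean distance rescaled by √(p/p_shared), so
samples with missing genes remain comparable; the dendrogram is cut into
`n_branches` (default 2 — a count is not prescribed, so it is exposed as
a parameter) and branch × site composition is tested with the Fisher
exact test — exactly for 2×2 tables, otherwise by a seeded Monte-Carlo
approximation (tables sampled under fixed margins; P = probability of a
table at most as probable as the observed one).  The Monte-Carlo path is
validated against the exact 2×2 computation to within 0.01 in the test
suite.

## Signature indices

A signature is a set of (gene, sign) terms; its index for a sample is the
sign-adjusted mean of the member genes' values.  Built-ins: IR-7 (SPP1 +,
six immune genes −, divisor 7), Buck-4 (+RGS4 −CLIC5 +CXCL13
+RPS28//FLJ46061, divisor 4), the five-gene ICS (−CLIC5 +CXCL13 +HLA-F
+TNFRSF17 +XCL2, divisor 5), and a provisional 12-member Buck-14 roster
kept for membership bookkeeping only.  Gene-symbol variants (HLAF/HLA-F,
IGCL2/IGLC2, FLJ46061/RPS28//FLJ46061) are collapsed by a single alias
table.

Missing-data policy: if any constituent gene of a sample is missing, the
sample's index is not computed, and the offending genes are recorded as
the reason.  Indices are Z-transformed within cohort (mean 0, SD 1 with
n−1 denominator, over non-missing scores); constant or near-empty score
vectors are errors, not silent NaNs.

Orientation: index formulas are applied literally to whatever scale the
matrix carries.  Because the IR-7 formula presupposes a log-expression
scale while the ICS formula's signs presuppose a ΔΔCT scale, no choice of
scale makes every printed formula risk-increasing at once.  The package
therefore never flips signs silently: `SignatureScorer(flip_sign=True)`
is the single, explicit orientation control, and the platform tag records
which scale a matrix carries.  Reproducibility is preferred over guessed
intent.

## Survival statistics

*Cox regression* uses lifelines with the Efron approximation for tied
event times (the default of the reference survival implementations this
pipeline mirrors) and a tightened Newton tolerance (1e−12) so
coefficients agree with direct partial-likelihood maximization to 1e−6.
Complete cases only; dropped samples are counted.  Reported per
covariate: coefficient, HR per unit, Wald 95% CI and P; per model: the
likelihood-ratio P against the null and Harrell's C of the linear
predictor.  Monotone-likelihood (separated) fits are flagged.

*Harrell's C* counts ordered pairs (i, j) with subject i an event and
t_j > t_i; tied predicted scores count ½; pairs with tied times are not
comparable.  The CI is the Noether-type normal approximation
C ± z·√(C(1−C)/m) over m comparable pairs — an approximation chosen for
transparency, adequate at the cohort sizes involved.  The implementation
is exhaustive pair counting (vectorized), checked in the tests against an
independent enumeration oracle and against lifelines.

*Kaplan-Meier / log-rank*: product-limit estimation with S(t) lookups
using events at times ≤ t; the two-group log-rank chi-square (df 1) comes
from lifelines and is checked against a hand-tabulated O−E/V example and
a permutation null.  Five-year DR-free fractions are S(5.0); a horizon
beyond a group's last observed time is flagged as extrapolated.

*Dichotomization*: median splits send ties at the median to the low
group.  The constrained optimal cut-point scans midpoints between
consecutive distinct scores (observed values would be the alternative;
midpoints keep thresholds strictly between data points), keeps candidates
leaving ≥ `min_frac` (default 20%) of samples in each group, and returns
the feasible candidate minimizing the log-rank P, ties resolving to the
smaller threshold.  Because the minimized P is an optimum over many
tests, it is descriptive, not an honest significance level.  Fixed
thresholds support cut-point transfer across cohorts and platforms; a
threshold stranding all samples on one side yields a result with an
undefined P and a warning rather than an error.

## Gene prioritization

Given per-gene P values from three models — training-cohort multivariate
(all roster genes jointly), validation univariate, validation
multivariate — a gene is high priority iff: (1) training multivariate
P < 0.15; (2) validation univariate or multivariate P < 0.15; (3) any of
the three P < 0.05.  A missing P fails the criterion it serves.  The
validation multivariate model contains the full roster (whether it should
instead contain only criterion-1 survivors is not documented; full-roster
is the default and the gene list is a parameter).  The filter is a pure
function of the P-value table, and relaxing either threshold can only
grow the priority set (property-tested).

## Forward-stepwise signature optimization

Candidate pool: the 11-gene union of the IR-7 and Buck-4 constituents,
each gene carrying the sign of its parent formula, fixed a priori and
never re-estimated (no gene is shared between the two parents, so no
conflict arises; a conflict would be a configuration error).  Before the
search, samples are restricted to those complete in every pool gene so
likelihood-ratio statistics are comparable across candidate models
(per-candidate complete cases would change the sample set between
candidates and make the objective incoherent; it remains available as an
option).  Step 1 picks the gene whose one-gene index has the smallest
Cox LR P — the same criterion as every later step; at step k+1 each
unused gene is trialed in the (k+1)-term sign-adjusted mean, the index is
Z-transformed (orientation consistency; LR P and candidate ordering are
unaffected by the affine rescaling), and the minimizing gene is added.
The path runs through the whole pool; the selected signature is the
prefix with the global minimum P, ties favoring the smaller subset.  The
procedure is deterministic.

The inner loop uses a dedicated 1-D Efron partial-likelihood solver
(bounded Brent on the exact log-likelihood) rather than a general Cox
fitter, for speed; it is tested to agree with lifelines to 1e−6 on both
coefficients and LR P values, with and without tied times.

Selection bias: the minimized P is the minimum over ~66 fitted models and
is therefore optimistic, and at ~139-sample scale the selected membership
varies from draw to draw.  This is documented behavior, not something the
package attempts to correct.

## Survival-tree risk modeling

The tree reimplements the exponential-deviance survival method of CART as
popularized by R `rpart` (`method = "exp"`): observed times are rescaled
by the full-sample Nelson-Aalen cumulative hazard into exposures e_i, so
event indicators d_i follow a Poisson model with node rate λ = Σd/Σe and
node deviance 2Σ[d log(d/(λe)) − (d − λe)].  Among the documented
variants of rpart's internal time-scaling, this implementation pins the
full-sample cumulative-hazard transform computed once before growing
(fold-specific retransforms change third-decimal details only).  Splits
maximize the parent-minus-children deviance reduction subject to:

* minimum terminal size 20 (a stability constraint on every leaf, and no
  node with fewer than 40 cases is split);
* growth threshold cp = 0.01 of root deviance (rpart's default);
* grade is encoded as ordered 1/2/3, so its candidate splits respect the
  I/II vs III ordering; nodal status is binary; signature scores are
  continuous with midpoint thresholds.

Pruning builds the nested cost-complexity sequence by iteratively
collapsing the weakest link; candidate complexity parameters are the
geometric means of successive critical values (plus the endpoints).  The
final cp is the candidate minimizing the summed 10-fold cross-validated
held-out deviance — the literal minimum, not the 1-SE rule, per the
procedure's stated selection criterion — with ties resolved to the larger
cp (simpler tree).  Held-out samples are scored with fold-trained leaf
rates shrunk toward the fold root rate by a gamma prior of coefficient 1
(rpart's shrinkage), keeping event-free leaves finite.  Fold assignment
is fixed by `cv_seed`.  Missing covariates are handled by complete-case
deletion; no surrogate splits.

The first-split behavior is cross-checked against R rpart itself in the
test suite (same split variable, threshold within the data spacing).
Under null-hazard inputs the literal-minimum CV rule prunes to a
root-only tree about 90% of the time at n = 200 — the same rate rpart
exhibits under identical conditions — so occasional one-split null trees
are expected behavior of the specified procedure, not a defect.

Leaf reporting: per-leaf KM summaries with 5-year DR-free fractions and
human-readable rule paths.  `stratify_leaf` deliberately bypasses the
minimum-terminal constraint to support post-hoc within-leaf exploration
(e.g. stratifying a low-risk leaf by grade), returning per-stratum KM
summaries and a log-rank P for two-stratum covariates.

## Synthetic cohort generator

The generator draws, per sample: a latent immune score z ~ N(0,1); gene
values loading_g·z + N(0, noise_sd²); node-positivity Bernoulli; grade
categorical; a distant-recurrence time that is exponential with rate
baseline_hazard · exp(latent_beta·z + node_log_hr·[LN+]); and uniform
administrative censoring on (0, 2·m_site) so the censoring median equals
the site's target median follow-up — deliberately simple, with no dropout
structure.  Missingness is completely at random per gene (assay dropout
from low RNA input is plausibly unrelated to outcome).  Everything is
deterministic given the config seed.

Default calibration (the emulated study conditions, chosen analytically
and fixed):

* three sites of 58/36/45 samples, median follow-up 3.7/8.98/13.65 years;
* node-positive fraction 40/139; grade probabilities (0.015, 0.29, 0.695);
* latent_beta = log 1.8; baseline_hazard 0.04/yr (expected ≈ 41/139
  events under the null nodal effect); the study-emulating default also
  sets node_log_hr = log 3.8 so the clinical covariate carries real
  signal for the tree stage;
* loadings ±0.75 on the five optimized-index genes (TNFRSF17, CLIC5,
  HLA-F, CXCL13, XCL2), ±0.1 on the other six index constituents, 0 on
  eight decoy genes; noise_sd 0.8.  Signs follow the IR-7/Buck-4 parent
  formulas, making both literal parent indices rise with risk and giving
  an analytic IR-7/Buck-4 raw-index correlation ≈ 0.57; the magnitude
  split gives the stepwise search a genuine compact optimum;
* missing rates: MATN1 0.25, SSX3 0.18, HAPLN1 0.14 (three decoys above
  the 10% reporting threshold), XCL2 0.09, IGLC2 0.02, 0.007 elsewhere —
  in expectation ≈ 16/139 samples miss at least one optimized-index gene
  and ≈ 19/139 miss at least one IR-7 gene.

What the generator does *not* emulate: inter-gene correlation beyond the
single latent factor (real immune blocks have richer structure),
informative censoring, site-level batch effects in expression,
non-proportional hazards, and the raw Ct layer (ΔΔCT-scale values are
emitted directly; the Ct → ΔΔCT path is exercised by its own unit
fixtures).  Passing tests on these cohorts therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to the full messiness of archival FFPE data.

Parameter recovery is verified directly: Cox on the true latent score
recovers latent_beta with well under 10% relative bias at n = 2,000 over
200 replicates, and a null latent effect yields HR ≈ 1.

## Pipeline and reproducibility

`run_pipeline` chains acquire → QC → score → stepwise → tree →
cut-point analysis, halting with a stage-named error on failure.  One
global seed fans out to stages through named `SeedSequence` substreams,
so reruns are byte-identical and no stage reads the wall clock or global
RNG state.  Reports are JSON; tables are tab-delimited text with ``NA``
missing tokens and full-precision floats (exact round trips).

Problem sizes used by the shipped verification runs — 100-replicate
recovery/null simulations at n = 200–400, 200-replicate parameter
recovery at n = 2,000, oracle comparisons at n ≤ 50 — were chosen to make
the Monte-Carlo assertions stable at desk scale while keeping the whole
suite in the low minutes.

## Known limitations

* The optimal-cut-point and stepwise P values carry selection bias by
  construction (documented above).
* Harrell's C CI is a Noether-type approximation, not the
  infinitesimal-jackknife variance.
* The tree offers no surrogate splits, variable importance, or
  competing-risk handling; covariates must be encoded numerically.
* Cross-platform transfer applies a fixed threshold to re-Z-transformed
  scores; it does not attempt distributional calibration between
  platforms.
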