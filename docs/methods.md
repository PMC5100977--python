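# Methods

## The analysis model

The package analyses a subjects × markers matrix of plasma concentrations
with a group label per subject and, for patients, a Short Sensory Profile
(SSP) total score.  The workflow treats the marker panel as a multivariate
profile and asks, in order: is the panel factorable (KMO, Bartlett); how many
axes of shared variance does it have (PCA + parallel analysis); do subjects
cluster by group in profile space (Canberra MDS, neighbor joining); can
group membership be predicted from the profile (leave-one-out KNN library
identification, MANOVA); and which markers predict the continuous severity
score (correlation screening, stepwise regression).

### PCA normalization

Concentrations from different assays live on incommensurate scales, so the
decomposition is always done on unit-variance variables.  Two equivalent
modes are exposed (`correlation`, and `covariance_normalized` which rescales
each marker by its standard deviation before taking the covariance); they
yield identical eigenvalues and variance shares, and the redundancy is kept
deliberately so either convention found in statistics packages can be named
explicitly.  A literal variance-division variant (`variance_division=True`)
exists for auditing against software that divides by the variance rather
than the standard deviation; it is not the default because it leaves
residual scale differences (values end up in units of 1/concentration).
Eigenvalues use the n−1 denominator; component signs are fixed by making
each component's largest-magnitude loading positive; reported
"contributions" are signed variable coordinates, loading × √eigenvalue.
Ranking by contribution magnitude is the supported use; the absolute scale
of contribution values differs between software packages and is not treated
as comparable across implementations.

### Parallel analysis

Component retention compares observed eigenvalues with percentiles of
eigenvalues from reference datasets.  The default reference permutes every
marker column independently within the observed data (preserving marginals,
destroying correlation); a standard-normal reference (`method="normal"`) is
also available.  With 1000 replicates the 50th and 95th percentile curves
are computed per component, and the number of retained components is the
length of the *leading run* of components whose observed eigenvalue exceeds
the 95th percentile.  Counting the leading run rather than every exceedance
matters: with p components each carrying a ~5% false-exceedance rate, a
"count all" rule would flag some component in roughly 1−0.95^p of null
datasets (~30% at p = 7), whereas the leading-run rule keeps the null
retention rate at the nominal ~5% and matches how scree plots are read in
practice.  Per-component exceedance flags remain available on the result.

### Canberra geometry

Subject dissimilarity is the averaged Canberra distance
D(X,Y) = (1/n)Σ|Xᵢ−Yᵢ|/(|Xᵢ|+|Yᵢ|), computed on raw concentrations — the
per-marker normalisation is built into each term, so no prior
standardisation is applied (a `--standardize`-style sensitivity analysis can
be done by rescaling the table first).  Terms with Xᵢ = Yᵢ = 0 contribute 0
(two absent markers are not dissimilar).  The denominator is |Xᵢ|+|Yᵢ|, the
form under which the function is a true metric on non-negative data; for
concentrations the algebraically ambiguous variant |Xᵢ+Yᵢ| coincides with
it.  Inputs with negative entries trigger a warning, because the metric
axioms (needed for KNN and neighbor joining to be meaningful) are only
guaranteed on the non-negative orthant.

Ordination is classical (Torgerson) MDS: double-center the squared-distance
matrix and take the top eigenpairs.  Canberra matrices are generally
non-Euclidean, so negative eigenvalues appear; they are dropped with a
warning and the embedding uses the positive part only.  Dendrograms use the
Saitou–Nei neighbor-joining algorithm (via scikit-bio), which exactly
recovers additive distance matrices; negative branch lengths are clamped to
zero.  Trees serialize to Newick.

### Library identification

The classifier is deliberately simple and transparent: a *library* of
reference subjects partitioned into *units*; an unknown profile is compared
to every entry by averaged Canberra distance, its k nearest entries are
taken (ties on distance broken by entry order, making results
deterministic), and the unknown is assigned to the modal unit among them.
The score, 100 × (neighbors in the assigned unit)/k, reads as neighbor
unanimity: 100 when all k agree, 50 at an even two-unit split.  Unit-count
ties go to the unit of the single nearest entry, then to label order.

k must not exceed the smallest unit (otherwise the modal rule is biased
against small units); `identify_subject` defaults to that upper bound.
Under leave-one-out evaluation the held-out subject's own unit shrinks by
one, so the largest feasible k is the smallest unit size minus one — that is
the leave-one-out default, and requesting more raises an error naming the
maximum.  Per-unit rates are percent correct within each unit; the overall
rate is their unit-size-weighted mean.

### Severity analyses

SSP totals run 38–190 points.  Two conventions for the severe boundary
coexist: the instrument manual (below 142 severe, 142–152 mild-to-moderate,
153–190 typical) and the dichotomy used in group analyses (≤145 severe,
>145 mild-to-moderate).  `SeverityThresholds` holds both numbers;
`classify_severity` gives the three-class instrument reading and
`severity_group` the two-class analysis split, which is what the MANOVA and
severity-identification stages use (typical-range patients are lumped with
mild-to-moderate, as is standard when only patients are analysed).

Correlation screening reports two-sided Pearson and Spearman p-values per
marker; Spearman p-values are exact (full permutation enumeration) up to
n = 9 and t-approximate beyond.  No multiplicity correction is applied at
the screening stage by default, since the stage is descriptive and feeds the
selection procedure rather than a confirmatory claim.

Stepwise regression is the classical probability-of-F procedure: forward
entry of the candidate with the smallest partial-F p-value when it is below
p-enter (default 0.05), backward removal of any included predictor whose
p-value exceeds p-remove (default 0.10), iterated to a fixpoint (p-enter <
p-remove is enforced, which precludes cycling).  Candidates that would make
the design numerically singular (relative singular value below 1e-8) are
skipped with a warning.  Every intermediate model is recorded with R, R²,
adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), overall F and p.  An empty trace
(no candidate enters) is a valid result, not an error.

### MANOVA

One-way MANOVA uses Wilks' Λ = det(W)/det(W+B) on the raw scatter matrices
(Λ is invariant to per-marker affine rescaling) with Rao's F approximation,
exact for two groups; univariate one-way F tests are reported per marker.

## The synthetic cohort generator

`generate_cohort` draws from a one-factor Gaussian model:
x_ij = μ_{g(i),j} + λ_j f_i + ε_ij with one standard-normal latent draw per
subject and independent residual noise, and for case subjects an SSP score
s_i = α + Σ β_j x_ij + η_i clipped to [38, 190].  This is the minimal
structure that reproduces the diagnostics the workflow assumes: the group
mean shift creates one dominant shared-variance axis in the pooled cohort
(high KMO, one retained component, complete case/control separation), the
common factor creates positive within-group inter-marker correlation, and
the β's create a negative linear marker–severity relationship.  Positivity
of concentrations is obtained by construction — group means sit many total
standard deviations above zero — rather than by truncation, so the Gaussian
theory used in the parameter-recovery and calibration tests is exact; a
warning fires if more than 1% of draws come out non-positive.  Severity is
generated for case subjects only, mirroring designs in which controls do not
receive the sensory assessment.

`study_like_config` packages the study-shaped defaults:

| parameter | panel 1 | panel 2 | rationale |
|---|---|---|---|
| subjects | 35 + 38 | 29 + 16 | the two recruitment waves of such a study |
| markers | 7 | 6 | panel compositions |
| group means (assay units) | 12 vs 30 | 12 vs 30 | an ~8 within-group-SD shift, large enough for complete separation |
| factor loading λ | 0.2 | 0.2 | weak within-group correlation; the pooled correlation is dominated by the group shift |
| residual SD σ | 1.0 | 1.0 | sets the scale |
| severity β | −2 on PE only | −2 on PGE2, mPGES-1, 8-isoprostane | panel 1 severity signal is a single weak marker; panel 2 carries the real model |
| severity noise τ | closed form for R² = 0.09 | closed form for R² = 0.65 | τ² = β'Σβ(1−R²)/R², Σ = λλ'+σ²I |
| severity intercept | 204.5 | 324.5 | mean SSP ≈ 144.5, astride the 145 cutoff so both severity classes occur |

The loadings were fixed at design time by simulating the joint conditions
(pooled KMO ≥ 0.85, exactly one retained component on full cohorts, no
retained component on the panel-1 case subset, adequate stepwise selection
power) and are not data-fitted.  `population_r2` gives the closed-form R² of
severity on the markers for any config and is the oracle for the
calibration tests.

### What the generator does and does not emulate

It reproduces panel sizes, group structure, factorability, separation and
the severity model — the properties the *method* depends on.  It does not
attempt real assay units or scales, marker-specific means, skewed or
heavy-tailed concentration distributions, richer covariance than one factor,
or the particular numeric values a real cohort produced (a real study's PC1
share, KMO values or regression R reflect its data; the synthetic analogs
reproduce the qualitative findings — dominant PC1, high KMO, perfect
case/control identification, a three-lipid severity model — not those
digits).  Passing tests therefore validate the machinery and its calibration
on data with the assumed structure, not the biological claims.

## Test design notes

- The stepwise selection-consistency check (three true predictors recovered
  in ≥80% of 200 cohorts at n = 29) uses a dedicated configuration with
  population R² = 0.75.  At R² = 0.65 split evenly over three correlated
  predictors, the per-predictor partial correlation is ≈0.43 and the joint
  probability that all three clear p-enter = 0.05 plateaus at ≈0.81 even as
  the predictor correlation goes to zero — a power ceiling of the procedure
  at that sample size, not an implementation property.  The study-shaped
  R² = 0.65 configuration is kept for the sample-R² calibration check
  (mean sample R² of the true three-predictor model within ±0.10 of 0.65
  over 100 cohorts).
- Monte-Carlo test sizes (100–400 seeds, 200 permutations inside
  seed-sweeps, 1000 permutations for single-cohort retention checks) were
  chosen so the full suite runs in well under a minute while keeping the
  binomial noise of each asserted rate far from its threshold.
- Oracles are independent of the code paths they check: Bartlett against a
  direct determinant evaluation, Wilks' Λ against explicit scatter matrices
  and against statsmodels MANOVA, OLS R² against the normal equations,
  KMO against OLS-residual partial correlations, neighbor joining against
  path-length matrices of randomly generated trees (dendropy), classical MDS
  against planar configurations, and LOO-KNN at k = 1 against brute-force
  nearest neighbors.

## Known limitations

- Classical MDS on Canberra matrices discards the negative-eigenvalue part;
  embedded distances understate the original dissimilarities slightly.
- Stepwise regression inherits the known inferential caveats of the
  procedure (post-selection p-values are optimistic); the package reports
  the conventional statistics and leaves inference adjustments to the user.
- The generator's Gaussian, one-factor, equal-loading structure makes
  several tests exact but is not a model of real plasma panels; see above.
- Missing data are rejected, not imputed.
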