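# Methods

## The coherence model

Global coherence measures how closely a discourse response tracks the
semantic content typically produced for its stimulus. The package operates
on an LSA word-vector space: a term–document count matrix is weighted
(log-entropy by default; tf-idf and raw exposed), factored by truncated
SVD, and each term's k-dimensional left-singular row is L2-normalized.
Determinism is guaranteed by a fixed sign convention (the largest-magnitude
loading of each singular vector is made positive) and a fixed start vector
for the sparse solver. Because stored vectors are unit-norm, cosine reduces
to a dot product; coherence itself is norm-invariant, so the normalization
is a convenience, not a modelling choice.

A response is preprocessed by lowercasing, splitting on non-alphabetic
characters (intra-word apostrophes kept, numerals dropped) and removing a
packaged function-word stoplist (articles, prepositions, pronouns,
auxiliaries, conjunctions, fillers such as "um"). The response vector is
the unweighted mean over token *instances* — a word used twice counts twice
(a type-mean is available via `composition="type"`). The prototype of a
task is the mean of control response vectors; each control is scored
against the prototype excluding itself, which keeps score and prototype
independent (self-inclusion can only raise a score, a property the tests
verify). Composite coherence is the mean over a participant's *present*
task scores: participants missing some tasks are retained, only those with
no scorable response anywhere are dropped. Deficit flags use the control
mean − 1.5·SD cutoff with the sample SD (n−1) and a strict `<`.

## Behavioural statistics

The 2×3 mixed ANOVA (group between, task within) is computed by pingouin,
complete cases only, with Greenhouse–Geisser corrected p reported alongside
the uncorrected value for within-subject effects; a direct sums-of-squares
fallback handles degenerate inputs the library rejects. Post-hoc paired
task contrasts are Bonferroni-corrected. The staged regressions are OLS
fits of composite coherence on (M1) phonological production, phonological
recognition, semantic processing; (M2) + verbal fluency, verbal quality,
motor speech; (M3) + executive functions; (M4) + interaction terms between
executive functions and every predictor significant at p < 0.001 in M1–M3,
built from mean-centred factors. R² is necessarily non-decreasing across
the nested models; ΔR² is reported per stage. Rank-deficient designs error
with the offending columns named.

## Lesion-symptom mapping

**VBCM** regresses behaviour on each within-mask voxel's continuous
abnormality plus covariates (age, months post-onset; lesion volume
optionally). The implementation residualizes both sides on the covariates
(Frisch–Waugh–Lovell), so the voxel coefficient's t equals the partial
correlation t with df = n − 2 − #covariates; the per-voxel t is verified
against both closed-form correlation t and full OLS in the tests. Voxel p
is two-tailed analytic; the map's sign convention is deficit-directed
(negative t = more damage, lower behaviour), and clusters are formed on
that sign by default (configurable to positive or both).

**SVR-LSM** takes binary lesions at voxels lesioned in ≥ 4 patients
(configurable), residualizes behaviour for the covariates, optionally
regresses lesion volume out of both the feature columns and behaviour, and
fits a linear ε-SVR. The weight map is back-projected from the support
vectors; fits run in the dual via a precomputed Gram matrix, which makes
each permutation refit O(n²) rather than O(n²·p). Hyper-parameters (C, ε)
are selected once on the observed data by seeded random search over
log-uniform C ∈ [1e-2, 1e3] and ε ∈ [1e-3, 1] with 5-fold cross-validated
MSE, and the same values are reused in every permutation refit —
re-optimizing inside each permutation would be prohibitively slow and adds
no validity. Each weight map (observed and permuted alike) is normalized
to unit L2 norm before the voxel-wise comparison: the permutation test then
asks *where weight concentrates*, not how large the map is overall, which
is what gives the multivariate route voxel-level power.

**Permutation inference.** With covariates, behaviour is permuted by the
Freedman–Lane scheme (permute the residuals of behaviour on covariates,
re-residualize). Voxel-level thresholds define suprathreshold sets;
clusters use 26-connectivity by default (6/18 available); the cluster-level
FWE p of an observed cluster of size s is (1 + #{permutation max cluster
size ≥ s}) / (n_perm + 1), so p ∈ [1/(n_perm+1), 1]. Cluster correction is
permutation-based throughout rather than random-field theory: it is
distribution-free and exact at any grid size. The paper-scale default is
10,000 permutations; tests and examples run at 300–1,000.

## The synthetic-data generator

The generator emulates a 20-control / 46-patient cohort.

*Transcripts.* Each lexicon (three task topics + one off-topic pool, all
disjoint from the stoplist) is split into five sub-topics; the corpus is
built from sub-topic documents with 15% within-topic leakage, giving graded
cosine structure (sub-topic ≫ topic > cross-topic). A participant draws a
Dirichlet preference over sub-topics — different speakers emphasize
different aspects of the scene, which is what gives even fully on-topic
responses realistic dispersion around the prototype — and a drift rate d:
each content token is off-topic with probability d. Controls:
d ~ N(0.05, 0.03), concentration 2.5, ~45 content tokens; patients:
d ~ N(0.32, 0.22) clipped to [0, 0.95], concentration 1.0, ~18 tokens. The
procedural task is the most focused (drift ×0.55, concentration ×3).
These values were calibrated once so that scored group means land near the
reference descriptive statistics (controls ≈ 0.83–0.92, patients
≈ 0.56–0.77 across tasks, patient SDs ≈ 0.1–0.2) and then frozen. The
generator does not attempt realistic syntax; function words are sprinkled
in only to exercise the preprocessor.

*Component scores.* Seven exactly orthogonal, zero-mean, unit-SD columns
per patient (QR of a demeaned Gaussian draw). Forward mode regenerates
coherence as X·B + intercept + ε with planted B = 0.132 (phonological
production), 0.101 (semantic processing), 0.08 (verbal fluency) and noise
SD 0.05 — chosen a priori by power reasoning: at n = 46 the coefficient SE
is ≈ 0.007, so the planted sign and rank order are recoverable in well
over 90% of replicates, while the executive-only model stays near R² = 0.
Null mode makes components independent of coherence.

*Lesions.* Contiguous blobs grown by stochastic frontier accretion on a
32×32×32 grid (2 mm voxels) — desk-scale; vascular-territory shape realism
is out of scope, contiguity is what cluster inference needs. Sizes follow
a lognormal calibrated to the reference cohort (mean 15,497, SD 11,188
voxels) truncated to [175, 41,379] and to half the grid volume. Behaviour
= 0.85 − effect · (lesioned fraction of the critical region) + N(0, 0.05),
clipped to [0, 1]; covariates are drawn from the reference demographic
ranges independent of behaviour. The analysis mask is the union of the
binary lesions (smoothing tails outside any lesion carry no information).
Continuous images are the binary masks smoothed at 8 mm FWHM
(σ = FWHM / (2√(2 ln 2))).

Two named condition sets are frozen as presets. `lesion_calibration`:
modest lesion sizes (lognormal mean 2,000, SD 1,500, range [175, 8,000])
and effect 0 — the null conditions for FWE calibration experiments, sized
so 200 replicates run in minutes. `lesion_recovery`: a 9³ critical region
with half the lesions seeded inside it at compact region scale
(N(600, 200) voxels) and larger background lesions elsewhere (mean 3,000),
effect 0.8, noise 0.03. The recovery experiment evaluates VBCM at a strict
height threshold (voxel p = 10⁻⁴): with a strong planted effect the strict
threshold trims the smoothing/spillover halo and localizes the cluster to
the signal core, the standard practice when the claim is localization. At
these settings the top FWE-significant cluster's Dice overlap with the
planted region exceeds 0.5 in ~97% of pilot replicates (mean ≈ 0.70).

## What passing tests do and do not show

The generator plants exactly the structure the pipeline is built to find:
linear coherence–component relations, a single compact critical region,
exchangeable noise. Passing tests therefore demonstrate that the
machinery is correct and calibrated — OLS/ANOVA match independent oracles,
permutation FWE rates sit inside the binomial CI of the nominal level,
planted signals are recovered — not that real transcripts or real lesions
satisfy these assumptions. In particular, real coherence–component
relations need not be linear, real lesion anatomy correlates with lesion
volume in ways the volume-control option only partially addresses, and the
LSA space built from the tiny synthetic corpus is not a substitute for a
space trained on a large text corpus.

## Numerical choices and degenerate inputs

Cosines are clipped to [−1, 1] against rounding; zero-norm vectors raise
rather than returning NaN. Zero-variance voxels are excluded from the VBCM
mask with a logged count; constant behaviour errors in SVR-LSM and yields
an empty map in VBCM. Binarization uses a strict `>` at the 0.5 threshold.
Permutation p-values include the observed statistic in the null
(+1 correction), keeping them valid at any permutation count. Voxel
coordinates are reported 0-based in voxel space; the input affine is
passed through untouched for mm conversion. All randomness flows from a
single integer seed per entry point; generated cohorts are byte-identical
under a fixed seed.
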