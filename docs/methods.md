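# Methods

## The model

A multifocal prostate gland is modeled as a set of tumor subclones, each a
lineage carrying a private set of somatic methylation changes on top of the
normal prostate methylome. Every primary focus (T) belongs to one subclone;
a lymph-node metastasis (PL) descends from exactly one subclone and keeps
its methylation profile (methylation is assumed clonally stable through
dissemination). Under these assumptions the seeding — hence aggressive —
subclone is identifiable as the one whose foci lie nearest the PL in
beta-value space, and the task decomposes into: purity filtering,
per-patient distance analysis, an independent copy-number cross-check, and
supervised learning of a probe panel that separates normal,
non-aggressive, and aggressive tissue.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure of an FFPE
multifocal-cancer 450K cohort:

* **Baselines.** Per-probe beta baselines are drawn from a two-component
  mixture (low ≈ 0.08, high ≈ 0.85, half of probes each), reproducing the
  bimodal marginal distribution of CpG methylation arrays so that
  variance-based probe selection and threshold filters behave
  realistically.
* **Designated probe blocks** (fixed, documented index convention): four
  GSTP1 stand-ins (low in normal tissue, 0.85 in every tumor lineage), a
  500-probe leukocyte-design block (blood-low / prostate-high), a
  500-probe blood-high block (gives blood its own identity and makes the
  blood-exclusion filter non-vacuous), and a 200-probe node block (where
  normal lymph node differs from prostate). Outside these blocks blood
  equals the prostate baseline, which makes the leukocyte-panel
  construction exactly recover the design block — a sharp oracle for the
  QC tests.
* **Subclones.** Each patient draws 2–4 foci assigned to (default) two
  subclones; each subclone shifts a private, disjoint 5% of bulk probes by
  ±0.10 toward the free end of the beta range. Foci of one subclone share
  the shift set. One subclone seeds the single PL. Measurement noise is
  i.i.d. Gaussian on the beta scale (SD 0.02) with clipping to [0, 1];
  noise on the beta scale (rather than M-values) matches the pipeline's
  working currency, and clipping stands in for the bounded support of true
  betas.
* **Intensities.** Total intensity per probe/sample is lognormal
  (median 5000, log-SD 0.1) multiplied by the planted copy ratio inside
  CNA segments; M = beta·T and U = (1−beta)·T, so beta recomputation is
  exactly consistent and intensity log-ratios recover the planted
  segments.
* **Contamination** is an affine mixture on the beta scale applied before
  noise; fraction f = 0 returns the sample and f = 1 the contaminant.

Default parameters (10 patients, 5000 probes, 2 subclones per patient,
shift = 5 × noise) are the regime in which clonality is recoverable; they
are deliberately a desk-scale stand-in for a ~400k-probe cohort. What the
generator does **not** model: within-focus heterogeneity (each focus is
homogeneous plus noise), probe type I/II chemistry, batch effects,
bisulfite conversion artifacts, and spatially correlated noise. Passing
tests therefore demonstrate the pipeline's correctness and statistical
calibration on data with the planted structure — not performance on real
FFPE arrays.

`generate_signal_matrix` is the classifier-recovery counterpart: 3000
probes, 5 of which carry signal — roughly half shifted in both tumor
classes (cancer-general changes) and the rest only in the aggressive class
(aggressiveness-specific changes). An earlier collinear design (all probes
shifting normal → non-aggressive → aggressive along one direction) was
replaced: it makes the middle class a thin slab between parallel
hyperplanes, a geometry that no linear three-class model resolves robustly
and that does not reflect the two kinds of methylation change the panel is
meant to capture. The baseline profile is seeded separately from the
sampling noise so training and held-out matrices share probe baselines, as
replicate draws from one population would.

## Distance analysis and categorization

Euclidean distances use complete-case probes within the sample set (count
recorded). The categorization rule takes the focus with minimal distance
to the reference PL (the PL nearest any focus, when several exist) as
aggressive; other foci are classified by excess distance dist2 with
boundaries **[0, g₁] aggressive, (g₁, g₂] undecided, (g₂, ∞)
non-aggressive** — boundary values fall in the less extreme category, a
documented reading of the inclusive wording "0–10", "between 10–20",
">20". The published gaps (10/20) are tied to ~396,020-probe distances;
Euclidean distance scales like √P, so synthetic tests derive gaps from the
planted geometry: E[d1²] ≈ 2Pσ² and E[d2²] ≈ 2Pσ² + 2ms² for m shifted
probes of magnitude s per subclone (disjoint sets), and the gaps are
placed at ⅓ and ⅔ of the expected dist2. These are analytic consequences
of the generator's parameters, fixed before any measurement. The gaps
remain plain function parameters; no automatic rescaling is applied to
user data.

## Minimal-evolution trees

Tree topology is chosen by the minimal-evolution criterion: branch lengths
for a candidate topology are the ordinary-least-squares solution of the
path-incidence system A·b = d over leaf pairs, and the objective is the
raw sum of OLS lengths (negative estimates included in the objective,
truncated to zero only for display, with a count recorded). Patients
contribute at most a handful of leaves, so topologies are enumerated
exhaustively up to 8 leaves — the exact optimum where it matters — and
larger inputs start from neighbor joining (scikit-bio) followed by
nearest-neighbor-interchange hill climbing. The longest input distance is
reported with each tree as the display scale reference. Classical
(Torgerson) MDS double-centers the squared distances and embeds on the top
eigenvectors; eigenvalues below 10⁻¹² of the leading one are zeroed so
duplicated samples collapse exactly.

## Copy number

log2((M+U)_sample / mean reference (M+U)) per probe, median-centered per
sample (calls are then invariant to uniform intensity scaling).
Segmentation is recursive binary splitting: the candidate breakpoint
maximizing the two-sided Welch t-statistic between flanks is accepted if
its Bonferroni-corrected p-value (over candidate positions) is below 0.01
and both flanks keep ≥ 10 probes; chromosomes are segmented independently
so segments never span a boundary. Segments with |mean| ≥ 0.3 are called
gains/losses. This is a self-contained CBS-like stand-in for array CNA
toolchains whose internals are not specified; equivalence with any
particular package is not claimed, and no batch correction is performed
(the generator produces no batch structure).

## Classifier

Candidate probes are the top 3000 by |mean beta difference| between the
aggressive and non-aggressive groups (ties by probe order). The fit is an
L1-penalized multinomial logistic regression (elastic-net mixing
configurable, default pure lasso — the customary default of
coordinate-descent GLM packages), features standardized internally,
coefficients reported on the raw beta scale.

Numerical design of the fitter:

* The regularization path is computed once on the full data, from the
  intercept-only model (the analytic class-frequency solution) down two
  decades of penalty in 16 steps, warm-started, and truncated early when
  the training deviance ratio reaches 0.999 or improves by < 10⁻⁴ — the
  standard early-stopping convention of glmnet-style path algorithms. On
  strongly separating data this keeps the dense tail of the grid out of
  consideration.
* Each fit uses a working-set strategy: the saga solver runs on the
  features active in, or violating the zero-coefficient KKT condition
  |∂loss/∂w| ≤ 1/C at, the warm-start solution; KKT conditions for all
  discarded features are then verified on the full design and violators
  are added until clean. This yields exact L1 supports at a small fraction
  of full-design cost (the same device coordinate-descent packages use for
  p ≫ n).
* A "random start" is a seed for the stratified K-fold assignment
  (3 folds, so the 10-sample class keeps ≥ 3 training samples per fold)
  used to pick the penalty on the shared path — matching cross-validated
  GLM semantics, where path coefficients are deterministic given the data
  and only fold assignment varies. The penalty is chosen by the
  one-standard-error rule (sparsest model within one SE of the CV-minimum
  log-loss); on near-separable data the CV minimum sits at the dense end
  of the truncated path, and the 1se rule is the standard parsimony
  convention. The CV-minimum rule remains available as a config option.
* Consensus: the union of probes selected across 15 restart seeds is
  refit once (to full solver convergence, so its L1 zeros are exact); the
  refit's nonzero probes and coefficients are the final model. Samples are
  sorted by id before fold assignment, making the panel invariant to
  input column order. All restart seeds derive from one user seed.

Prediction is a softmax over the three classes; exact probability ties
break by the documented class order normal < non-aggressive < aggressive;
a call is confident only when the maximum strictly exceeds the threshold
(default 0.67). Samples with missing values among panel probes are
rejected per sample with a reason.

## Statistics

Welch t (unequal variances, Welch–Satterthwaite degrees of freedom; the
degenerate zero-variance/equal-means case returns p = 1 by convention),
two-tailed Fisher exact (hypergeometric tail sum, via scipy, verified
against exhaustive enumeration in the tests), Pearson chi-square without
continuity correction (Fisher covers the small-count cases), and
Benjamini–Hochberg FDR for per-probe differential methylation.
Association reports use confident predictions only, Welch t for
continuous covariates and per-level two-tailed Fisher plus an overall
chi-square for categorical ones. Percentages are displayed at one decimal;
full precision is retained internally.

## Problem sizes

The test-suite and acceptance script run the pipeline at: 100 cohorts of
10 patients × 5000 probes for seeding-focus recovery; 20 replicates of
53 training / 53 held-out samples × 3000 probes for classifier recovery;
50 random ≤ 6-leaf matrices and all 2×2 tables with margins ≤ 12 for the
enumeration oracles; and 10,000 null replicates for calibration. These
sizes were chosen to make the Monte-Carlo error of each reported rate
small relative to its acceptance margin while keeping a full run on a
single CPU in the minutes range.

## Known limitations

The pipeline inherits the method's biological assumptions (single clonal
origin of metastases, methylation stability through dissemination); it
does not attempt patient-level monoclonal/multifocal labels beyond the
focus categories; the distance-gap units are data-scale-dependent and left
to the analyst; CNA output is not calibrated against any specific array
toolchain; and synthetic validation bounds what the tests can claim about
real FFPE data (see the generator section).
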