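# Methods

`crcmicro` implements a colorectal-cancer (CRC) lifestyle index and the
statistical chain that links it to gut-metagenome diversity,
composition, and CRC hazard.  Because the cohorts this kind of analysis
runs on (national health-survey samples with register-based cancer
follow-up) are access-controlled, the package ships a synthetic-cohort
generator with planted, recoverable effects; every statistical stage is
validated against that ground truth and against independent brute-force
oracles.

## The lifestyle index

Nine risk factors — BMI, waist circumference (WC), height, leisure-time
physical activity, whole grains, dairy, red meat, processed meat and
alcohol — are each scored 0 / 0.5 / 1 for not meeting / partially
meeting / meeting a target cut-off (see the table in
`crcmicro/scoring.py`).  BMI and WC points are averaged into a
body-fatness score; the four dietary points are averaged into a dietary
score; body fatness + height + activity + diet gives a total in [0, 4],
higher = lower-risk lifestyle.

Conventions worth knowing:

* Height has no defensible absolute cut-offs, so it is scored by
  sex-specific empirical tertiles (shortest tertile = 1 point); heights
  tied at a cut point fall in the lower (higher-scoring) tertile, so
  equal heights never straddle a boundary.
* Processed meat of exactly 21 g/week earns the full point: the
  full-point condition is evaluated first, the favourable convention for
  inclusive targets.
* If the WC column is absent from the whole dataset, body fatness falls
  back to BMI alone.  A missing value in a *present* column raises an
  error — participants with missing scoring data are excluded upstream,
  never imputed.
* Quintiles are assigned by ranking with stable order and splitting into
  near-equal fifths, with every block of tied scores assigned wholesale
  to the quintile of its first member.  The index moves in 1/8-point
  steps, so tie blocks are large and observed quintile sizes are
  legitimately unequal; the deviation from n/5 is bounded by the largest
  tie block.

## Synthetic cohorts

`SimulationConfig` defaults are the package's study conditions: 1,228
participants, 46% men, 150 species, library sizes uniform on
50,000–900,000 reads, planted Shannon slope 0.05 per index point,
planted hazard ratio 0.81 per index point, five survival cohorts of
8,698 for meta-analysis.  Lifestyle marginals (age ~ N(48, 13) truncated
to 25–74, sex-specific heights N(163, 6)/N(176, 7) cm, BMI N(26.5, 4.5),
gamma-distributed food intakes, 24% smokers, 8.6% medication users)
were set to match the published cohort medians/IQRs and proportions.
Variables are independent except BMI–WC (r = 0.85), so the body-fatness
averaging is exercised on realistically collinear inputs.  No
participant-level lifestyle covariance structure beyond that is
asserted; none is publicly estimable.

The microbiome model: per-sample latent log abundances are Gaussian
(between-taxon SD 1.5, within-sample noise SD 0.7) with a
compound-symmetric shared component (SD 0.5) inside each planted
co-occurrence block, plus the planted per-taxon shift `lfc x (index -
mean index)`.  A per-sample softmax concentration is then calibrated by
bisection so that the Shannon entropy of the *expected* composition
equals `base + 0.05 x (index - mean) + N(0, 0.3)`; the Gaussian term is
index-independent biological scatter, chosen so that the fitted
alpha-diversity SE at n = 1,228 (~0.013) matches the scale reported for
real cohorts of this size.  The planted slope is therefore exact in
expectation; the only distortion is the multinomial entropy bias, which
at ≥50k reads is O(n_species / depth) ≈ 1e-4 and index-independent.
Counts are multinomial draws at the sampled depth.  The phylogeny is a
random binary tree with exponential branch lengths in which planted
block members are clade-mates.  Default planted taxa: five
index-negative species labelled as Lachnospiraceae (one block) and three
index-positive species labelled as Bifidobacterium (a second block),
echoing the direction of published findings.

Survival times are exponential with log-hazard `log(0.004) + log(0.81)
x index + 0.2 x smoker + 0.01 x (age - mean)`, administratively censored
at 16 years (~4% events, the same order as the real pooled cohorts).
Multi-cohort families share the log-hazard exactly (homogeneous) or
spread it with a configurable between-cohort SD.  All randomness
descends deterministically from one master seed via per-stage child
seeds.

What the generator does *not* emulate: sequencing error, chimeras, host
contamination, overdispersed (non-multinomial) counts, taxon-taxon
ecological interactions beyond the planted blocks, left truncation or
competing risks.  Passing tests therefore certify the statistical
machinery under a clean compositional model, not robustness to those
artefacts.

## Feature-table preparation

Samples need ≥50,000 reads (inclusive).  Species are dropped when
prevalence (< 1% of samples with a positive raw count) **or** mean
relative abundance (< 0.01%) falls below threshold; "relative
abundance" is read as the mean across samples, the common cohort-pipeline
convention, and prevalence counts strictly positive raw counts with no
pseudo-count.  QC precedes the species filter and the filter is computed
once, not per analysis.  I/O is a plain TSV dialect (header of taxon
ids, optional `#taxonomy` line, first column sample id) plus newick
trees; the binary BIOM container is out of scope for this build.

## Diversity

Shannon entropy uses natural log on species-level raw counts with
0·ln 0 = 0.  Weighted UniFrac is computed from a per-branch sample-mass
table (one postorder traversal) followed by a branch-length-weighted
Manhattan distance; the unnormalized variant is the default and the
normalized variant (dividing by the pair's weighted total mass) is a
flag.  The matrix is checked in tests against a per-pair recursive
oracle (≤1e-10) and against scikit-bio.

## Association statistics

* **OLS** (statsmodels) with the confounder set sex, age, energy,
  smoking, medication (+BMI for non-anthropometric exposures).
  Continuous exposures can be standardized to unit variance so
  coefficients are per SD; the index itself is analyzed per point.
  Benjamini–Hochberg FDR across an exposure family.
* **PERMANOVA**: Gower-centered inner-product matrix; the exposure's
  marginal sum of squares is the gain in explained trace of the full
  design over the covariate-only design (Type-II-like); permutations
  shuffle raw sample rows; p = (1 + #{F* ≥ F}) / (1 + n_perm), default
  999 permutations, seeded.  An exhaustive-enumeration mode exists for
  tiny n and is checked against an independent oracle.
* **PERMDISP**: distance to the group spatial median (Weiszfeld) in
  principal-coordinate space, one-way F, label permutations.  The
  embedding can be truncated to leading axes; large-cohort runs use 10,
  the convention of reference implementations.
* **dbRDA**: the PCoA embedding is regressed on the full design through
  a thin QR basis; constrained proportion = constrained SS / total
  (positive-eigenvalue) SS; per-axis shares come from the SVD of the
  fitted values; overall permutation F-test.  Negative-eigenvalue mass
  above 5% of the total is recorded as a warning on the result.
* **PCoA**: double-centered eigendecomposition; coordinates are
  eigenvectors scaled by sqrt of positive eigenvalues; negative
  eigenvalues are reported but not embedded.
* **Factor fit**: centroid r² = 1 − SS_within / SS_total on the first
  two ordination axes with a label-permutation p, used for Q5-vs-Q1
  ordination separation.
* **Interaction**: exposure × sex product term, Wald p.

## Differential abundance

A compact re-implementation of the bias-correction idea used in
compositional differential-abundance analysis — not a port of any
published software: per-sample log sampling-fraction offsets are the
sample effects of a two-way model for log(count + 1), fitted by
alternating least squares to a tolerance of 1e-6 (the offset converges
to each sample's mean residual across taxa, which absorbs library-size
variation; bias components lying in the design column space are not
identifiable, the usual limitation of mean-based correction).  Each
taxon's offset-corrected log counts are regressed on the index plus
covariates (Wald t, BH FDR across taxa).  Positive coefficients mean
abundance rises with index points (lower-risk lifestyles).  Taxa absent
from an entire index-quintile stratum are structural zeros: flagged,
not tested.  The robustness screen refits at pseudo-counts 0.1 / 0.5 /
1.0 and passes a taxon only if the FDR decision and sign agree
everywhere; the primary fit uses pseudo-count 1.  Exact invariance of
coefficients to per-sample depth rescaling holds only up to the
pseudo-count distortion log((k + 1/c)/(k + 1)), negligible for
well-sequenced taxa; tests assert it at the tolerance that distortion
allows.  Single continuous exposure only; no directional mixed FDR or
multi-group contrasts.

## Co-occurrence clustering

On CLR-transformed counts (pseudo-count 1), the proportionality of two
taxa is rho = 2 cov / (var + var); 1 − rho in [0, 2] feeds Ward's
minimum-variance linkage (scipy; taxa sorted by id first so input order
cannot change the dendrogram; the merge sequence is oracle-tested
against a naive O(n³) Lance–Williams implementation).  Clustering input
is restricted to taxa that are FDR-significant *and* screen-robust.
The cut is chosen by the Kelley–Gardner–Sutcliffe penalty: for each k
in 2..n−1 the mean within-cluster dissimilarity (over multi-member
clusters, the maptree convention) is linearly rescaled onto [1, n−1]
and k added; argmin wins, ties to the smaller k, a flat profile returns
k = 2 with a warning.  On data without block structure the penalty has
no knee and mid-range k is the method's honest answer; simulated
k-block data is recovered reliably.  Cluster abundance for the
per-cluster regression is the CLR mean over member taxa (default) or
log summed relative abundance (flag).

## Survival validation

Cohort-specific Cox proportional-hazards models (follow-up time as the
time scale; sex, age, energy, smoking as adjustment) are fitted by
Newton–Raphson with step-halving on the Breslow partial likelihood,
stopping when the score norm falls below 1e-8 × (1 + events) — the
score is a sum over events, so an absolute tolerance would be
unattainable at cohort scale in double precision.  Standard errors come
from the observed information; CIs use z = 1.96.  Coefficients drifting
beyond |β| > 10 (or 25 mid-iteration) are flagged as monotone
likelihood rather than reported as converged estimates.  Ties are
Breslow-handled; simulated times are continuous, so the choice is
immaterial there.  Quintile models use indicator coding with the lowest
quintile as reference; the trend test replaces indicators by each
quintile's median score as one continuous covariate.  Per-cohort (β,
SE) pairs are pooled by DerSimonian–Laird random effects: Q = Σ w(β −
β_FE)², τ² = max(0, (Q − df) / (Σw − Σw²/Σw)), weights 1/(v + τ²),
heterogeneity p from χ²_df.  The meta layer takes (β, SE) pairs
directly, so cohorts fitted elsewhere can be pooled without refitting.

## Problem sizes used in validation

The test suite's calibration experiments run 200 replicates of each
null (OLS, PERMANOVA, dispersion, factor fit, per-taxon DA p-values,
Cochran's Q over five homogeneous cohorts of 250) at 30–100 samples
with 99 permutations, checking uniformity by Kolmogorov–Smirnov at
α = 0.01, and 50 replicates for the BH false-discovery proportion.
Recovery experiments run 20 replicates each: the Shannon slope at
n = 250 (study-condition depths), the planted DA sign at n = 600 and
≥50k reads, and the KGS block count on three planted blocks; the hazard
ratio is recovered once at n = 40,000.  These sizes are the package's
chosen validation conditions; all are seeded and deterministic.

## Known limitations

* The DA model is Gaussian on log(count + 1); it does not model
  zero-inflation or overdispersion explicitly, and mean-based bias
  correction cannot separate bias components collinear with the design.
* PERMANOVA permutes raw rows; residual-permutation schemes are not
  implemented.
* The Cox layer has no left truncation, time-varying covariates, or
  competing risks.
* KGS cluster-count selection is only meaningful when block structure
  exists (see above).
* The quintile tie convention makes quintile sizes data-dependent;
  analyses that need exact fifths should pre-jitter scores.
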