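# Methods

`tmephenotype` implements an immune-phenotyping workflow for bulk tumor
transcriptomes: per-sample infiltration scoring of tumor-microenvironment
(TME) cell types, unsupervised discovery of immune phenotypes by consensus
non-negative matrix factorization (NMF), a battery of immune-escape scores,
burden-adjusted differential genomics, and survival characterization. A
seeded synthetic-cohort generator with full ground truth makes every stage
testable without external data.

## Preprocessing

**log-CPM transform.** Raw counts are mapped to
`log2((c + p) / (L + 2p) * 1e6)` with library size `L` and prior count
`p = 0.5`. The prior damps low-count variance; the doubled prior in the
denominator bounds the transform. Exact invariance to library scaling holds
only in the `p -> 0` limit; at the default prior the distortion is
`O(p / L)`.

**Batch calibration.** Cohorts profiled on different platforms are merged
with a parametric empirical-Bayes location/scale adjustment: per-gene
standardization to the pooled mean/variance, per-batch gene-wise shift and
scale estimates, shrinkage toward batch-level normal / inverse-gamma priors
by iterated conditional modes (relative change < 1e-6 or 100 iterations),
removal, and restoration of the pooled scale. A single batch is a no-op;
genes with (numerically) zero pooled variance pass through un-scaled with a
warning, since constant genes are legitimate in synthetic fixtures. The
implementation agrees with the parametric ComBat in scanpy to ~1e-2 on
shared fixtures (small differences stem from shrinkage-iteration details);
the agreement is asserted in the test suite.

Note the shrinkage bound on residual batch separation: the empirical-Bayes
posterior leaves roughly half of the *sampling* noise of the per-batch mean
in place (shrink factor `delta^2 / (n tau^2 + delta^2) ~ 1/2` when
batch-shift variation across genes is pure sampling noise), so the residual
per-gene batch difference after adjustment scales with
`noise_sd / sqrt(n_per_batch)` — a property of the method, not a defect of
the implementation. Calibration checks therefore use technical-replicate
noise (sd 0.25 on the log2 scale) where this residual is far below 0.1.

## Infiltration scoring (ssGSEA)

For each sample, genes are ranked by expression (average ranks on ties,
descending order). For a gene set S the enrichment score is the sum over
the ordered gene list of the difference between the in-set cumulative
distribution weighted by `rank^alpha` (normalized over S) and the uniform
out-of-set cumulative distribution. `alpha = 0.25` by default, exposed as
config. Scores depend on ranks only, hence are invariant under strictly
monotone per-sample transforms — asserted to 1e-12.

The bundled 31-cell-type signature GMT is a *synthetic stand-in* with
plausible marker genes per named cell type (filename and loader say so);
real analyses should supply a curated GMT. Auxiliary sets: ESTIMATE-style
immune and stromal sets, an exhausted-T-cell set, and the two-gene
cytolytic set.

**Normalization.** Cohort-wide min-max to [0, 1], then per-cell-type
z-scaling (sd with ddof=1); constant rows skip z-scaling and are flagged.
The composition order is config; the default (min-max, then z) treats the
min-max stage as idempotent cohort anchoring and the z stage as the
clustering scale.

**Characterization.** Immune/stromal scores are ssGSEA scores on the
dedicated sets, optionally affinely rescaled (default identity — the
original ESTIMATE scale cannot be recovered without its exact 141-gene
signatures, so purity values here are internally consistent rather than
ESTIMATE-identical). Tumor purity is
`cos(0.6049872018 + 0.0001467884 * (immune + stromal))`, argument clipped
to [0, pi/2], purity to (0, 1], with clipping flagged. Ratios (M1/M2,
Th17/Treg, Th1/Th2, exhausted/CD8) are computed on the min-max-normalized
(non-negative) scores as `(num + eps) / (den + eps)`, `eps = 0.01`.
Aggregate scores are means of z-scaled scores over the adaptive /
activated-adaptive / innate / stromal groups (group membership is shipped
as editable YAML config).

## Consensus-NMF subtyping

Scaled scores are folded into a non-negative matrix by doubling rows into
positive and negative parts (`max(z,0)`, `max(-z,0)`); unlike a global
min-shift this keeps results independent of single extreme values.

NMF minimizes the generalized KL divergence with multiplicative updates
(Frobenius updates available); the objective is recorded every sweep and
asserted non-increasing. Zero entries are floored at 1e-12 inside the
updates. An optional connectivity stopping rule (hard assignment stable for
m sweeps) implements the classic consensus-NMF protocol; the default stops
on relative objective change < 1e-6.

**Consensus and rank selection.** For each rank k in 2..6, 30 seeded runs
each factorize a random 80% subsample of the samples; the consensus entry
for a sample pair is its co-assignment frequency among runs where both were
drawn. The cophenetic coefficient of each consensus matrix is the Pearson
correlation between the off-diagonal consensus dissimilarities (1 - C) and
the cophenetic distances of their average-linkage hierarchical clustering.
The selected rank is the highest k before the largest drop of the
cophenetic coefficient (max of `rho_k - rho_{k+1}`, ties toward smaller k).

Subsampling is a deliberate design choice: repeated restarts on the *full*
matrix converge to the same basin on any cleanly structured matrix, giving
cophenetic coefficients ~1.0 at every rank and leaving the drop rule with
nothing but noise to compare. Perturbing the data is what exposes the
instability of over-fitted ranks while the true rank stays robust
(the Monti et al. consensus-clustering rationale). `subsample=None`
restores pure restart consensus.

Consensus matrices are permutation-equivariant at the aggregation level
(`consensus_from_assignments`); the full seeded path is not exactly
equivariant because random initializations are drawn per run, not per
sample ordering.

**Final labels and naming.** The final assignment at the selected rank is
the coefficient argmax of the best-objective run among 30 full-cohort
factorizations (consensus-tree cutting was evaluated and gave no accuracy
gain). With exactly 3 clusters, the cluster with the highest mean
activated-adaptive aggregate is named immune-active, the highest stromal
aggregate among the rest stroma-rich, the remainder immune-desert; if one
cluster tops both aggregates the larger margin wins (logged). Other ranks
get `cluster-i` names. Clustering uses the 31 TME cell-type signatures
only — the ESTIMATE union sets track global infiltration and would anchor
a spurious, perfectly stable extra component if included.

**Pseudo-bulk.** Single-cell UMI counts are summed per sample; genes with
fewer than 50 total reads are removed; the per-sample mean then feeds the
log-CPM transform, after which the bulk pipeline applies unchanged.

## Genomics

* mutation load `log2(n_nonsilent + 1)`;
* SCNV load = % of genomic units with a non-neutral thresholded call
  (|call| >= 1 by default; deep-only via config), calls restricted to
  {-2,-1,0,1,2};
* cytolytic activity = log2-scale geometric mean of GZMA and PRF1 with
  offset 0.01 (the convention of the cytolytic-score literature; the
  offset guards zero expression);
* repertoire diversity: richness, Shannon entropy (nats), evenness
  `H / ln(richness)` (1 for a single clonotype).

**Burden-adjusted differential test.** For each gene with overall event
rate >= 2.5%, the subtype pair indicator is regressed on (burden, event) by
logistic ML; the Wald p of the event term decides. This conditions the
comparison on the per-sample burden, which is confounded with subtype
(hypermutated tumors concentrate in the immune-active phenotype), and is
what keeps the type-I error at nominal level where a naive Fisher test is
grossly inflated. Separation or a singular design triggers a
likelihood-ratio fallback (flagged non-convergent, logged); a constant
burden column is dropped, reducing to the single-covariate fit. BH q-values
are reported alongside but the paper-convention call is p < 0.05
unadjusted. CNV comparisons run per direction with opposite-direction
calls zeroed and SCNV load as the burden covariate. Subtypes are compared
pairwise (one-vs-one). Externally supplied per-sample columns (neoantigen
load, CTA, HRD, ITH) are compared by Kruskal-Wallis with Dunn's post-hoc
z-tests (implemented here; BH-adjusted).

## Survival

Kaplan-Meier product-limit curves with Greenwood variance and the
`S(t) <= 0.5` median; log-rank tests over pooled event times (df =
groups - 1); Cox proportional hazards with Efron tie handling (lifelines,
Newton precision tightened to 1e-12 so coefficients match brute-force
partial-likelihood optimization to 1e-6). Multivariate models enroll
covariates with univariate p < 0.1. Per-cell-type prognostic scans
dichotomize scores at the median. Covariates must be numeric; categorical
factors are dummy-coded by the caller (each dummy is enrolled on its own
univariate p).

## Synthetic cohorts

Each sample draws a phenotype (equal weights), per-cell-type abundances,
and all downstream modalities from one seeded generator, so a config
reproduces its cohort byte-for-byte.

Abundance model: group-level offsets per phenotype (immune-active:
activated-adaptive +2.5, other immune +1, stromal -1; immune-desert: all
-1; stroma-rich: stromal +2.5, non-activated immune +1,
activated-adaptive -0.5), plus a per-sample latent *global infiltration
level* (sd 0.55) loading on the non-activated adaptive and innate cells,
plus iid noise (sd 0.3). The latent factor reproduces a salient feature of
real cohorts — a continuum of overall immune content within each phenotype
— and it is load-bearing: without it every rank's consensus is perfectly
stable and the cophenetic-drop rank diagnostic has no signal to work with.
Signature genes gain `effect_size` (1.0 log2 units) per abundance unit on
top of a N(6, 1.5) baseline, additive per-batch shifts (3 batches, sd 0.5)
and N(0, 0.5) noise. The abundance-to-expression link is linear on the log2
scale, under which rank-based scoring is provably monotone in abundance.

Mutations: per-sample non-silent totals are log2-normal per phenotype
(means 8.5 / 6.5 / 6.5 — the immune-active excess emulates dMMR/MSI-H
hypermutation); per-gene event probability follows the burden on the logit
scale (intercept -2.5, slope 0.8 per log2 unit), with planted differential
genes receiving an extra log-odds of 2.0 (OR ~7.4, the scale of strongly
subtype-enriched drivers) in the immune-active phenotype. CNV: per-unit
alteration probability 0.08 / 0.08 / 0.20 (stroma-rich highest), fixed
per-unit direction bias, 30% deep calls. Clonotypes: Poisson richness
(means 100 / 15 / 60; immune-desert lowest) with geometric counts.
Survival: exponential, baseline hazard 0.015 / month, stroma-rich hazard
ratio 2.3, uniform censoring on [6, 120] months. Single cell: per-cell
major type drawn from phenotype-dependent proportions, multinomial UMIs
with marker boost 8.

Default dimensions (300 samples, 2,000 genes, 31 signatures x 10 genes, 12
single-cell samples x 60 cells) keep the full suite in minutes on one CPU.

**What passing tests do and do not show.** The generator emulates the
*statistical* structure the pipeline targets (archetypal infiltration with
a within-phenotype continuum, burden confounding, direction-coded CNV,
subtype-dependent hazard). It does not model platform-specific probe
effects, gene-gene correlation beyond signatures, single-cell dropout or
doublets, or segment-level CNV — so green tests certify the machinery and
its calibration under the stated model, not performance on any particular
real cohort. At the default conditions the operating characteristics are:
ARI ~0.90 against planted labels, naming accuracy >= 0.96, and
cophenetic-drop selection of rank 3 in roughly half to four-fifths of
cohorts depending on the draw — rank selection by a single largest drop is
the least stable link of the chain, which mirrors practical experience
with the diagnostic.

## Numerical choices and degenerate inputs

KL updates floor denominators and WH at 1e-12; an objective increase
beyond 1e-8 relative raises (update bug, not data). Cophenetic coefficient
of a constant dissimilarity structure is defined as 1. Ties in hard
assignment resolve to the lowest cluster index. `select_rank` ties break
toward the smaller rank. All-censored KM curves have undefined (NaN)
median. Purity clipping, constant-row z-skips, dropped gene sets and
non-convergent logistic fits are all flagged rather than silent.

## Known limitations

* Rank selection by the largest cophenetic drop is noise-sensitive when
  consensus is uniformly high or uniformly low; profiles should be
  inspected, not only the argmax (the per-rank coefficients are always
  returned and written by the CLI).
* Purity values are on an internally consistent scale, not the published
  ESTIMATE scale.
* The bundled signatures are placeholders; scientific use requires curated
  marker sets.
* Cox covariates are treated marginally at enrollment (each dummy on its
  own univariate p); no interaction or time-dependent terms.
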