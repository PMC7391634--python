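# Methods

This note documents the statistical models implemented in `methylmr`,
the choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions used throughout.

## Data model and conventions

Methylation is carried as beta values (fraction methylated, in [0,1])
in probes × samples matrices; regression phenotypes use the M-value
scale M = log2(β/(1−β)), the variance-stabilized log-odds, with betas
clipped to [ε, 1−ε], ε = 1e−3, before the transform. The inverse
β = 2^M/(1+2^M) is exact to 1e−12 inside the clip region. EWAS effect
sizes are reported on the beta scale (the scale of published per-CpG
tables), while meQTL and MR models run on M-values for statistical
stability. Genotypes are expected effect-allele dosages in [0,2];
coordinates are 1-based with inclusive interval bounds; every genetic
table carries an explicit effect-allele column.

## Quality control

Samples are removed when more than 5% of their probes fail detection
(p > 0.01), and when flagged as sex-mismatched (sex inference happens
upstream; only precomputed flags are consumed — the conventional
reading of sample-level detection filtering, since a literal per-sample
"detection P > 0.01" criterion is not executable). Probes are removed
for bead failure (< 3 beads) in ≥ 5% of samples, non-CpG chemistry,
SNP association, or detection failure in ≥ 5% of samples. Filtering is
idempotent, and every removal is recorded with a reason.

## Cell-type deconvolution

Bulk preputial tissue is modelled as a convex mixture of eight
reference profiles (epithelial, fibroblast, B, NK, CD4 T, monocyte,
neutrophil, eosinophil). Per sample, the marker-probe betas are
regressed on the reference by non-negative least squares and the
coefficients renormalized to sum to one. This targets the same estimand
as robust-partial-correlation deconvolution but has a simpler,
testable contract: noiseless mixtures are recovered exactly (to 1e−6)
and 0.02-sd beta noise yields mean absolute fraction errors well below
0.05. A Huber-weighted NNLS variant (`robust=True`, delta 0.05 beta
units) down-weights contaminated markers. Group differences in
fractions are tested per cell type with the two-sided Mann–Whitney
rank-sum test by default (Welch t optional).

## Latent covariates

**Surrogate variables.** The matrix is residualized on the protected
design, and the SVs are the top left singular vectors of the residuals
in sample space. The number of components, when not fixed, is chosen
by permutation parallel analysis: each observed singular value is kept
while it exceeds the 95th percentile of the corresponding singular
value over B (default 100) within-probe permutations of the residuals.
This is distribution-free and directly testable (pure-noise matrices
select k = 0 in ≥ 90% of runs), in contrast to estimators based on
random-matrix asymptotics. One caveat found during validation and
worth stating: when an unmeasured batch is strongly collinear with the
phenotype, protecting the phenotype removes the batch's
phenotype-aligned component from the residuals, so the resulting SVs
cannot de-confound the scan. Under a global null the right tool is the
unprotected estimator (equivalently, principal components of the
centered matrix), which is what the calibration validation uses.

**Methylation PCs** are the sample-space principal components of the
column-centered beta (or M) matrix, with variance-explained fractions
reported in non-increasing order.

## EWAS

Each design compares two groups by per-CpG OLS of beta on the group
indicator plus covariates, with classical homoskedastic SEs (matching
standard EWAS linear-model tools; an HC0 robust option exists). Group
means and delta beta (comparison − case, so case hypermethylation is
negative) are reported unadjusted. Constant CpGs yield NA with a
warning and are excluded from FDR. BH q-values are computed within each
design over tested CpGs; suggestive sets use FDR < 0.20 for the
case–control design and FDR < 0.15 for the case-only designs — the
stricter case-only threshold limits false positives driven by the
smaller comparison groups. Genomic inflation is
λ = median(χ²₁)/0.45494; covariate tuning scans an ordered list of
candidate sets, selects the λ closest to 1, breaks ties toward fewer
covariates, skips infeasible (collinear) candidates, and logs the full
trace. Candidate CpGs from earlier reports are looked up with a
three-way status: absent from the platform, failed QC, or tested (no
liftover is attempted; platform-absent candidates are simply reported
as such).

## meQTL scan and instruments

For each suggestive CpG, every same-chromosome variant is tested by OLS
of the CpG's M-values on dosage, partialling out methylation PCs
(Frisch–Waugh–Lovell), giving slope, classical SE, t and two-sided p
with n − k − 2 degrees of freedom; monomorphic variants return NA. A
frequentist OLS scan is used rather than a score test — equivalent at
these sample sizes and exactly testable against closed forms. No
multiplicity correction is applied within the scan; instrument
qualification uses the fixed threshold P < 1e−3. Qualifying variants
are greedily pruned in ascending-p order (ties broken by chromosome,
position, id — a documented deterministic completion of standard
clumping semantics, since pruning order is otherwise undefined),
accepting a variant iff its dosage r² with every accepted variant is
below 0.2. r² is computed in-sample by default; a reference panel can
be supplied instead. Empty sets are flagged `no_instruments`, never
silently dropped.

## One-sample 2SLS MR

Stage 1 regresses the CpG's M-values on the instrument dosages (plus
any exogenous covariates); stage 2 regresses the binary outcome on the
stage-1 fitted values. The wording of the procedure this implements is
sometimes garbled in the literature; the implementation is the standard
2SLS estimator (exposure on instruments, then outcome on fitted
exposure). The binary outcome enters a linear probability model —
matching the least-squares formulation of the commonly used structural
equation implementation — so the estimate reads as outcome-probability
change per M-value unit; a logistic control-function variant could be
added but is deliberately not the default, to keep the estimator
exactly testable against its algebraic identities. Standard errors use
the classical 2SLS formula with residuals from the *observed* exposure
(y − Xβ̂), and p-values are two-sided t with n − k df. Covariates
default to none; methylation-PC adjustment is available by
configuration. The just-identified case reduces exactly to
cov(G,Y)/cov(G,M). First-stage diagnostics report the partial F for the
joint instrument block (flag `weak_instrument` below F = 10,
configurable; `strong` when the noiseless cap of 1e12 is reached) and
the first-stage R². Significance is declared at P < 0.05 and reported
as a flag; no rows are dropped.

## Two-sample Wald-ratio MR

Genes whose intervals overlap the ±500 kb window around a CpG
(inclusive edges) are candidate cis mediators; interval overlap is the
default because the window is defined on gene symbols rather than
transcription starts, and a TSS mode is provided. Exposure (eQTL) and
outcome (GWAS) summary statistics are harmonized on variant id: effect
alleles matching the exposure's other allele flip the outcome beta;
palindromic A/T and C/G variants are dropped (allele frequencies are
not guaranteed in summary fixtures, so frequency-based inference is
not attempted); mismatched allele pairs are dropped. Harmonization is
idempotent. Per (gene, tissue), the smallest-p exposure variant is the
single instrument (the natural reading of "a single
expression-associated variant"; exposed as `iv_choice`), and the Wald
ratio is β_y/β_x with first-order delta-method SE s_y/|β_x| (a
second-order option adds β_y²s_x²/β_x⁴). One result per (gene, tissue);
no cross-tissue meta-analysis, no multi-IV inverse-variance weighting.

## GWAS-region cross-reference

Suggestive CpGs within ±500 kb of a published index variant (inclusive,
same chromosome, shared build) are paired with it; the CpG's
instruments are then tested for LD with the index variant in a
reference genotype panel. The "linked" verdict threshold is r² ≥ 0.2 —
chosen for consistency with the pruning threshold, as no published
convention fixes it — and the verdict is monotone in the threshold.
When study genotypes are available the direct index-variant meQTL
p-value is also reported. This is LD cross-referencing only; no formal
mediation model is fitted.

## The synthetic-data generator

The generator's defaults reproduce the motivating study design: 45
cases and 46 controls, 21 cases with chordee and 9 severe cases (all
severe cases have chordee, giving the published cross-tabulation of 12
moderate-with-chordee / 24 moderate-without / 9 severe, with meatal
positions 6/17 distal, 6/6 midshaft, 0/1 subcoronal, 7 penoscrotal, 2
perineal-proximal).

* **Genotypes** are Gaussian-copula haplotypes with block-constant
  correlation (default blocks of 6 variants at ρ = 0.6, MAF uniform on
  [0.1, 0.5]) thresholded at the allele-frequency quantile, so each
  variant is Hardy–Weinberg binomial with tunable within-block r² for
  pruning tests.
* **Methylation.** True methylation is m_true = baseline +
  Σ effect×dosage + N(0, bio_sd); the measured latent value adds batch
  shifts and technical noise, M = m_true + batch + N(0, noise_sd), and
  β = 2^M/(1+2^M) — the same link the pipeline inverts, so the
  transform round-trip is exact. The biological-variance term matters:
  it makes the exposure partly non-genetic, which is precisely the
  setting instrumental-variable estimation is for, and it gives the
  outcome model a continuous liability even at CpGs without meQTLs.
  Default effect sizes are paper-scale: cis-meQTL effects of 1.0–1.5
  M-units per allele against noise_sd = 0.5 (strong top-meQTL
  signals, consistent with the extremely small one-sample MR p-values
  such studies report at n ≈ 90), and causal liability effects of 1.5
  logits per true-M unit.
* **Cell mixture.** Per-sample fractions are Dirichlet draws
  (concentration (8, 6, 0.5, 0.5, 0.8, 0.8, 1.5, 0.4): epithelium- and
  fibroblast-dominated tissue with a variable neutrophil component);
  marker probes carry the convex combination of synthetic reference
  profiles plus 0.01-sd noise.
* **Outcomes.** Case liability is logit-linear in the true (noise-free)
  M-values of the planted causal CpGs. Exact configured group sizes and
  Bernoulli sampling are reconciled by retrospective case–control
  sampling: exactly n_cases samples are drawn without replacement with
  weights equal to the Bernoulli odds (Gumbel top-k), i.e. the
  independent Bernoulli draws conditioned on the observed totals. Under
  the null this is uniform sampling, so labels are independent of
  methylation; in the separation limit the top-liability samples become
  the cases. Severity and chordee are assigned within cases the same
  way, with severe ⊂ chordee. Controls carry no chordee/severity coding
  (not applicable).
* **Summary statistics** plant one IV per gene with
  β_outcome = ratio × β_exposure + noise, configurable allele flips and
  palindromic fractions to exercise harmonization.

Determinism: all draws flow through `numpy.random.SeedSequence`, so a
fixed seed gives bit-identical fixtures.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: array probe chemistry (type I/II design,
background and dye bias; normalization from raw intensities is out of
scope and inputs are assumed normalized), genome-wide LD structure
beyond block-constant copulas, population stratification, cell-type
composition acting as a confounder of the outcome, trans-acting meQTLs,
and pleiotropic instruments (the planted instruments affect the outcome
only through methylation, so the exclusion restriction holds by
construction; real instruments may violate it, and pleiotropy-robust
estimators are deliberately out of scope).

## Validation problem sizes and numerical notes

The validation suite runs, as the package's own choice of scale: 2SLS
consistency at n = 500 with 5 instruments (first-stage R² ≈ 0.2, 200
replicates; null calibration at 1000 replicates); Wald-ratio recovery
over 500 genes; EWAS null calibration over ten 1000-CpG scans at
n = 91 — averaged because a single 1000-CpG median-based λ has sampling
SE ≈ 0.074, so a ±0.05 check is only meaningful for the mean — and
inflation control on a 4000-probe batch-confounded fixture (SV
estimation error, and with it the residual post-adjustment inflation,
shrinks with probe count; real arrays have two orders of magnitude more
probes than any fixture here); oracle equality of BH q-values (100
random vectors, quadratic-time reference) and of greedy pruning (100
random 12-variant instances, definitional stepwise re-computation);
deconvolution recovery over 100 samples; and an end-to-end run per seed
at the default study scale. First-stage F is capped at 1e12 (the
noiseless limit is infinite). Just-identified 2SLS-vs-ratio agreement
is asserted in relative terms (1e−10), since the ratio itself is
unbounded when a random toy draws a near-zero first-stage covariance.

## Known limitations

The linear probability model can fit probabilities outside [0,1] for
extreme exposures; estimates remain interpretable as average marginal
effects. In-sample LD pruning with small n misestimates r² near the
threshold. The covariate-tuning criterion |λ − 1| is itself noisy at
small probe counts and can pick an over-adjusted set by chance. The
candidate-CpG lookup does not lift coordinates between genome builds.
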