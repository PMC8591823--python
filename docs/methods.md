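# Methods

This note records the statistical models, the synthetic-data design, the
numerical choices and the known limitations of `metaboqtl`.

## Pipeline model, stage by stage

**Trait derivation.** Serial body weights (≈14-day grid) are fitted per
animal by OLS of weight on day; the intercept is initial BW and the slope is
ADG. Midpoint BW is `initial + ADG * days_on_test / 2` and metabolic body
weight is `midpoint^0.75` (exact 0.75 exponent, double precision). DMI is
standardized by the linear energy ratio `dmi * diet_energy /
reference_energy` (factor 1 when both are equal, the synthetic default).
RFI is the residual of standardized DMI on intercept + ADG + MWT, fitted
pooled by default with an optional per-group fit; OLS residual algebra
guarantees mean-zero RFI uncorrelated with both predictors.

**Genotype QC.** Filters are conjunctive and strict in the "remove if
below" direction: imputation accuracy < 0.95, observed-dosage MAF < 0.05,
exact HWE p < 1e-4, or non-autosomal chromosome label (29 cattle autosomes
by default). The HWE test is the exact conditional test: given the allele
counts, the probability of every achievable heterozygote count is computed
and all outcomes no more probable than the observed one are summed
(two-sided summed-probability rule). Probabilities are computed in log space
with a 1e-12 relative tolerance when comparing ties. The QC report
attributes each removed SNP to the first failing filter in the order
non-autosome → accuracy → MAF → HWE; the retained set is order-free.

**Pre-adjustment.** Each trait and metabolite is regressed on intercept,
dummy-coded animal type / birth year / herd / pen, numeric age, and K−1 = 5
of the 6 breed-composition fractions (the sum-to-one constraint makes the
K-th column structurally collinear). Rank deficiency raises an error naming
the aliased columns rather than silently dropping them. Residuals more than
3 sample SDs from the residual mean are masked in a single pass (no re-fit
after exclusion); masking is per phenotype, so different phenotypes may
retain different animals. All configured factors are always included; a
data-dependent significance screen of factors is deliberately not the
default because it makes the adjusted phenotype depend on the realization.

**Trait–metabolite screen.** Simple OLS of adjusted trait on adjusted
metabolite over the jointly retained animals; selection at p < 0.1
(strict), ordered by p with metabolite name breaking ties. V_m/V_P is
defined as the joint multiple-regression R² of the trait on all selected
metabolites (×100); the per-metabolite univariate R² is also emitted. The
joint definition is used because one number is reported per trait over
several metabolites; with correlated metabolites the joint R² is below the
sum of univariate R²s and at least their maximum.

**GRM and REML.** The GRM is the allele-frequency-standardized cross
product over polymorphic SNPs, `G = Z Z' / m` with
`Z_ij = (x_ij − 2p_i) / sqrt(2 p_i (1−p_i))`; missing dosages are
mean-imputed per SNP (their centered contribution is zero). One GRM is
built from all post-QC SNPs and reused for every metabolite; the tested SNP
stays in the GRM (no leave-one-chromosome-out), which is simpler, matches
the single-GRM description of the workflow, and costs a mild, documented
deflation of the tested SNP's own signal. Variance components for
`y = mu·1 + a + e` are estimated by average-information REML run in the
eigenbasis of G: after one O(n³) eigendecomposition every iteration is
O(n). An AI proposal is clamped at the variance floor (1e-8 × var(y)) and
accepted only if the restricted log-likelihood does not decrease; otherwise
an EM-type step is taken, halved toward the current iterate as needed, so
accepted iterations are monotone. Convergence is |Δ logL| < 1e-6, at most
100 iterations; non-convergence raises an error carrying the last iterate.
Standard errors come from the inverse AI matrix; the SE of
h² = σ²_a/(σ²_a+σ²_e) by the delta method. A GRM with (near-)constant
eigenvalues (e.g. the identity) leaves only σ²_a + σ²_e identifiable; this
is detected and warned about rather than failed.

**mGWAS.** For each SNP, generalized least squares of the adjusted
metabolite on (1, dosage) with V = G σ̂²_a + I σ̂²_e fixed at the null REML
estimates — the standard MLMA economy: one REML fit per metabolite, then
O(n) per SNP in the shared eigenbasis. The per-SNP 2×2 weighted normal
equations are solved vectorized across SNPs. The primary test is Wald
chi-square (1 df); an exact F(1, n−2) option exists and is slightly more
conservative. Monomorphic SNPs are skipped with a log entry; a singular V
gets one jitter retry. Significance is p < 1e-5 (strict); the variance
explained by a SNP is `2 p q β² / S² × 100` with p the observed
alternate-allele frequency and S² the variance of the adjusted metabolite
entering the scan.

**Gene mapping.** Coordinates are 1-based inclusive throughout (GFF3
convention; BED input is shifted on read). A gene is a candidate for a
metabolite when its span intersects the ±70-kbp window of any significant
SNP: `gene.start ≤ pos + 70000` and `gene.end ≥ pos − 70000`. The 70-kbp
flank reflects the distance over which linkage-disequilibrium phase
correlation stays high in North American beef populations. snoRNA and
miRNA biotypes are excluded (protein-coding focus). QTL regions are the
transitive merge of significant SNPs whose windows overlap (inter-SNP
distance ≤ 140 kbp on one chromosome), realised by a single sorted sweep;
region bounds are the extreme member positions ± 70 kbp. The merge rule is
a design choice — any clustering consistent with the window logic would do
— and guarantees #QTLs ≤ #SNPs with maximal (non-mergeable) regions.

**Enrichment.** One-sided hypergeometric (Fisher exact upper tail)
probability of the observed overlap between a candidate list and each GMT
set, with the universe defaulting to all annotation genes. Candidates
outside the universe are counted, warned about and excluded, mirroring
knowledge-base mapping loss. No multiple-testing correction is applied to
the significance flag (raw p < 0.05, strict); a Benjamini-Hochberg column
is emitted for information. This replaces proprietary knowledge-base
overlap tools with a transparent, reproducible equivalent; equivalence with
any proprietary statistic is not claimed.

## Synthetic-data generator

The generator emulates a feedlot study of ~500 crossbred cattle genotyped
at imputed sequence density (desk scale: thousands of SNPs rather than
millions) with 31 plasma metabolites quantified in µM.

- **Genotypes**: per-SNP allele frequency uniform in `maf_range`
  (default 0.05–0.5), dosages binomial(2, p), independent across SNPs by
  default; an optional AR(1) Gaussian-copula haplotype mode (`ld_rho`)
  produces block-correlated alleles for exercising QTL clustering.
  Positions are uniform over 29 autosomes of 10 Mbp.
- **Covariates**: bull/heifer/steer in the emulated population's 93/125/275
  proportions, 10 birth years, 5 herds, 8 pens, age ~ N(270, 30) days, and
  Dirichlet(1) breed composition over 6 ancestral components.
- **Metabolites**: baseline 100 µM + planted causal SNP effects + a
  GRM-consistent polygenic value (`Z u` with i.i.d. standardized-SNP
  effects) + additive covariate shifts (level effects ~ N(0, 5 µM)) +
  N(0, 10 µM) noise. `metabolite_h2` is the polygenic heritability
  relative to polygenic + residual variance (σ²_a = h²/(1−h²)·σ²_e);
  planted causal variance adds on top, so a causal effect can coexist with
  h² = 0.
- **Feed records**: latent initial BW ~ N(300, 30) kg and ADG ~
  N(1.4, 0.15) kg/day; serial weights on a 14-day grid with 5 kg scale
  noise; DMI = 0.5 + 1.2·ADG + 0.09·MWT + planted metabolite effects +
  N(0, 0.6) kg/day. Trait effects enter the trait's generative quantity
  (ADG effects shift latent ADG, MWT effects latent initial BW, DMI/RFI
  effects intake), so an RFI-planted metabolite survives the expected-DMI
  regression by construction.
- **Annotation and gene sets**: genes tiled with exponential gaps (mean
  85 kbp) and lengths (mean 30 kbp) — about one gene per 115 kbp, the
  density of a mammalian autosome — 90% protein-coding, 5% each
  snoRNA/miRNA; a dedicated protein-coding gene spans each causal SNP and
  is recorded in the truth. GMT sets are random draws plus one
  `planted_function` set collecting the planted genes.

All randomness flows from one seed through per-component child generators,
so the genotypes generated alone equal those inside a full study and a
fixed seed reproduces every table bitwise.

The demo study design (`demo_config`) plants three causal SNPs, each
explaining 8% of one metabolite's variance, on three metabolites each
explaining 1.5% of RFI variance. These sizes were fixed by a power
analysis at design time: at n = 500 the scan's analytic power for an 8%
SNP at p < 1e-5 is ≈0.99 and the screen's power for a 1.5% metabolite at
p < 0.1 is ≈0.87, so most — not all — planted genes are recovered per run,
which is the regime the validation suite checks. Causal SNPs are anchored
to fixed genome positions but snapped to the nearest SNP with realized
MAF ≥ 0.10, so the planted signal cannot be removed by the pipeline's own
MAF filter.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: realistic cattle LD maps (independent SNPs by
default), pedigree/family structure beyond what random genotypes induce,
genotype-covariate confounding (covariate shifts are independent of
genotype), metabolite-metabolite correlation beyond shared polygenic
sampling, nonlinear growth, diet-energy variation, and measurement-batch
effects. Calibration and power results transfer to real data only insofar
as these features are second-order for the tested property.

## Numerical choices and conventions

- Thresholds are applied exactly as phrased for removal/selection:
  MAF < 0.05 removed, p < 0.1 selected, p < 1e-5 significant,
  p < 0.05 enriched — boundary values go the other way.
- Outlier SD is the sample SD (ddof 1), computed once.
- Tie-breaks: metabolite selection sorts (p, name); significant SNPs sort
  (numeric-aware chromosome, position); enrichment sorts (p, set name).
- REML floor 1e-8 × var(y); GRM eigenvalues clipped at 0; scan adds
  1e-8 × (σ²_a + σ²_e) jitter once if V is singular.
- Degenerate inputs raise typed errors (`ConfigError`, `DataError`,
  `ConvergenceError` → CLI exit codes 2/3/4); empty QC output and empty
  candidate sets warn instead of raising.
- Metabolite concentrations are analysed on the raw µM scale; no transform
  is applied by default (none is prescribed for the emulated workflow), and
  the pre-adjustment residual is what enters every association stage, so a
  monotone transform would change only effect-size units, not the test
  logic.

## Design choices on genuinely open points

- The expected-DMI regression behind RFI is pooled across animals by
  default (per-group fitting available) — contemporary-group structure is
  study-specific.
- V_m/V_P is the joint R² (see above); both joint and univariate values are
  computed.
- The stage-level shell verbs are provided as library functions plus the
  `run-all`/`demo`/`simulate` CLI; the pipeline is primarily a Python API
  and the CLI stays thin.
- Outlier masks are per phenotype, not joint across phenotypes.
- Breed fractions enter as K−1 columns; the dropped component is the last.

## Known limitations

- Non-LOCO single-GRM scanning deflates the tested SNP's own statistic
  slightly (proximal contamination); at desk scale (m in the thousands)
  the effect is visible as empirical power a few points below the
  non-central chi-square oracle.
- REML heritability at n ≈ 500–800 with thousands of SNPs has a sampling
  SD of ~0.08–0.13; null heritability estimates above 0.1 occur in roughly
  one replicate in ten by the estimator's own distribution.
- The enrichment universe choice materially changes p-values; the default
  (all annotation genes) is one defensible choice, configurable.
- The hypergeometric test treats genes as exchangeable; gene length and SNP
  density biases typical of GWAS gene-set testing are not corrected.
- VCF output is minimal (GT + one INFO key); dosage-probability formats
  (GP/DS) are not emitted.
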