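# Methods

## The model

All inference is under the additive animal model. For records y stacked by
trait,

    y = Xb + u + e,      u ~ N(0, G0 ⊗ K),      e ~ N(0, R)

where b holds the fixed effects (intercept plus dummy-coded categorical
factors: tank/pen, and sex where it is not nested in single-sex tanks), K is a
relationship matrix over individuals (pedigree A, genomic G, or single-step
H), G0 is the trait × trait genetic covariance matrix and R carries a
residual variance per trait plus a residual covariance for each trait pair
measured on the same individuals. Heritability is h² = V_g/(V_g+V_r);
coefficients of variation are CV = √V_p/mean·100 and CGV = √V_g/mean·100;
genetic/residual correlations are the usual covariance-over-geometric-mean
ratios.

**GxE layout.** The same trait recorded in two environments is treated as two
traits. Because no fish has records in both environments, the residual
covariance between the two environment-traits has no data support and is
structurally zero — exactly the constraint the two-environment model
requires; `gxe_fit` enforces one-environment-per-individual and fits sex and
tank within each environment. The cross-environment genetic correlation r_g
is the GxE statistic; the package prints it against the conventional 0.7
re-ranking benchmark.

## REML estimation

Because records enter V = Σ_k θ_k V_k **linearly** in the (co)variance
parameters θ (genetic blocks are K submatrices, residual blocks are
indicators), the REML score and average-information (AI) matrix are exact:

    score_k = −½ [tr(P V_k) − y′P V_k P y],    AI_kl = ½ y′P V_k P V_l P y

with P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹. Each iteration costs one Cholesky
factorization and one inverse of V (n × n over records). Updates are damped
AI steps with step halving; if no damped step helps, a backtracking
gradient-ascent step is taken. **A step is accepted only if it does not
decrease the restricted log-likelihood**, so the likelihood trace is monotone
by construction. This replaces the more common log-Cholesky/EM combination:
EM for the record-stacked multivariate model needs the full prediction-error
covariance (prohibitive at n ≈ 2,000 per trait), while monotone backtracking
gives the same ascent guarantee; validity (G0, R0 positive semi-definite,
variances above a floor of 1e-8 × the phenotypic variance) is enforced by
step rejection and clamping.

Convergence: relative log-likelihood change < 1e-9 **and** maximum relative
parameter change < 1e-6 (defaults, configurable). Starting values: half the
OLS residual variance for each variance, 0.1·√(v_i v_j) for covariances.
Standard errors come from the inverse AI matrix at the optimum; parameters
clamped at the variance floor are flagged `boundary` and their SEs reported
as NaN rather than from a degenerate AI matrix. Derived-parameter SEs (h²,
correlations) use the first-order delta method on the AI inverse.

Checks: on a balanced 50-sire × 20-offspring one-way design the fit equals
the expected-mean-square ANOVA estimators to machine precision; with K = I
and one record per individual only V_g + V_r is identified and the total
equals RSS/(n − rank(X)).

## Relationship matrices

- **A** by the tabular method over a topologically sorted pedigree; unknown
  parents are unrelated non-inbred founders. A⁻¹ by Henderson's rules with
  inbreeding coefficients taken from the tabular diagonal; a dense inverse
  cross-check agrees to 1e-8.
- **G** is VanRaden method 1 with column centering at 2p and denominator
  2Σp(1−p); missing dosages are mean-imputed before centering. Frequencies
  default to the observed panel (parents + offspring after intersection when
  built on the common panel); monomorphic markers are a hard error directing
  the user to the MAF filter.
- **H⁻¹** augments A⁻¹ on the genotyped block with τG*⁻¹ − ωA₂₂⁻¹, where
  G* = αG + (1−α)A₂₂ guards invertibility. Defaults α = 0.95, τ = ω = 1.
  When G_raw = A₂₂ the augmentation vanishes and H⁻¹ = A⁻¹ for any α.

## Genotype QC

Filter order is PLINK-like and fixed: duplicate marker ids/positions (first
occurrence kept) → individuals missing **strictly more than** 10% of calls →
markers missing in more than 10% of individuals → Hardy-Weinberg exact-test
p < 1e-6 → MAF < 0.005 computed on non-missing calls. The HWE test is the
exact conditional enumeration over heterozygote counts given the minor-allele
count, which stays calibrated at low MAF. Panel intersection matches marker
id and allele pair, recoding dosage as 2−d when A1/A2 are swapped between
panels. Individual filters and the marker filter chain are each idempotent;
the composition is not guaranteed to be (removing markers can raise an
individual's missing fraction), which is why the QC report reconciles counts
stage by stage.

## Parentage

Opposite homozygosity (OH) counts loci where one individual is homozygous for
one allele and the other homozygous for the other; a true parent-offspring
pair has OH = 0 up to genotyping error. For each offspring the minimum-OH
sire and dam are tentative parents, accepted only when (i) neither minimum is
tied, (ii) both OH rates (OH / jointly typed loci) are at or below the
threshold (default 0.01 — tolerant of ~0.5% genotyping error with margin; no
published acceptance threshold exists), and (iii) the pair is a known mating.
Everything else falls to a per-pair log-likelihood under Mendelian
transmission with a symmetric dosage-error model, searched over the known
matings, with a 10-natural-log-unit margin between best and runner-up before
assignment; otherwise the offspring stays unassigned and keeps unknown-parent
links downstream (the single-step H matrix absorbs ungenotyped/unassigned
individuals). The likelihood stage is a principled stand-in: the original
in-house fallback is unspecified, so its behaviour is documented here rather
than claimed as a reproduction.

## GWAS

MLMA-LOCO: for each chromosome c a VanRaden GRM is built from all markers
**not** on c (computed as the full cross-product minus the chromosome's
contribution, denominator adjusted), variance components are re-estimated
under that GRM (a flag reuses one global fit for speed), and every marker on
c is tested as a fixed covariate by the GLS Wald statistic effect²/SE²
against χ²(1), holding the components fixed within the chromosome. Candidate
dosages are mean-imputed like the GRM; zero-variance markers are flagged
`untestable`, markers on a non-converged chromosome `no_vc`. Thresholds
depend only on (n_snps, n_chromosomes): −log₁₀(0.05/N) and
−log₁₀(0.05/(N/C)), with C read from the analyzed marker map. With
relationship = identity and fixed components (0, σ²) the scan reduces exactly
to ordinary least squares with known residual variance.

## The simulator

The generator emulates a nucleus breeding population: defaults are 72 sires
and 139 dams mated hierarchically (dam j to sire ⌊j/2⌋, so one male serves
up to two females; 139 full-sib families), 14 offspring per family, 3,000
biallelic SNPs evenly spread over 29 chromosomes with MAF ~ U(0.05, 0.5),
offspring split between two environments stratified by family and sex,
single-sex tanks (6 per environment), and a bottom-fraction cull operator.
Trait defaults are the two growth measurements (whole-body weight, g; fork
length, cm) with per-environment genetic and residual (co)variances at the
scale of the motivating dataset (weight: V_g/V_r 127.10/175.08 in RAS,
129.58/591.94 in the loch; means 88.03 g and 121.87 g; male shift −6.57 g)
and per-trait cross-environment genetic correlations (0.62 weight, 0.78
length). Condition factor K = 100·W/L³ (Fulton's convention — the ×100
factor is required for K values near 1.25 with grams and centimetres) is
derived from the simulated weight and length, not simulated separately.

Mechanism: founder genotypes are binomial(2, p) draws; offspring receive one
uniformly chosen allele per parent per locus (gene dropping, loci unlinked).
Each SNP gets one effect per (trait, environment) cell from a joint normal
whose correlation matrix combines the within-environment trait correlations
with the per-trait cross-environment correlation (cross-trait-cross-env
entries use the averaged within-environment correlation scaled by
√(r_t·r_s); an indefinite assembly is projected to the nearest correlation
matrix). Effects act at the SNP level — rather than rotating breeding values
after the fact — so genotype → phenotype causality is intact for association
testing, and a `causal_chromosomes` option restricts effects to named
chromosomes for null-calibration designs. Effect columns are rescaled so the
genic variance Σ 2p₀(1−p₀)β² over founder frequencies equals the configured
V_g exactly; realized breeding-value variance then fluctuates only through
family structure and drift. Genotyping error perturbs dosage symmetrically
(0→1, 2→1, 1→0 or 2); the pre-error dosages back the truth records.
Phenotype = intercept + sex effect + tank effect (drawn once per tank from a
configurable per-environment normal, so a tank effect can be created in one
environment and suppressed in the other) + breeding value in the environment
of residence + multivariate-normal residual.

What the simulator does **not** model — and therefore what passing tests do
not establish about real data: linkage and LD within chromosomes, dominance
and epistasis, selection during rearing beyond the explicit cull operator,
family-size imbalance (sizes are constant unless a per-family distribution is
supplied; the motivating data ranged from 1 to 28), maternal/common-tank
random effects, genotyping-batch artifacts, and any physiology
(photoperiod/smoltification, water chemistry).

## Problem sizes and runtime choices

The replicate experiments run at the full study design scale (139 families,
~973 phenotyped offspring per environment, 3,000 SNPs): one univariate fit
takes ~1 s and one bivariate GxE fit ~5 s on a single core, so the
30-replicate recovery experiments complete in a few minutes. GWAS
calibration uses 4,000 markers on 20 chromosomes with effects confined to
chromosomes 1–10 and the 2,000 markers on chromosomes 11–20 as the tested
null, n ≈ 540 phenotyped in one environment. Unit tests use a scaled-down
population (12 sires × 22 dams) wherever the full design adds nothing.

## Known limitations

- The AI-REML engine builds dense n × n covariance matrices over records; it
  is comfortable to ~5,000 records but not designed for national-evaluation
  scales (no sparse MME path).
- Tank/pen is a fixed effect, matching the analysis being emulated; no
  maternal or common-environment random effects are available.
- `derive_params` reports the model-based CV alongside the raw phenotypic CV
  (the pipeline's descriptives): the two differ whenever fixed effects absorb
  variance, and published tables do not always say which was used.
- Parentage assumes candidate parents are genotyped; there is no sibship
  reconstruction without candidates and no multi-generation inference.
- No imputation, phasing, strand resolution against a reference, or VCF
  support.
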