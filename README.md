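# smoltgxe

Quantitative-genetic analysis of fish growth traits measured in two freshwater
rearing environments — a recirculating aquaculture system (RAS) and a loch
net-pen — built for the question every breeding program faces when husbandry
changes: **do families re-rank across environments?**

The package covers the full chain from raw SNP genotypes to the
genotype-by-environment (GxE) verdict:

- **`smoltgxe.synth`** — a nucleus-breeding-population simulator (hierarchical
  1-sire:2-dam matings, Mendelian gene dropping over unlinked biallelic SNPs,
  environment-specific trait variances, controllable cross-environment genetic
  correlation) so every downstream stage has recoverable ground truth.
- **`smoltgxe.plinkio` / `smoltgxe.qc`** — PLINK PED/MAP and BED/BIM/FAM
  codecs; duplicate, missingness, Hardy-Weinberg exact-test and MAF filters;
  common-marker intersection of separately genotyped panels.
- **`smoltgxe.parentage`** — pedigree reconstruction by opposite homozygosity
  (OH) with a known-matings cross-check and a Mendelian-transmission
  likelihood fallback.
- **`smoltgxe.relmat`** — pedigree numerator matrix **A** (tabular method,
  Henderson-rules inverse), VanRaden genomic matrix
  **G** = ZZ′/2Σpᵢ(1−pᵢ), and the single-step
  **H**⁻¹ = A⁻¹ + [0 0; 0 τG\*⁻¹ − ωA₂₂⁻¹] with G\* = αG + (1−α)A₂₂.
- **`smoltgxe.varcomp`** — average-information REML for the animal model
  y = Xb + Zu + e with u ~ N(0, G₀ ⊗ K), single- or multi-trait, with the
  cross-environment GxE layout (same trait in two environments as two traits,
  residual covariance structurally zero) and derived parameters
  h² = V_g/(V_g+V_r), CV = √V_p/mean·100, CGV = √V_g/mean·100, r_g, r_r, r_p
  with delta-method standard errors.
- **`smoltgxe.gwas`** — mixed-linear-model association with
  leave-one-chromosome-out GRMs, Wald tests per marker, and Bonferroni lines
  at −log₁₀(0.05/N) (genome) and −log₁₀(0.05/(N/C)) (chromosome).
- **`smoltgxe.pipeline`** — one-config orchestration of all stages with a
  machine-readable report.

The GxE statistic is the genetic correlation r_g between the environment-
specific expressions of a trait; values below ~0.7–0.8 flag family re-ranking
strong enough to matter for selection.

## Worked example

The numbered scripts under `analysis/` run the study end to end on simulated
data (139 full-sib families from 72 sires × 139 dams, ~1,946 phenotyped
offspring split between environments, 3,000 SNPs on 29 chromosomes, weight
simulated with V_g/V_r of 127.10/175.08 in RAS and 129.58/591.94 in the loch,
cross-environment r_g = 0.62):

```bash
python analysis/01_simulate.py          # writes results/simulation/
python analysis/02_qc.py                # filters + common panel
python analysis/03_parentage.py         # OH pedigree reconstruction
python analysis/04_relationship_matrices.py
python analysis/05_reml_univariate.py   # per-environment h2
python analysis/06_gxe.py               # the GxE genetic correlation
python analysis/07_gwas.py              # MLMA-LOCO scans per environment
python analysis/08_recovery_report.py   # replicate calibration
```

Output of one run (seed 1):

```
parentage recovery: 100.00% of offspring matched to their true sire-dam pair
RAS: Vg=130.15 (SE 20.81), Vr=177.22 (SE 14.61), h2=0.42 (SE 0.05), CGV=13.23%
loch: Vg=71.42 (SE 29.77), Vr=641.52 (SE 38.30), h2=0.10 (SE 0.04), CGV=7.12%
cross-environment genetic correlation for weight: 0.76 (SE 0.18)
```

A single replicate is noisy (the loch heritability above sits ~2 SE under its
generating value, and r_g 0.76 vs the generating 0.62); `08_recovery_report.py`
shows the estimators are centered over replicates:

```
h2:  mean 0.409 (truth 0.421), replicate SD 0.067 vs mean reported SE 0.055
r_g: mean 0.628 (truth 0.62), replicate SD 0.125 vs mean reported SE 0.136
```

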