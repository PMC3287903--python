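# winnerscurse

Simulation pipeline for quantifying **winner's-curse selection bias in
two-stage genetic association studies**: a stage-1 GWAS-like scan selects a
tag SNP by significance, and stage 2 estimates the genetic effect at the
causal variant(s) — either a single common SNP or a rare-variant collapsing
statistic — in the *same* sample. Estimating only after selecting inflates
effect estimates (the winner's curse), while incomplete linkage
disequilibrium (LD) between tag and causal SNPs attenuates them; this
package measures how the two forces combine, for statistical geneticists
planning replication or targeted-sequencing studies from GWAS hits.

## The model

Genotypes are additive minor-allele counts under Hardy–Weinberg
equilibrium. LD between a tag SNP (MAF `p_T`) and a causal SNP (MAF `p_C`)
is the haplotype allelic correlation `ρ_TC`, bounded by

```
ρ_max = sqrt( p_min (1 − p_max) / ( p_max (1 − p_min) ) )
```

so a common SNP can never tightly tag a much rarer one. The expected OLS
slope at the tag SNP is `γ_TC · β` with the attenuation factor

```
γ_TC = ρ_TC · sqrt( p_C (1 − p_C) / ( p_T (1 − p_T) ) )
```

(0 for an uncorrelated tag, 1 when the tag is the causal SNP). Rare-variant
effects are summarised by the collapsing score `r_i / n_i` (the fraction of
genotyped rare SNPs at which individual `i` carries a minor allele); its
regression coefficient `λ` is the effect for carrying a rare allele at every
genotyped rare SNP.

Each replicate data set is simulated, the tag SNP is tested (linear or
logistic additive model), replicates significant at the chosen threshold are
"selected", and effects are estimated at both stages for **all** replicates.
Summaries report estimated power (fraction selected), conditional and
unconditional mean estimates, and the signed **relative bias**
`100·(mean_selected − mean_all)/mean_all`. A closed-form truncated-normal
oracle (`E[Z | |Z| > c]` for `Z ~ N(μ,1)`) provides the analytic account of
the curse that the simulations are checked against.

Three study designs are built in: **S1** common tag / common causal SNP,
**S2** common tag / multiple rare causal SNPs in a gene, and **S3** a
low-MAF (1–5%) tag from the gene itself, excluded from the collapsing
statistic, with the significance threshold calibrated on the ladder
{0.05, 0.01, 0.001} to keep power below 20%.

## Worked example

```sh
winnerscurse simulate --config examples/scenario2.yaml --out results/s2
```

or equivalently, the numbered drivers under `analysis/`:

```sh
python analysis/02_scenario2_common_tag_rare_burden.py
```

which prints (seed fixed in the script):

```
calibrated threshold: alpha=0.05 (pilot powers {0.05: 0.195, 0.01: 0.055, 0.001: 0.02})
estimated power: 0.170
tag estimate  all/selected: 0.07/0.16 (relative bias 147%)
tag-burden correlation: 0.30
lambda-hat    all/selected: 2.05/2.29 (relative bias 12%; lambda_true=2.0)
```

Reading: the common tag captures the rare-variant burden only weakly
(correlation 0.30), so stage-1 power is low (17%) and conditioning on
significance inflates the mean tag estimate by 147%. The collapsing
estimate `λ̂` is unbiased over all 200 replicates (2.05 vs a true λ of 2.0)
but inherits part of the curse through the tag–burden correlation: +12%
among selected replicates. Running `analysis/03_scenario3_low_maf_tag.py`
shows the flip side — a low-MAF tag reaches correlation 0.77 and transfers
far more of the bias (+69% on `λ̂`) at similar tag-level bias, and
`analysis/01_...` sweeps `γ_TC` from 0 (no carry-through to the causal SNP)
to 1 (high power, minimal bias).

The CLI also provides `calibrate` (threshold-ladder search), `summarize`
(recompute tables from persisted per-replicate records) and `convert`
(round-trip genotypes between a tab-separated additive matrix and a minimal
biallelic VCF; real genotypes can enter the pipeline the same way).

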