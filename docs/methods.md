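# Methods

## Generating model

**Genotypes.** Every locus is biallelic with a specified minor-allele
frequency (MAF) in (0, 0.5]. Individuals are formed as two independent
haplotypes (Hardy–Weinberg equilibrium, random mating, one homogeneous
population) and coded additively as minor-allele counts 0/1/2. Linkage
disequilibrium between two loci is parameterised by the Pearson correlation
ρ of minor-allele indicators on haplotypes; under HWE the genotype-level
correlation equals the haplotype-level ρ, which the tests verify
empirically. A tag–causal pair is realised through its 2×2 haplotype table
with disequilibrium coefficient D = ρ·sqrt(p_T q_T p_C q_C); the table is
rejected (never clipped) when any cell would be negative.

**LD feasibility bounds.** The attainable positive correlation is
ρ_max = sqrt(p_min(1−p_max)/(p_max(1−p_min))), reached when the rarer
allele occurs only on haplotypes carrying the commoner minor allele.
Negative ρ (minor alleles in repulsion) is accepted but is capped
separately at ρ_min = −sqrt(p_T p_C / (q_T q_C)), the point where the
both-minor haplotype frequency reaches zero; for non-rare MAFs this cap is
strictly tighter than −ρ_max (e.g. two loci at MAF 0.25 cannot reach
ρ = −1), so a symmetric |ρ| ≤ ρ_max rule would admit impossible tables.
Both caps carry a 1e−9 relative tolerance: a ρ equal to the bound is
feasible, one exceeding it by a part per million is not.

**Genes with multiple rare variants.** A gene is a tag locus plus L rare
loci (each MAF < 5%, the rare/common boundary used throughout). Haplotypes
are built tag-allele first; each rare allele is drawn conditionally on the
tag allele with conditional probabilities chosen so each tag–rare pair
attains its target ρ, and rare loci are mutually independent given the tag
allele. This is the simplest joint structure in which one tag is
simultaneously correlated with many rare variants; real haplotype mosaics
(recombination, nested LD among the rare variants themselves) are not
modelled, so tag–burden correlations here are fully determined by the
per-pair ρ values.

**Covariates and traits.** Age ~ Uniform(20, 80) years and
Smoking ~ Bernoulli(0.3) are generic stand-ins (configurable); they enter
only the Q1-like trait. Three trait kinds: quantitative with covariates
(Q1-like), quantitative without (Q2-like), and binary disease status
(logistic, no covariates). The genetic term is either Σ β_j·G_j over causal
loci or λ_true·(r_i/n_i) under the collapsing model — exactly one of the
two drives a given simulation. Quantitative noise is Gaussian with sd σ.
Genotype missingness can be masked in at a configurable rate (default 0)
to exercise the r_i/n_i denominator; traits are always generated from the
complete genotypes, so missingness is non-informative.

## Estimation and selection

Stage-1 and stage-2 effects are estimated by ordinary least squares
(quantitative) or maximum-likelihood logistic regression (binary), with
intercept, Wald tests, and complete-case handling; fits are delegated to
statsmodels. Covariates, when the trait kind has them, enter both stages —
the covariate set belongs to the trait, not to a stage. Monomorphic
predictors raise a degenerate-design error; logistic separation is detected
(a genotype threshold perfectly predicting status, or a non-converged fit)
and raised, never returned as a finite estimate.

The collapsing score is r_i/n_i with r_i the number of rare loci at which
individual i carries ≥ 1 minor allele and n_i the number of non-missing
rare loci — the carrier-indicator reading of the burden statistic. An
allele-counting variant (`count_alleles=True`) is available but not the
default. Rows with n_i = 0 are flagged undefined and excluded from the
burden regression. In scenario S3 the tag SNP, though itself rare, is
excluded from the score.

Selection keeps replicates whose stage-1 tag test is significant:
two-sided p < α, or, for the one-sided rule, a positive estimate with
two-sided p < 2α (an exact one-sided level-α test). Stage-2 estimates are
computed for **every** replicate and filtered at summary time, so
conditional and unconditional summaries come from the same records.
Degenerate replicates are flagged with a reason, counted, logged, and
excluded from both numerator and denominator of all summaries.

**Threshold calibration.** Scenarios S2/S3 choose the largest threshold
from the ladder {0.05, 0.01, 0.001} whose estimated power on a pilot
replicate set (drawn from the same generating model with a shifted seed
stream, so calibration and analysis replicates are disjoint) stays below
the 20% ceiling; if none qualifies the run fails loudly with the pilot
powers listed.

## Summary measures

Estimated power is the fraction of valid replicates selected. Relative
bias is signed: 100·(mean_selected − mean_all)/mean_all. The ratio is
reported undefined (NaN, with both means still reported) when no replicate
is selected or when |mean_all| ≤ 1e−3 × the estimate SD — dividing by a
near-zero null mean (as for an uncorrelated tag under two-sided selection)
produces arbitrarily large, sign-unstable percentages; a magnitude variant
of the summary exists for exactly that case. The attenuation factor is
γ_TC = ρ_TC·sqrt(p_C q_C/(p_T q_T)), the OLS identity under the additive
model: the expected tag slope is γ_TC·β, verified by large-n simulation.
The per-replicate tag–burden Pearson correlation is averaged across
replicates (per-replicate-then-average, not pooled).

The analytic winner's-curse oracle treats the standardized estimate as
Z ~ N(μ, 1) with noncentrality μ = β·sqrt(2 n p q)/σ and returns
E[Z | selection] and the selection probability in closed form for one- and
two-sided rules; it is cross-checked against quadrature and used to verify
the simulated conditional means.

## Reproducibility and numerics

One master seed per run; replicate k uses `SeedSequence(seed, spawn_key=(k,))`
split into independent streams for genotypes, covariates, trait noise, and
missingness, so any replicate is reproducible in isolation and adding
replicates never perturbs earlier ones. Identical (config, seed) produce
byte-identical CSV outputs. Logistic fits use statsmodels' Newton defaults
with a 100-iteration cap. Haplotype cell values within 1e−12 below zero
(floating-point residue at the feasibility boundary) are clipped to zero;
marginals are preserved to 1e−12.

## Study conditions and test sizes

Default sample sizes follow the emulated study: n = 616 for S1 and
n = 697 for S2/S3, with 200 replicates per run and the {0.05, 0.01, 0.001}
ladder under a 20% power ceiling. Effect sizes are not dictated by the
emulated data set, whose phenotype model is not public; they were chosen
once to land in the scientifically relevant regimes — e.g. β = 0.0574 at
MAF 0.3, σ = 1 gives ~15% power at α = 0.05 (noncentrality ≈ 0.92), the
S2 gene (tag MAF 0.20, ten rare SNPs at MAF 0.02, per-pair ρ = 0.10,
λ = 2) yields a tag–burden correlation ≈ 0.3 with power < 20%, and the S3
gene (tag MAF 0.03, per-pair ρ = 0.40, λ = 0.6) yields correlation ≈ 0.77.
Verification runs use 2,000–5,000 replicates where Monte Carlo bands must
be tight (oracle match, carry-through null, ladder monotonicity, type-I
error) and n = 10^5 individuals for large-n identities (attenuation,
parameter recovery); the acceptance script reports the same quantities at
2,000–3,000 replicates. All error bands are 3-sigma Monte Carlo or
binomial bands computed from the data, not tuned constants.

## What passing tests do and do not show

The simulations validate the estimation and selection machinery under the
generator's assumptions: HWE, a homogeneous population, per-pair LD with
conditional independence of rare variants, Gaussian or Bernoulli traits,
non-informative missingness. Real cohorts add population stratification,
relatedness, richer haplotype structure, informative missingness, and
genotyping error, none of which is emulated; conclusions about the
*magnitude* of bias in real two-stage designs therefore transfer only
qualitatively. Bias-correction estimators (conditional likelihood,
bootstrap shrinkage) are out of scope, as are genome-wide multi-SNP scans:
each run studies one tag SNP, which is how the two-stage question is posed.
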