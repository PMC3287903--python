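"""Genotype, covariate, and trait simulation with controlled tag–causal LD.

Simulated data sets emulate a two-stage association study: a tag SNP
genotyped at stage 1 stands proxy, through linkage disequilibrium (LD),
for one common causal SNP or for several rare causal SNPs in a gene that
are only observed at the sequencing stage.

LD between two biallelic loci is parameterised by the Pearson correlation
rho of minor-allele indicators on haplotypes. Genotypes are formed under
Hardy–Weinberg equilibrium (two independent haplotypes per individual,
additive 0/1/2 minor-allele-count coding), under which the genotype-level
correlation equals the haplotype-level rho. The attainable |rho| is
bounded by the allele-frequency mismatch; specs violating the bound are
rejected, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "FeasibilityError",
    "DomainError",
    "LdPairSpec",
    "GeneSpec",
    "TraitModel",
    "ReplicateData",
    "RARE_MAF_CEILING",
    "rho_max",
    "rho_bounds",
    "haplotype_freqs",
    "sample_pair_genotypes",
    "sample_gene_genotypes",
    "simulate_covariates",
    "simulate_trait",
    "mask_missing",
]

#: MAF below which a SNP counts as rare (common above it).
RARE_MAF_CEILING = 0.05

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


class DomainError(ValueError):
    """A frequency or parameter outside its mathematical domain."""


class FeasibilityError(ValueError):
    """A requested LD level exceeds what the two MAFs allow."""


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_maf(p: float, name: str) -> None:
    if not (0.0 < p <= 0.5):
        raise DomainError(
            f"{name} must be a minor-allele frequency in (0, 0.5], got {p!r}"
        )


def rho_max(p_t: float, p_c: float) -> float:
    """Upper bound on the haplotype allelic correlation between two SNPs.

    For minor-allele frequencies ``p_t`` and ``p_c`` (both in (0, 0.5]) the
    Pearson correlation of minor-allele indicators cannot exceed

        sqrt( p_min (1 - p_max) / ( p_max (1 - p_min) ) )

    with ``p_min = min(p_t, p_c)``, ``p_max = max(p_t, p_c)``: a common tag
    SNP can capture only a small share of the variation at a much rarer
    SNP, however tight the physical linkage.
    """
    _check_maf(p_t, "p_t")
    _check_maf(p_c, "p_c")
    p_min, p_max = min(p_t, p_c), max(p_t, p_c)
    return float(np.sqrt(p_min * (1.0 - p_max) / (p_max * (1.0 - p_min))))


# relative slack when checking |rho| <= rho_max: admits rho == rho_max computed
# by the formula above, but rejects rho_max * (1 + 1e-6)
_RHO_TOL = 1e-9


def rho_bounds(p_t: float, p_c: float) -> tuple[float, float]:
    """Attainable (rho_min, rho_max) for a pair of minor-allele frequencies.

    The positive limit is ``rho_max``; repulsion (negative rho) is capped
    separately by the both-minor haplotype frequency reaching zero:
    rho_min = -sqrt( p_t p_c / ((1-p_t)(1-p_c)) ).
    """
    _check_maf(p_t, "p_t")
    _check_maf(p_c, "p_c")
    lo = -float(np.sqrt(p_t * p_c / ((1.0 - p_t) * (1.0 - p_c))))
    return lo, rho_max(p_t, p_c)


def _check_rho(p_t: float, p_c: float, rho: float, what: str) -> None:
    lo, hi = rho_bounds(p_t, p_c)
    bound = hi if rho >= 0 else -lo
    if abs(rho) > bound * (1.0 + _RHO_TOL):
        raise FeasibilityError(
            f"{what}: |rho|={abs(rho):.6g} exceeds the attainable "
            f"{'rho_max' if rho >= 0 else '|rho_min|'}({p_t}, {p_c})="
            f"{bound:.6g}; the MAF mismatch caps the correlation"
        )


@dataclass(frozen=True)
class LdPairSpec:
    """A tag–causal locus pair: two MAFs and a target haplotype correlation.

    ``rho_tc`` may be negative (minor alleles in repulsion); the
    feasibility bound applies to its magnitude.
    """

    p_t: float
    p_c: float
    rho_tc: float

    def __post_init__(self) -> None:
        _check_maf(self.p_t, "p_t")
        _check_maf(self.p_c, "p_c")
        _check_rho(self.p_t, self.p_c, self.rho_tc, "LdPairSpec")

    @property
    def rho_bound(self) -> float:
        return rho_max(self.p_t, self.p_c)


@dataclass(frozen=True)
class GeneSpec:
    """A tag locus plus multiple rare causal loci in one gene.

    Rare loci are mutually independent conditional on the tag allele, so
    each tag–rare pair attains its target haplotype correlation while the
    gene keeps the simplest joint structure consistent with a tag SNP
    correlated with several rare SNPs.
    """

    tag_maf: float
    rare_mafs: tuple[float, ...]
    tag_rare_rho: tuple[float, ...]
    exclude_tag_from_burden: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "rare_mafs", tuple(float(p) for p in self.rare_mafs))
        object.__setattr__(
            self, "tag_rare_rho", tuple(float(r) for r in self.tag_rare_rho)
        )
        _check_maf(self.tag_maf, "tag_maf")
        if len(self.rare_mafs) == 0:
            raise ValueError("GeneSpec needs at least one rare causal locus")
        if len(self.rare_mafs) != len(self.tag_rare_rho):
            raise ValueError(
                "tag_rare_rho must have one entry per rare locus "
                f"({len(self.tag_rare_rho)} vs {len(self.rare_mafs)})"
            )
        for j, p in enumerate(self.rare_mafs):
            _check_maf(p, f"rare_mafs[{j}]")
            if p >= RARE_MAF_CEILING:
                raise ValueError(
                    f"rare_mafs[{j}]={p} is not rare (MAF must be < "
                    f"{RARE_MAF_CEILING})"
                )
        for j, r in enumerate(self.tag_rare_rho):
            _check_rho(self.tag_maf, self.rare_mafs[j], r, f"rare locus {j}")

    @property
    def n_rare(self) -> int:
        return len(self.rare_mafs)


@dataclass(frozen=True)
class TraitModel:
    """Generating model for a quantitative trait or binary disease status.

    kind:
        ``quantitative_with_covariates`` — linear model with Age and
        Smoking covariates (Q1-like); ``quantitative`` — linear model
        without covariates (Q2-like); ``binary`` — logistic model without
        covariates (disease-status-like).
    beta:
        Additive effect per minor allele at each causal locus (trait units,
        or log-odds for binary). A scalar is broadcast over causal loci.
    lambda_true:
        Burden-model effect per unit of the rare-variant carrier
        proportion r_i/n_i; mutually exclusive with ``beta``.
    covariate_effects:
        (per-year Age effect, Smoking effect); quantitative_with_covariates
        only.
    sigma:
        Residual standard deviation (quantitative kinds).
    intercept:
        Baseline trait mean, or baseline log-odds for binary.
    """

    kind: str
    beta: Optional[Union[float, tuple[float, ...]]] = None
    lambda_true: Optional[float] = None
    covariate_effects: tuple[float, float] = (0.0, 0.0)
    sigma: float = 1.0
    intercept: float = 0.0

    KINDS = ("quantitative_with_covariates", "quantitative", "binary")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        if (self.beta is None) == (self.lambda_true is None):
            raise ValueError(
                "exactly one of beta / lambda_true must drive the genetic term"
            )
        if self.kind != "binary" and not self.sigma > 0:
            raise ValueError("sigma must be > 0 for quantitative traits")
        if isinstance(self.beta, (list, tuple)):
            object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))

    @property
    def uses_covariates(self) -> bool:
        return self.kind == "quantitative_with_covariates"


@dataclass
class ReplicateData:
    """One simulated data set: genotypes, covariates, and (optionally) a trait.

    ``genotypes`` is an n x m float matrix of minor-allele counts in
    {0, 1, 2}, with NaN marking missing calls. ``locus_roles`` labels each
    column as ``tag``, ``causal`` or ``rare_causal``.
    """

    genotypes: np.ndarray
    locus_roles: list[str]
    locus_ids: list[str]
    covariates: Optional[np.ndarray] = None
    trait: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing genotype entries must be in {0, 1, 2}")
        if self.genotypes.shape[1] != len(self.locus_roles):
            raise ValueError("locus_roles must label every genotype column")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def columns(self, role: str) -> np.ndarray:
        idx = [j for j, r in enumerate(self.locus_roles) if r == role]
        return self.genotypes[:, idx]


def haplotype_freqs(spec: LdPairSpec) -> np.ndarray:
    """Four haplotype frequencies realising the pair's MAFs and rho.

    Returns, in order: (minor,minor), (minor at tag only), (minor at
    causal only), (major,major). The disequilibrium coefficient is
    D = rho * sqrt(p_t q_t p_c q_c), so f(minor,minor) = p_t*p_c + D.
    """
    p_t, p_c, rho = spec.p_t, spec.p_c, spec.rho_tc
    d = rho * np.sqrt(p_t * (1 - p_t) * p_c * (1 - p_c))
    f = np.array(
        [
            p_t * p_c + d,
            p_t * (1 - p_c) - d,
            (1 - p_t) * p_c - d,
            (1 - p_t) * (1 - p_c) + d,
        ]
    )
    if (f < -1e-12).any():
        raise FeasibilityError(
            f"rho={rho} is infeasible for MAFs ({p_t}, {p_c}): a haplotype "
            f"frequency would be negative (bound rho_max={spec.rho_bound:.6g})"
        )
    return np.clip(f, 0.0, None)


def _pair_haplotypes(spec: LdPairSpec, n_hap: int, rng: np.random.Generator):
    """Draw n_hap haplotypes; returns (tag allele, causal allele) 0/1 arrays."""
    f = haplotype_freqs(spec)
    h = rng.choice(4, size=n_hap, p=f / f.sum())
    return (h < 2).astype(np.int8), ((h == 0) | (h == 2)).astype(np.int8)


def sample_pair_genotypes(spec: LdPairSpec, n: int, seed: SeedLike) -> np.ndarray:
    """HWE genotypes at a tag–causal pair: n x 2 minor-allele counts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    t1, c1 = _pair_haplotypes(spec, n, rng)
    t2, c2 = _pair_haplotypes(spec, n, rng)
    return np.column_stack([t1 + t2, c1 + c2]).astype(float)


def sample_gene_genotypes(spec: GeneSpec, n: int, seed: SeedLike) -> np.ndarray:
    """HWE genotypes for a gene: n x (1 + L) matrix, tag column first.

    Haplotypes are built tag-allele first; each rare allele is then drawn
    conditionally on the tag allele with conditional carrier probabilities
    chosen so the pair attains its target haplotype correlation. Rare loci
    are mutually independent given the tag allele.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    p_t = spec.tag_maf
    # P(rare minor | tag minor/major) for each rare locus, from the pair table
    p_given = np.empty((spec.n_rare, 2))
    for j in range(spec.n_rare):
        try:
            f = haplotype_freqs(LdPairSpec(p_t, spec.rare_mafs[j], spec.tag_rare_rho[j]))
        except FeasibilityError as err:
            raise FeasibilityError(f"rare locus {j}: {err}") from err
        p_given[j, 1] = f[0] / p_t          # given tag minor
        p_given[j, 0] = f[2] / (1.0 - p_t)  # given tag major
    geno = np.zeros((n, 1 + spec.n_rare))
    for _ in range(2):  # two haplotypes per individual
        tag_allele = (rng.random(n) < p_t).astype(np.int8)
        geno[:, 0] += tag_allele
        u = rng.random((n, spec.n_rare))
        geno[:, 1:] += u < p_given[:, tag_allele].T
    return geno


def simulate_covariates(
    n: int,
    seed: SeedLike,
    age_range: tuple[float, float] = (20.0, 80.0),
    smoking_prob: float = 0.3,
) -> np.ndarray:
    """n x 2 covariate matrix: Age (uniform, years) and Smoking (Bernoulli)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= smoking_prob <= 1.0):
        raise ValueError("smoking_prob must be in [0, 1]")
    rng = _rng(seed)
    age = rng.uniform(age_range[0], age_range[1], size=n)
    smoking = rng.binomial(1, smoking_prob, size=n).astype(float)
    return np.column_stack([age, smoking])


def _burden_proportion(rare: np.ndarray) -> np.ndarray:
    """Carrier proportion r_i/n_i over complete rare-genotype columns."""
    return (rare >= 1).mean(axis=1)


def simulate_trait(model: TraitModel, data: ReplicateData, seed: SeedLike) -> np.ndarray:
    """Draw the trait vector implied by the generating model.

    The genetic term is either sum_j beta_j * G_ij over causal columns, or
    lambda_true * (r_i/n_i) over rare causal columns when simulating under
    the collapsing (burden) model. Quantitative traits add Gaussian noise
    with sd sigma; the binary kind draws Bernoulli(expit(linear predictor)).
    """
    rng = _rng(seed)
    n = data.n
    if model.beta is not None:
        idx = [
            j for j, r in enumerate(data.locus_roles) if r in ("causal", "rare_causal")
        ]
        causal = data.genotypes[:, idx]
        if causal.shape[1] == 0:
            raise ValueError("beta given but no causal columns in data")
        beta = np.asarray(model.beta, dtype=float)
        if beta.ndim == 0:
            beta = np.full(causal.shape[1], float(beta))
        if beta.shape[0] != causal.shape[1]:
            raise ValueError(
                f"beta has {beta.shape[0]} entries for {causal.shape[1]} causal loci"
            )
        if np.isnan(causal).any():
            raise ValueError("trait simulation requires complete causal genotypes")
        genetic = causal @ beta
    else:
        rare = data.columns("rare_causal")
        if rare.shape[1] == 0:
            raise ValueError("lambda_true given but no rare_causal columns in data")
        if np.isnan(rare).any():
            raise ValueError("trait simulation requires complete rare genotypes")
        genetic = model.lambda_true * _burden_proportion(rare)

    eta = model.intercept + genetic
    if model.uses_covariates:
        if data.covariates is None:
            raise ValueError("quantitative_with_covariates requires covariates")
        eta = eta + data.covariates @ np.asarray(model.covariate_effects, dtype=float)
    if model.kind == "binary":
        p = 1.0 / (1.0 + np.exp(-eta))
        return rng.binomial(1, p, size=n).astype(float)
    return eta + rng.normal(0.0, model.sigma, size=n)


def mask_missing(genotypes: np.ndarray, rate: float, seed: SeedLike) -> np.ndarray:
    """Return a copy with entries set missing (NaN) independently at `rate`."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must be in [0, 1)")
    out = np.asarray(genotypes, dtype=float).copy()
    if rate > 0:
        rng = _rng(seed)
        out[rng.random(out.shape) < rate] = np.nan
    return out
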