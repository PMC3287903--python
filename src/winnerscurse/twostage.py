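"""Replicate loop for the three two-stage study scenarios.

Each replicate simulates one data set, tests the tag SNP at stage 1,
applies the selection rule, and records stage-2 estimates at the causal
SNP (scenario S1) or at the rare-variant collapsing statistic r_i/n_i
(scenarios S2 and S3). Stage-2 estimates are computed for every
replicate — selection marks records rather than skipping them — so both
conditional (selected-only) and unconditional summaries can be formed
afterwards.

Scenarios:

* S1 — common tag SNP, one common causal SNP (an LD pair).
* S2 — common tag SNP (MAF > 5%), multiple rare causal SNPs in a gene.
* S3 — low-MAF tag SNP (MAF 1–5%) drawn from the gene itself; the tag is
  excluded from the collapsing statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import association, metrics
from .association import DegenerateDesignError, EffectEstimate, SeparationError
from .synthetic_data import (
    GeneSpec,
    LdPairSpec,
    RARE_MAF_CEILING,
    ReplicateData,
    TraitModel,
    mask_missing,
    sample_gene_genotypes,
    sample_pair_genotypes,
    simulate_covariates,
    simulate_trait,
)

__all__ = [
    "ConfigurationError",
    "SelectionRule",
    "CalibrationRequest",
    "CovariateConfig",
    "RunConfig",
    "ReplicateRecord",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "calibrate_alpha",
]

log = logging.getLogger(__name__)

S3_TAG_MAF_RANGE = (0.01, 0.05)


class ConfigurationError(ValueError):
    """A run configuration violates a scenario definition."""


@dataclass(frozen=True)
class SelectionRule:
    """Stage-1 selection: keep replicates whose tag test is significant.

    ``one_sided_positive`` selects on a sign-consistent (positive)
    estimate with two-sided p < 2*alpha, i.e. a one-sided level-alpha
    test — used when sign flips at a weakly correlated tag make two-sided
    magnitudes misleading.
    """

    alpha: float = 0.05
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sidedness not in ("two_sided", "one_sided_positive"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")

    def is_selected(self, tag: EffectEstimate) -> bool:
        if self.sidedness == "two_sided":
            return tag.p_value < self.alpha
        return tag.estimate > 0 and tag.p_value < 2.0 * self.alpha


@dataclass(frozen=True)
class CalibrationRequest:
    """Choose the largest ladder threshold whose pilot power stays below
    the ceiling (thresholds the study actually reports: 0.05/0.01/0.001)."""

    power_ceiling: float = 0.20
    ladder: tuple[float, ...] = (0.05, 0.01, 0.001)
    pilot_replicates: Optional[int] = None
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 < self.power_ceiling < 1.0):
            raise ValueError("power_ceiling must be in (0, 1)")
        if not self.ladder:
            raise ValueError("ladder must be non-empty")


@dataclass(frozen=True)
class CovariateConfig:
    age_min: float = 20.0
    age_max: float = 80.0
    smoking_prob: float = 0.3


@dataclass(frozen=True)
class RunConfig:
    """Full generating configuration for one scenario run.

    A run is reproducible from this object plus its master seed alone;
    per-replicate seeds are derived deterministically from the master
    seed and the replicate index.
    """

    scenario: str
    n: int
    trait: TraitModel
    seed: int = 0
    replicates: int = 200
    pair: Optional[LdPairSpec] = None
    gene: Optional[GeneSpec] = None
    selection: Optional[SelectionRule] = None
    calibration: Optional[CalibrationRequest] = None
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    missing_rate: float = 0.0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scenario not in ("S1", "S2", "S3"):
            raise ConfigurationError(f"scenario must be S1/S2/S3, got {self.scenario!r}")
        if self.n < 1 or self.replicates < 1:
            raise ConfigurationError("n and replicates must be >= 1")
        if (self.selection is None) == (self.calibration is None):
            raise ConfigurationError(
                "exactly one of selection / calibration must be given"
            )
        if self.scenario == "S1":
            if self.pair is None:
                raise ConfigurationError("scenario S1 requires a tag-causal pair spec")
        else:
            if self.gene is None:
                raise ConfigurationError(f"scenario {self.scenario} requires a gene spec")
            tag_maf = self.gene.tag_maf
            if self.scenario == "S2" and tag_maf <= RARE_MAF_CEILING:
                raise ConfigurationError(
                    f"scenario S2 requires a common tag SNP (MAF > {RARE_MAF_CEILING}); "
                    f"got tag MAF {tag_maf}"
                )
            if self.scenario == "S3":
                lo, hi = S3_TAG_MAF_RANGE
                if not (lo <= tag_maf <= hi):
                    raise ConfigurationError(
                        f"scenario S3 requires tag MAF in [{lo}, {hi}]; got {tag_maf}"
                    )
                if not self.gene.exclude_tag_from_burden:
                    raise ConfigurationError(
                        "scenario S3 requires exclude_tag_from_burden=true: the tag "
                        "SNP is excluded from the collapsing statistic r_i/n_i"
                    )

    def replicate_seed(self, index: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed, spawn_key=(index,))


@dataclass
class ReplicateRecord:
    """Stage-1 and stage-2 results for one simulated data set."""

    replicate_index: int
    tag_estimate: Optional[EffectEstimate] = None
    causal_estimate: Optional[EffectEstimate] = None
    lambda_estimate: Optional[EffectEstimate] = None
    tag_burden_corr: Optional[float] = None
    selected: bool = False
    valid: bool = True
    invalid_reason: Optional[str] = None


@dataclass
class ScenarioResult:
    """All replicate records for one configured scenario run."""

    scenario: str
    records: list[ReplicateRecord]
    config: RunConfig
    rule: SelectionRule
    pilot_powers: Optional[dict[float, float]] = None

    @property
    def valid_records(self) -> list[ReplicateRecord]:
        return [r for r in self.records if r.valid]

    @property
    def n_invalid(self) -> int:
        return sum(not r.valid for r in self.records)

    @property
    def estimated_power(self) -> float:
        return metrics.estimated_power([r.selected for r in self.valid_records])

    @property
    def tag_burden_correlation(self) -> Optional[float]:
        vals = [r.tag_burden_corr for r in self.valid_records
                if r.tag_burden_corr is not None]
        return float(np.mean(vals)) if vals else None

    def estimates(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(estimates, selected) arrays over valid records; which in
        {tag, causal, lambda}."""
        attr = {"tag": "tag_estimate", "causal": "causal_estimate",
                "lambda": "lambda_estimate"}[which]
        recs = [r for r in self.valid_records if getattr(r, attr) is not None]
        est = np.array([getattr(r, attr).estimate for r in recs])
        sel = np.array([r.selected for r in recs], dtype=bool)
        return est, sel

    def bias_summary(self, which: str, magnitude: bool = False) -> metrics.BiasSummary:
        est, sel = self.estimates(which)
        return metrics.bias_summary(est, sel, magnitude=magnitude)


def _simulate_replicate_data(config: RunConfig, index: int) -> ReplicateData:
    ss = config.replicate_seed(index)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    if config.scenario == "S1":
        geno = sample_pair_genotypes(config.pair, config.n, rngs[0])
        roles = ["tag", "causal"]
        ids = ["tag", "causal"]
    else:
        geno = sample_gene_genotypes(config.gene, config.n, rngs[0])
        roles = ["tag"] + ["rare_causal"] * config.gene.n_rare
        ids = ["tag"] + [f"rare{j}" for j in range(config.gene.n_rare)]
    cov = simulate_covariates(
        config.n, rngs[1],
        age_range=(config.covariates.age_min, config.covariates.age_max),
        smoking_prob=config.covariates.smoking_prob,
    )
    data = ReplicateData(genotypes=geno, locus_roles=roles, locus_ids=ids,
                         covariates=cov)
    data.trait = simulate_trait(config.trait, data, rngs[2])
    if config.missing_rate > 0:
        data.genotypes = mask_missing(data.genotypes, config.missing_rate, rngs[3])
    return data


def _burden_columns(config: RunConfig, data: ReplicateData) -> np.ndarray:
    """Columns entering r_i/n_i: the gene's rare loci, plus the tag itself
    when it is rare and not excluded (S3 always excludes it)."""
    rare = data.columns("rare_causal")
    gene = config.gene
    if gene.tag_maf < RARE_MAF_CEILING and not gene.exclude_tag_from_burden:
        rare = np.column_stack([data.columns("tag"), rare])
    return rare


def run_replicate(
    config: RunConfig, index: int, rule: SelectionRule
) -> ReplicateRecord:
    """Simulate one data set, fit stage 1 and stage 2, mark selection.

    Degenerate replicates (monomorphic tag, no rare carriers, separated
    logistic fit) are flagged invalid with the reason recorded; they are
    excluded from summaries downstream, never silently repaired.
    """
    rec = ReplicateRecord(replicate_index=index)
    data = _simulate_replicate_data(config, index)
    trait = data.trait
    cov = data.covariates if config.trait.uses_covariates else None
    binary = config.trait.kind == "binary"
    tag = data.columns("tag")[:, 0]
    try:
        rec.tag_estimate = (
            association.additive_logistic(tag, trait)
            if binary
            else association.additive_linear(tag, trait, cov)
        )
        if config.scenario == "S1":
            causal = data.columns("causal")[:, 0]
            rec.causal_estimate = (
                association.additive_logistic(causal, trait)
                if binary
                else association.additive_linear(causal, trait, cov)
            )
        else:
            scores = association.burden_scores(_burden_columns(config, data))
            rec.lambda_estimate = association.collapsing_regression(
                scores, trait, cov, "binary" if binary else "quantitative"
            )
            rec.tag_burden_corr = metrics.tag_burden_correlation(tag, scores)
    except (DegenerateDesignError, SeparationError, ValueError) as err:
        rec.valid = False
        rec.invalid_reason = str(err)
        return rec
    rec.selected = rule.is_selected(rec.tag_estimate)
    return rec


def calibrate_alpha(
    config: RunConfig, request: Optional[CalibrationRequest] = None
) -> tuple[SelectionRule, dict[float, float]]:
    """Pick the largest ladder threshold with pilot power below the ceiling.

    Runs a pilot replicate set once, estimates power at every ladder
    threshold from the recorded tag p-values, and returns the chosen rule
    together with the per-threshold pilot powers. Fails loudly when even
    the strictest threshold leaves power at or above the ceiling.
    """
    request = request or config.calibration
    if request is None:
        raise ConfigurationError("no calibration request given")
    n_pilot = request.pilot_replicates or config.replicates
    probe = SelectionRule(alpha=min(request.ladder), sidedness=request.sidedness)
    records = [run_replicate(config, i, probe) for i in range(n_pilot)]
    valid = [r for r in records if r.valid]
    if not valid:
        raise ConfigurationError("calibration pilot produced no valid replicates")
    powers: dict[float, float] = {}
    for alpha in sorted(request.ladder, reverse=True):
        rule = SelectionRule(alpha=alpha, sidedness=request.sidedness)
        powers[alpha] = float(
            np.mean([rule.is_selected(r.tag_estimate) for r in valid])
        )
    for alpha in sorted(request.ladder, reverse=True):
        if powers[alpha] < request.power_ceiling:
            log.info("calibrated alpha=%g (pilot power %.3f)", alpha, powers[alpha])
            return SelectionRule(alpha=alpha, sidedness=request.sidedness), powers
    raise ConfigurationError(
        "no ladder threshold keeps estimated power below "
        f"{request.power_ceiling}; pilot powers: "
        + ", ".join(f"alpha={a}: {p:.3f}" for a, p in powers.items())
    )


def run_scenario(config: RunConfig) -> ScenarioResult:
    """Run all replicates of a configured scenario.

    When the config carries a calibration request instead of a fixed
    rule, the threshold ladder is calibrated first on a pilot set drawn
    from the same generating model (separate seed stream).
    """
    pilot_powers = None
    if config.selection is not None:
        rule = config.selection
    else:
        # pilot uses a shifted seed so calibration replicates are disjoint
        pilot_cfg = replace(config, seed=(config.seed + 1_000_003) % (2**31),
                            selection=SelectionRule(), calibration=None)
        rule, pilot_powers = calibrate_alpha(pilot_cfg, config.calibration)
    records = [run_replicate(config, i, rule) for i in range(config.replicates)]
    n_bad = sum(not r.valid for r in records)
    if n_bad:
        log.warning(
            "%s: %d of %d replicates degenerate and excluded from summaries",
            config.scenario, n_bad, config.replicates,
        )
    return ScenarioResult(
        scenario=config.scenario,
        records=records,
        config=config,
        rule=rule,
        pilot_powers=pilot_powers,
    )
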