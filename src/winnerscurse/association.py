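"""Single-SNP and rare-variant collapsing regressions.

Stage-1 and stage-2 effect estimation: additive linear and logistic
regression of a trait on a minor-allele-count genotype, and the
Morris–Zeggini collapsing regression of a trait on the per-individual
carrier proportion r_i/n_i, whose coefficient lambda is the effect for an
individual carrying a rare allele at every genotyped rare SNP.

All fits are complete-case (rows with any missing value dropped) and use
Wald tests from the statsmodels results objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm

__all__ = [
    "DegenerateDesignError",
    "SeparationError",
    "EffectEstimate",
    "BurdenScore",
    "additive_linear",
    "additive_logistic",
    "burden_scores",
    "collapsing_regression",
]


class DegenerateDesignError(ValueError):
    """The design matrix is rank-deficient (e.g. monomorphic genotype)."""


class SeparationError(RuntimeError):
    """Logistic fit failed: the predictor perfectly separates the classes."""


@dataclass(frozen=True)
class EffectEstimate:
    """A fitted genetic effect: point estimate, SE, Wald statistic, p-value."""

    estimate: float
    std_error: float
    p_value: float
    statistic: float
    n_used: int


@dataclass(frozen=True)
class BurdenScore:
    """Per-individual rare-variant summary: score = r_i / n_i.

    r_i counts rare loci where the individual carries at least one minor
    allele; n_i counts rare loci with a non-missing genotype. The score is
    NaN (and flagged in ``defined``) where n_i = 0.
    """

    score: np.ndarray
    r: np.ndarray
    n: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.n > 0


def _complete_rows(*arrays: Optional[np.ndarray]) -> np.ndarray:
    mask = None
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        ok = ~np.isnan(a) if a.ndim == 1 else ~np.isnan(a).any(axis=1)
        mask = ok if mask is None else (mask & ok)
    return mask


def _design(x: np.ndarray, covariates: Optional[np.ndarray]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cols.append(cov if cov.ndim == 2 else cov[:, None])
    return np.column_stack(cols)


def _check_fit_preconditions(x: np.ndarray, n_params: int, what: str) -> None:
    if x.size - n_params < 3:
        raise ValueError(
            f"{what}: need at least {n_params + 3} complete observations, "
            f"have {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDesignError(
            f"{what}: predictor is constant (monomorphic / zero-variance); "
            "the effect is not estimable"
        )


def _linear_fit(
    x: np.ndarray, y: np.ndarray, covariates: Optional[np.ndarray], what: str
) -> EffectEstimate:
    mask = _complete_rows(x, y, covariates)
    x, y = np.asarray(x, float)[mask], np.asarray(y, float)[mask]
    cov = None if covariates is None else np.asarray(covariates, float)[mask]
    X = _design(x, cov)
    _check_fit_preconditions(x, X.shape[1], what)
    res = sm.OLS(y, X).fit()
    return EffectEstimate(
        estimate=float(res.params[1]),
        std_error=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        statistic=float(res.tvalues[1]),
        n_used=int(mask.sum()),
    )


def additive_linear(
    genotype: np.ndarray,
    trait: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> EffectEstimate:
    """OLS of a quantitative trait on a 0/1/2 genotype (plus covariates).

    The estimate is the genotype coefficient — trait units per minor
    allele — with its Wald (t) p-value. Rows with any missing value are
    dropped; a monomorphic genotype raises ``DegenerateDesignError``.
    """
    return _linear_fit(genotype, trait, covariates, "additive_linear")


def additive_logistic(genotype: np.ndarray, status: np.ndarray) -> EffectEstimate:
    """ML logistic regression of binary status on genotype, with intercept.

    The estimate is the log-odds per minor allele. Complete separation is
    detected and raised as ``SeparationError`` rather than returned as a
    spuriously finite estimate.
    """
    mask = _complete_rows(genotype, status)
    x = np.asarray(genotype, float)[mask]
    y = np.asarray(status, float)[mask]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("status must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("additive_logistic: both classes must be present")
    X = _design(x, None)
    _check_fit_preconditions(x, 2, "additive_logistic")
    _check_separation(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception as err:  # statsmodels raises on perfect prediction
            raise SeparationError(f"logistic fit failed: {err}") from err
    if not res.mle_retvals.get("converged", True) or not np.isfinite(res.bse[1]):
        raise SeparationError(
            "logistic fit did not converge (quasi-separation suspected)"
        )
    return EffectEstimate(
        estimate=float(res.params[1]),
        std_error=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        statistic=float(res.tvalues[1]),
        n_used=int(mask.sum()),
    )


def _check_separation(x: np.ndarray, y: np.ndarray) -> None:
    """Raise when a threshold on x perfectly predicts y (complete separation)."""
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        raise SeparationError(
            "complete separation: genotype perfectly predicts case status"
        )


def burden_scores(rare_genotypes: np.ndarray, count_alleles: bool = False) -> BurdenScore:
    """Collapse an n x L rare-genotype matrix to per-individual scores.

    By default r_i counts loci at which the individual carries at least
    one minor allele (carrier indicator per locus). With
    ``count_alleles=True`` r_i sums minor-allele counts instead, an
    alternative some collapsing analyses use; it is not the default.
    Missing genotypes (NaN) are excluded from both r_i and n_i.
    """
    g = np.atleast_2d(np.asarray(rare_genotypes, dtype=float))
    if g.shape[1] < 1:
        raise ValueError("burden_scores needs at least one rare locus")
    observed = ~np.isnan(g)
    contrib = np.where(observed, g if count_alleles else (g >= 1), 0.0)
    r = contrib.sum(axis=1)
    n = observed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        score = np.where(n > 0, r / np.maximum(n, 1), np.nan)
    return BurdenScore(score=score, r=r, n=n)


def collapsing_regression(
    scores: BurdenScore,
    trait: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    trait_kind: str = "quantitative",
) -> EffectEstimate:
    """Regress the trait on r_i/n_i; the coefficient is lambda-hat.

    Individuals with no genotyped rare locus (n_i = 0) are excluded.
    ``trait_kind`` selects a linear (quantitative) or logistic (binary)
    model.
    """
    x = scores.score if isinstance(scores, BurdenScore) else np.asarray(scores, float)
    if trait_kind == "quantitative":
        return _linear_fit(x, trait, covariates, "collapsing_regression")
    if trait_kind == "binary":
        mask = _complete_rows(x, trait)
        return additive_logistic(np.asarray(x, float)[mask],
                                 np.asarray(trait, float)[mask])
    raise ValueError(f"trait_kind must be quantitative or binary, got {trait_kind!r}")
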