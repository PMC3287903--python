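"""Summary measures for two-stage selection bias.

Estimated power, conditional and unconditional mean effect estimates,
signed relative bias, the tag-SNP attenuation factor gamma_tc, the
tag–burden correlation, and an analytic truncated-normal account of the
winner's curse used as an oracle for the simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import numpy as np
from scipy import stats

from .synthetic_data import _check_rho, rho_max  # noqa: F401  (re-export bound)

__all__ = [
    "BiasSummary",
    "estimated_power",
    "bias_summary",
    "gamma_tc",
    "tag_burden_correlation",
    "truncnorm_conditional_mean",
    "TruncatedNormalSelection",
]

#: |mean over all replicates| must exceed this multiple of the estimate SD
#: for the relative-bias ratio to be reported (division-by-noise guard).
RELATIVE_BIAS_FLOOR = 1e-3


@dataclass(frozen=True)
class BiasSummary:
    """Selection-bias summary for one estimate across replicates.

    ``relative_bias_pct`` is signed: 100 * (mean_selected - mean_all) /
    mean_all. It is NaN when no replicate was selected or when |mean_all|
    falls below the stability floor; both means are still reported.
    """

    mean_all: float
    mean_selected: float
    relative_bias_pct: float
    estimated_power: float
    n_all: int
    n_selected: int


def _as_arrays(estimates, selected):
    est = np.asarray(estimates, dtype=float)
    sel = np.asarray(selected, dtype=bool)
    if est.shape != sel.shape:
        raise ValueError("estimates and selected must have equal length")
    ok = ~np.isnan(est)
    return est[ok], sel[ok]


def estimated_power(selected: Iterable[bool]) -> float:
    """Proportion of valid replicates in which the stage-1 test was significant."""
    sel = np.asarray(list(selected), dtype=bool)
    if sel.size == 0:
        raise ValueError("estimated_power needs at least one valid replicate")
    return float(sel.mean())


def bias_summary(
    estimates: Iterable[float],
    selected: Iterable[bool],
    magnitude: bool = False,
) -> BiasSummary:
    """Conditional vs unconditional mean estimate and signed relative bias.

    ``magnitude=True`` summarises |estimate| instead — useful when sign
    flips around the null make the signed mean misleading (the situation
    that motivates one-sided selection at an uncorrelated tag).
    """
    est, sel = _as_arrays(list(estimates), list(selected))
    if est.size == 0:
        raise ValueError("bias_summary needs at least one valid estimate")
    if magnitude:
        est = np.abs(est)
    mean_all = float(est.mean())
    n_sel = int(sel.sum())
    mean_sel = float(est[sel].mean()) if n_sel else float("nan")
    sd = float(est.std(ddof=1)) if est.size > 1 else 0.0
    if n_sel == 0 or abs(mean_all) <= RELATIVE_BIAS_FLOOR * sd:
        rel = float("nan")
    else:
        rel = 100.0 * (mean_sel - mean_all) / mean_all
    return BiasSummary(
        mean_all=mean_all,
        mean_selected=mean_sel,
        relative_bias_pct=rel,
        estimated_power=float(sel.mean()),
        n_all=int(est.size),
        n_selected=n_sel,
    )


def gamma_tc(p_t: float, p_c: float, rho_tc: float) -> float:
    """Attenuation factor relating the expected tag-SNP slope to the causal effect.

    Under the additive model the expected OLS slope at the tag SNP is
    gamma_tc * beta_causal with

        gamma_tc = rho_TC * sqrt( p_C (1 - p_C) / ( p_T (1 - p_T) ) ).

    It is 0 when tag and causal SNPs are independent and 1 when the tag
    SNP is the causal SNP itself.
    """
    _check_rho(p_t, p_c, rho_tc, "gamma_tc")
    return float(
        rho_tc * np.sqrt(p_c * (1.0 - p_c) / (p_t * (1.0 - p_t)))
    )


def tag_burden_correlation(
    tag_genotypes: np.ndarray, scores: np.ndarray
) -> float:
    """Sample Pearson correlation between tag genotype and r_i/n_i.

    Pairs with a missing tag genotype or an undefined score are dropped;
    at least 3 complete, non-constant pairs are required.
    """
    t = np.asarray(tag_genotypes, dtype=float)
    s = np.asarray(getattr(scores, "score", scores), dtype=float)
    ok = ~np.isnan(t) & ~np.isnan(s)
    t, s = t[ok], s[ok]
    if t.size < 3:
        raise ValueError("tag_burden_correlation needs >= 3 complete pairs")
    if np.ptp(t) == 0 or np.ptp(s) == 0:
        raise ValueError("tag_burden_correlation: constant input")
    return float(stats.pearsonr(t, s).statistic)


class TruncatedNormalSelection(NamedTuple):
    """Conditional mean of the test statistic given selection, and the
    selection probability (analytic power)."""

    conditional_mean: float
    selection_probability: float


def truncnorm_conditional_mean(
    mu: float, c: float, sidedness: str = "two_sided"
) -> TruncatedNormalSelection:
    """Winner's-curse oracle under the normal approximation.

    For Z ~ Normal(mu, 1) and critical value c > 0:

    * two_sided — selection event |Z| > c;
      E[Z | |Z| > c] = mu + (phi(c - mu) - phi(c + mu)) / P with
      P = Phi(mu - c) + Phi(-mu - c);
    * one_sided_positive — selection event Z > c;
      E[Z | Z > c] = mu + phi(c - mu) / Phi(mu - c).

    Returns both the conditional mean and the selection probability.
    """
    if not c > 0:
        raise ValueError("critical value c must be > 0")
    phi, Phi = stats.norm.pdf, stats.norm.cdf
    if sidedness == "two_sided":
        p = Phi(mu - c) + Phi(-mu - c)
        mean = mu + (phi(c - mu) - phi(c + mu)) / p
    elif sidedness == "one_sided_positive":
        p = Phi(mu - c)
        mean = mu + phi(c - mu) / p
    else:
        raise ValueError(
            "sidedness must be two_sided or one_sided_positive, got "
            f"{sidedness!r}"
        )
    return TruncatedNormalSelection(float(mean), float(p))
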