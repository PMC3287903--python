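#!/usr/bin/env python
"""Scenario 1: common tag SNP, common causal SNP.

One quantitative (Q2-like, no covariates) trait driven by a single common
causal SNP (MAF 0.30, beta 0.20, sigma 1); n = 616 individuals, 200
replicate data sets per tag. A ladder of tag SNPs with haplotype
correlation rho in {0, 0.3, 0.5, 0.7, 0.9, 1.0} to the causal SNP spans
the attenuation factor gamma_TC from 0 (uncorrelated tag) to 1 (the
causal SNP as its own tag). Stage-1 selection keeps replicates with a
significant additive tag test at p < 0.05 (one-sided alpha = 0.025 for
the uncorrelated tag, where sign flips make two-sided magnitudes
misleading).

Expected pattern: the unconditional tag estimate grows with gamma_TC
(attenuation), while selection inflates the conditional estimates most
where power is low; at rho = 0 none of the tag-level bias carries through
to the causal SNP, and at rho = 1 power is high and bias minimal.

Writes results/scenario1_summary.csv and per-tag long-format distribution
exports (four groups per tag: causal/all, tag/all, tag/selected,
causal/selected) for boxplotting.
"""

from pathlib import Path

import pandas as pd

import winnerscurse as wc
from winnerscurse import cli_io, metrics

OUT = Path(__file__).resolve().parents[1] / "results"

N, REPLICATES, SEED = 616, 200, 20111129
P_CAUSAL = 0.30
BETA, SIGMA = 0.20, 1.0
RHO_LADDER = (0.0, 0.3, 0.5, 0.7, 0.9, 1.0)


def run_tag(rho: float) -> wc.ScenarioResult:
    one_sided = rho == 0.0
    return wc.run_scenario(wc.RunConfig(
        scenario="S1", n=N, seed=SEED + int(rho * 100), replicates=REPLICATES,
        pair=wc.LdPairSpec(P_CAUSAL, P_CAUSAL, rho),
        trait=wc.TraitModel(kind="quantitative", beta=BETA, sigma=SIGMA),
        selection=wc.SelectionRule(
            alpha=0.025 if one_sided else 0.05,
            sidedness="one_sided_positive" if one_sided else "two_sided",
        ),
    ))


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows, results = [], []
    for rho in RHO_LADDER:
        res = run_tag(rho)
        results.append(res)
        gamma = metrics.gamma_tc(P_CAUSAL, P_CAUSAL, rho)
        row = cli_io.summary_row(res)
        row["rho_tc"] = rho
        row["gamma_tc"] = round(gamma, 3)
        rows.append(row)
        cli_io.write_distributions(
            res, OUT / f"scenario1_distributions_rho{rho:.1f}.csv"
        )
        print(
            f"rho={rho:3.1f} gamma={gamma:4.2f} power={row['estimated_power']} "
            f"tag all/sel={row['tag_mean_all']}/{row['tag_mean_selected']} "
            f"(bias {row['tag_relative_bias_pct']}%) "
            f"causal all/sel={row['stage2_mean_all']}/{row['stage2_mean_selected']} "
            f"(bias {row['stage2_relative_bias_pct']}%)"
        )
    pd.DataFrame(rows).to_csv(OUT / "scenario1_summary.csv", index=False)

    tag_means = [float(r["tag_mean_all"]) for r in rows]
    print("\nFindings:")
    print(f"- unconditional tag estimates rise with gamma_TC: "
          f"{tag_means[0]:.2f} -> {tag_means[-1]:.2f} (attenuation)")
    print("- selection inflates tag estimates most where power is low "
          "(small gamma_TC); at rho=1 power is high and bias is small")
    print("- at rho=0 the causal-SNP conditional mean stays at its "
          "unconditional value: tag-level bias does not carry through")
    print("  (the rho=0 tag's signed bias ratio divides by a near-zero null "
          "mean and is not interpretable; the conditional/unconditional "
          "means themselves tell the story)")
    print(f"\nWrote {OUT / 'scenario1_summary.csv'} and per-tag distribution "
          "exports.")


if __name__ == "__main__":
    main()
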