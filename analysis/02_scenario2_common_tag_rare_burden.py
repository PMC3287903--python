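#!/usr/bin/env python
"""Scenario 2: common tag SNP, multiple rare causal SNPs in one gene.

A gene of 10 rare causal SNPs (MAF 0.02 each) drives a quantitative trait
through the collapsing model (lambda_true = 2 per unit of the carrier
proportion r_i/n_i, sigma = 1); n = 697 individuals, 200 replicates. A
common tag SNP (MAF 0.20) is correlated with every rare SNP on
haplotypes (rho = 0.10 per pair), giving a tag–burden correlation around
0.3–0.4, the regime where a common SNP weakly tags a rare-variant
burden. The significance threshold is calibrated on the ladder
{0.05, 0.01, 0.001} so that estimated stage-1 power stays below 20%.

Expected pattern: the mean tag estimate over selected replicates is
strongly inflated relative to all replicates, while lambda-hat at the
collapsing statistic is biased to a lesser degree — imperfect correlation
transfers only part of the tag-level selection bias.

Writes results/scenario2_summary.csv.
"""

from pathlib import Path

import pandas as pd

import winnerscurse as wc
from winnerscurse import cli_io

OUT = Path(__file__).resolve().parents[1] / "results"

N, REPLICATES, SEED = 697, 200, 20111202
GENE = wc.GeneSpec(tag_maf=0.20, rare_mafs=(0.02,) * 10,
                   tag_rare_rho=(0.10,) * 10)
LAMBDA_TRUE = 2.0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = wc.RunConfig(
        scenario="S2", n=N, seed=SEED, replicates=REPLICATES, gene=GENE,
        trait=wc.TraitModel(kind="quantitative", lambda_true=LAMBDA_TRUE,
                            sigma=1.0),
        calibration=wc.CalibrationRequest(power_ceiling=0.20),
    )
    res = wc.run_scenario(config)
    row = cli_io.summary_row(res)
    row["lambda_true"] = LAMBDA_TRUE
    pd.DataFrame([row]).to_csv(OUT / "scenario2_summary.csv", index=False)
    cli_io.write_records(res, OUT / "scenario2_records.csv")

    print(f"calibrated threshold: alpha={res.rule.alpha} "
          f"(pilot powers {res.pilot_powers})")
    print(f"estimated power: {row['estimated_power']}")
    print(f"tag estimate  all/selected: {row['tag_mean_all']}/"
          f"{row['tag_mean_selected']} (relative bias "
          f"{row['tag_relative_bias_pct']}%)")
    print(f"tag-burden correlation: {row['tag_burden_correlation']}")
    print(f"lambda-hat    all/selected: {row['stage2_mean_all']}/"
          f"{row['stage2_mean_selected']} (relative bias "
          f"{row['stage2_relative_bias_pct']}%; lambda_true={LAMBDA_TRUE})")
    print("\nFinding: selection at the weakly-correlated common tag inflates "
          "the tag estimate far more than the collapsing-statistic estimate; "
          "part, but not all, of the winner's curse transfers to stage 2.")


if __name__ == "__main__":
    main()
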