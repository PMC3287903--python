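#!/usr/bin/env python
"""Scenario 3: low-MAF tag SNP (1–5%), multiple rare causal SNPs.

The tag SNP is itself a low-frequency variant from the causal gene (MAF
0.03) and is excluded from the collapsing statistic r_i/n_i. Because two
SNPs with similar MAFs have a higher LD ceiling, a rare tag can reach a
much larger tag–burden correlation than the common tags of scenario 2:
here rho = 0.40 per tag–rare pair (8 rare SNPs, MAF 0.02 each) gives a
tag–burden correlation near 0.8. The trait follows the collapsing model
with lambda_true = 0.6 and the threshold is calibrated for power < 20%.

Expected pattern: bias at the tag is severe when power is low, and — with
the higher correlation — a much larger share of the tag-level selection
bias carries through to lambda-hat than in scenario 2.

Writes results/scenario3_summary.csv.
"""

from pathlib import Path

import pandas as pd

import winnerscurse as wc
from winnerscurse import cli_io

OUT = Path(__file__).resolve().parents[1] / "results"

N, REPLICATES, SEED = 697, 200, 20111203
GENE = wc.GeneSpec(tag_maf=0.03, rare_mafs=(0.02,) * 8,
                   tag_rare_rho=(0.40,) * 8, exclude_tag_from_burden=True)
LAMBDA_TRUE = 0.6


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = wc.RunConfig(
        scenario="S3", n=N, seed=SEED, replicates=REPLICATES, gene=GENE,
        trait=wc.TraitModel(kind="quantitative", lambda_true=LAMBDA_TRUE,
                            sigma=1.0),
        calibration=wc.CalibrationRequest(power_ceiling=0.20),
    )
    res = wc.run_scenario(config)
    row = cli_io.summary_row(res)
    row["lambda_true"] = LAMBDA_TRUE
    pd.DataFrame([row]).to_csv(OUT / "scenario3_summary.csv", index=False)
    cli_io.write_records(res, OUT / "scenario3_records.csv")

    print(f"calibrated threshold: alpha={res.rule.alpha} "
          f"(pilot powers {res.pilot_powers})")
    print(f"estimated power: {row['estimated_power']}")
    print(f"tag estimate  all/selected: {row['tag_mean_all']}/"
          f"{row['tag_mean_selected']} (relative bias "
          f"{row['tag_relative_bias_pct']}%)")
    print(f"tag-burden correlation: {row['tag_burden_correlation']} "
          "(vs ~0.3 for the common tag of scenario 2)")
    print(f"lambda-hat    all/selected: {row['stage2_mean_all']}/"
          f"{row['stage2_mean_selected']} (relative bias "
          f"{row['stage2_relative_bias_pct']}%; lambda_true={LAMBDA_TRUE})")
    print("\nFinding: the low-MAF tag achieves a far higher correlation with "
          "the rare-variant burden, so more of the winner's curse is "
          "transferred to the stage-2 collapsing estimate than with a "
          "common tag.")


if __name__ == "__main__":
    main()
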