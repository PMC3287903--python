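# Scenario 3: low-MAF tag SNP (MAF 0.03, itself in the causal gene but
# excluded from the collapsing statistic) strongly correlated with 8 rare
# causal SNPs; threshold calibrated for stage-1 power < 20%.
scenario: S3
n: 697
replicates: 200
seed: 1
gene:
  tag_maf: 0.03
  rare_mafs: [0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02]
  tag_rare_rho: [0.40, 0.40, 0.40, 0.40, 0.40, 0.40, 0.40, 0.40]
  exclude_tag_from_burden: true
trait: {kind: quantitative, lambda_true: 0.6, sigma: 1.0}
calibration: {power_ceiling: 0.20, ladder: [0.05, 0.01, 0.001]}
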