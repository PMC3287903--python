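# Scenario 2: common tag SNP (MAF 0.20) weakly correlated with 10 rare
# causal SNPs (MAF 0.02) whose burden r_i/n_i drives the trait; the
# selection threshold is calibrated on the ladder so stage-1 power < 20%.
scenario: S2
n: 697
replicates: 200
seed: 1
gene:
  tag_maf: 0.20
  rare_mafs: [0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02]
  tag_rare_rho: [0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10]
trait: {kind: quantitative, lambda_true: 2.0, sigma: 1.0}
calibration: {power_ceiling: 0.20, ladder: [0.05, 0.01, 0.001]}
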