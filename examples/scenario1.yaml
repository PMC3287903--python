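# Scenario 1: common tag SNP (MAF 0.30) in LD (rho 0.5) with a common
# causal SNP driving a Q2-like quantitative trait; two-sided selection
# at p < 0.05 over 200 replicates of n = 616.
scenario: S1
n: 616
replicates: 200
seed: 1
pair: {p_t: 0.30, p_c: 0.30, rho_tc: 0.5}
trait: {kind: quantitative, beta: 0.20, sigma: 1.0}
selection: {alpha: 0.05, sidedness: two_sided}
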