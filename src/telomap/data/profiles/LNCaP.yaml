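# Telomerase-positive prostate cancer line; 0.4% of telomeres exceed 15 kb
# and the longest reported telomere is 23.5 kb, so the super-long tail
# component is short-ranged compared to the ALT+ lines.
name: LNCaP
frac_its_plus: 0.0
frac_its_minus: 0.0
frac_tfe: 0.0
ectr_per_100_molecules: 0.0
mean_molecules_per_arm: 30
frac_telomeres_gt_15kb: 0.004
endtel_len: {body_mean_kb: 3.2, body_sd_kb: 2.1, tail_median_kb: 16.0, tail_sigma: 0.25}
its_plus_len: {body_mean_kb: 2.0, body_sd_kb: 1.0}
ectr_len: {body_mean_kb: 11.0, body_sd_kb: 8.0}
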