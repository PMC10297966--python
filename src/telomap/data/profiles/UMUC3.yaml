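# Telomerase-positive bladder cancer line: no fusions, no TFEs, no ECTRs,
# and no telomeres above 15 kb were reported (longest 14.75 kb).  The
# end-telomere dispersion follows the line's reported CV of 0.8 (sd =
# 0.8 x 3.1 kb); the table's sd entry (2.8) is inconsistent with both
# that CV and the absence of super-long telomeres under a lognormal body.
name: UMUC3
frac_its_plus: 0.0
frac_its_minus: 0.0
frac_tfe: 0.0
ectr_per_100_molecules: 0.0
mean_molecules_per_arm: 30
frac_telomeres_gt_15kb: 0.0
endtel_len: {body_mean_kb: 3.1, body_sd_kb: 2.5, tail_median_kb: 16.0, tail_sigma: 0.25}
its_plus_len: {body_mean_kb: 2.0, body_sd_kb: 1.0}
ectr_len: {body_mean_kb: 11.0, body_sd_kb: 8.0}
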