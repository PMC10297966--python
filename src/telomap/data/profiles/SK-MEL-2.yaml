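# ALT+ melanoma line; 1.0% of measured telomeres exceed 15 kb (the
# lognormal body already carries more mass than that, so the calibrated
# tail weight is 0).
name: SK-MEL-2
frac_its_plus: 0.086
frac_its_minus: 0.005
frac_tfe: 0.076
ectr_per_100_molecules: 15.0
mean_molecules_per_arm: 30
frac_telomeres_gt_15kb: 0.010
endtel_len: {body_mean_kb: 3.5, body_sd_kb: 3.9}
its_plus_len: {body_mean_kb: 3.7, body_sd_kb: 3.4}
ectr_len: {body_mean_kb: 11.0, body_sd_kb: 8.0}
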