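# ALT+ osteosarcoma line; 4.3% of measured telomeres exceed 15 kb.
name: Saos-2
frac_its_plus: 0.176
frac_its_minus: 0.005
frac_tfe: 0.063
ectr_per_100_molecules: 15.0
mean_molecules_per_arm: 30
frac_telomeres_gt_15kb: 0.043
endtel_len: {body_mean_kb: 4.5, body_sd_kb: 5.6}
its_plus_len: {body_mean_kb: 2.7, body_sd_kb: 3.6}
ectr_len: {body_mean_kb: 11.0, body_sd_kb: 8.0}
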