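# ALT+ osteosarcoma line.  Category percentages and mean +/- sd telomere
# lengths transcribe the published genome-wide readout table; 4.1% of
# measured telomeres exceed 15 kb.
name: U2OS
frac_its_plus: 0.231
frac_its_minus: 0.122
frac_tfe: 0.064
ectr_per_100_molecules: 15.0
mean_molecules_per_arm: 30
frac_telomeres_gt_15kb: 0.041
endtel_len: {body_mean_kb: 5.0, body_sd_kb: 2.2}
its_plus_len: {body_mean_kb: 1.8, body_sd_kb: 3.3}
ectr_len: {body_mean_kb: 11.0, body_sd_kb: 8.0}
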