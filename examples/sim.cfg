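# example simulation config: four stages, coupling switched off at the last
n_genes = 2000
stages = s11,s13,egg,gast
coupling_beta = 1.2,1.2,1.2,0.0
depth_rna = 2000000
depth_rpf = 2000000
depth_tags = 600000
noise_sd_log2te = 0.5
seed = 7
genotypes = wispy,png,smg
png.n_up = 30
png.n_down = 40
profile_classes = 0|1|2|1:0.1:1.0
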