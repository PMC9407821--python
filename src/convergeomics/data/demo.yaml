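# Demo configuration: a compact synthetic study emulating the target design --
# two focal herbivore species vs a non-herbivore panel, two tissues, planted
# convergent expression shifts (|log2FC| = 2) and promoter methylation shifts
# (delta = 0.3) placed so that inverse methylation-expression pairs exist.
tissues: [stomach, small_intestine]
n_genes: 800
focal_species: [giant_panda, red_panda]
outgroup_species: [ferret, dog, mouse]
n_convergent_up: 80
n_convergent_down: 80
effect_log2fc: 2.0
nb_dispersion: 0.1
library_size_range: [800000, 1200000]
gene_length_range: [500, 2000]
n_hypo_promoters: 80
n_hyper_promoters: 80
meth_delta: 0.3
baseline_promoter_meth: 0.1
baseline_body_meth: 0.8
beta_precision: 50.0
read_depth_mean: 10.0
cpg_per_promoter: 20
cg_only_reports: true
seed: 20220814
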