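# Example olfnet run configuration: `olfnet all --config run.yaml`
# Every key is optional; unknown keys are rejected.

seed: 7
out_dir: olfnet_run
stages: [synth, behavior, integrate, couple, brainblood]

# --- synthetic cohort -------------------------------------------------------
n_subjects: 120          # desk-scale default; the published behavioral cohort is 465
use_published_cohort: false  # true -> exact published cell counts (465 subjects)
n_regions: 40            # full atlas is 332 regions
n_genes: 600
eigengene_metric_r: -0.5 # planted module-diffusivity coupling (strongest reported scale)
latent_loading: 0.6      # shared cross-domain factor strength
latent_edges: 20

# --- behavior stage ---------------------------------------------------------
anova_factors: [apoe, diet, age_group]  # full 5-factor design needs the 465-subject cohort

# --- elastic net ------------------------------------------------------------
en_alpha: 0.5            # L1/L2 mixing weight, the published setting
en_folds: 10             # cross-validation folds, the published setting

# --- MCCA inference ---------------------------------------------------------
boot_b: 1000             # bootstrap draws, the published setting
perm_p: 2000             # permutation draws
weight_threshold: 0.05   # subnetwork edge-weight cutoff, the published setting
mcca_method: sumcor      # or maxvar

# --- coupling / enrichment --------------------------------------------------
blood_k: 10              # blood eigengenes, the published setting
brain_k: 4               # per-region components, the published setting
fdr_level: 0.05
top_regions_k: 5
# gmt: path/to/gene_sets.gmt   # defaults to the generated toy collection
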