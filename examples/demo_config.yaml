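# Demo pipeline configuration: desk-scale synthetic run of every stage.
# Usage: nanoliver pipeline --config examples/demo_config.yaml -o demo_run/
seed: 1
genome:
  length: 20000
  gc_fraction: 0.45
  n_promoters: 4
methylome:
  promoter_open_prob: 0.85
  background_open_prob: 0.15
  cpg_meth_prob: 0.7
calls:
  coverage: 12
  llr_mean_effect: 4.0
  llr_sd: 1.0
  contamination_fraction: 0.05
  read_length: 4000
  threshold: 2.0
  min_coverage: 4
  flank: 1500
insertions:
  n_loci: 3
  support_per_locus: 4
  n_native_reads: 2
  n_background_reads: 8
  min_dual_len: 30
  cluster_radius: 50
  min_support: 2
bulk:
  n_genes: 1500
  n_samples_per_group: 3
  de_fraction: 0.1
  lfc_scale: 3.0
  dispersion_scale: 0.05
  n_perm: 200
sc:
  n_cells: 400
  lowq_fraction: 0.1
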