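# Demo: three planted TGFB1 → … → CTGF regulatory paths hidden among
# 20 decoy genes, plus a synthetic qPCR experiment and serum cohort.
seed: 7
output_dir: demo_out
synthetic:
  network:
    planted_paths:
      - [TGFB1, TFX1, miR-378a-3p, CTGF]
      - [TGFB1, SMAD3, TFX2, miR-378a-3p, CTGF]
      - [TGFB1, TFX1, miR-30b, CTGF]
    n_decoy_genes: 20
    n_tfs: 3
    n_mirnas: 2
    ppi_edge_prob: 0.1
    node_types:
      TFX1: TF
      TFX2: TF
  qpcr:
    genes: [TGFB1, miR-378a-3p, CTGF, GAPDH]
    fold_changes:
      OM:
        TGFB1: 0.42
        miR-378a-3p: 0.68
        CTGF: 0.58
    reference_gene: GAPDH
    control_group: control
    n_replicates: 6
    ct_noise_sd: 0.25
  cohort: default
consensus:
  min_tools: 3
search:
  max_depth: 4
  edge_types: [ppi, tf_mirna, mirna_target]
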