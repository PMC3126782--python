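# Synthetic six-library design at desk scale.
seed: 1
max_mismatches: 3
weighting: equal
trim:
  five_prime: 4
  three_prime: 12
policy:
  alpha: 0.05
  fold_threshold: 2.0
  pseudo_rpkm: 0.10
comparisons:
  - [FA, FB]
  - [FP, FB]
  - [MA, MB]
  - [MP, MB]
simulate:
  n_genes: 200
  n_paralog_families: 5
  paralog_divergence: 0.05
  isoforms_per_gene: 1
  transcript_length_range: [200, 1500]
  base_expression: [0.0, 1.0]
  library_size: 20000
  read_length: 43
  error_rate: 0.005
  enhanced_design:
    FA: {10: 8.0, 11: 8.0, 12: 8.0, 13: 4.0, 14: 4.0}
    FP: {20: 8.0, 21: 8.0}
    MA: {10: 4.0, 11: 4.0, 30: 8.0}
    MP: {20: 4.0, 31: 8.0}
  family_design:
    Or: [10, 11, 12]
    Ir: [13, 14]
    Gr: [30, 31]
    Obp: [20, 21]
  pfam_design:
    PF02949: [10, 11, 12]
    PF00060: [13, 14]
    PF08395: [30, 31]
    PF01395: [20, 21]
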