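# Minimal three-species panel with two planted events, for fast tests.
name: small3
species: [Ca, Ma, Mb]
clades:
  all: [Ca, Ma, Mb]
  pair: [Ma, Mb]
species_tree: "(Ca,(Ma,Mb));"
scaffolds_per_species: 3
genes_per_scaffold: 12
flank_width: 5
background_share_prob: 0.7
evalue:
  native_meta: [1.0e-180, 1.0e-20]
  native_nonmeta_prob: 0.3
  native_nonmeta: [1.0e-3, 1.0]
  hgt_nonmeta: [1.0e-180, 1.0e-50]
  hgt_meta_prob: 0.5
  hgt_meta: [1.0e-3, 1.0]
contaminants_per_species: 0
events:
  - id: evA
    node: all
    copies: {Ca: 1, Ma: 1, Mb: 1}
    intronless: 2
    donor: Bacillus_subtilis
  - id: evB
    node: pair
    copies: {Ma: 2, Mb: 1}
    intronless: 1
    donor: Escherichia_coli
ablate_flanks: []
te:
  n_shared_families: 3
  n_unique_per_species: 1
  seq_len: [300, 600]
  divergence: 0.10
expression:
  samples: [embryo, adult]
  expressed_events: [evA]
  biased_samples: [adult]
  background_genes: 10
alignment:
  length: 200
  n_donor: 4
  n_metazoan: 4
regression:
  slope: 2.0
  intercept: 130.0
  noise_sd: 60.0
  te_mb_range: [20, 1500]
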