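# Nine-species myriapod-like panel: four centipede-like and five
# millipede-like genomes, with eleven HGT events planted at the clade nodes
# (1 all-millipede, 7 helminthomorph, 2 all-centipede, 1 pleurostigmomorph),
# 65 member genes in total, 32 of them intron-less.
name: myriapod9
species: [Ttu, Lni, Rim, Sma, Emi, Tco, Ato, Nno, Hho]
clades:
  centipedes: [Ttu, Lni, Rim, Sma]
  pleurostigmomorphs: [Lni, Rim, Sma]
  millipedes: [Emi, Tco, Ato, Nno, Hho]
  helminthomorphs: [Tco, Ato, Nno, Hho]
species_tree: "((Ttu,(Lni,(Rim,Sma))),(Emi,(Tco,(Ato,(Nno,Hho)))));"
scaffolds_per_species: 5
genes_per_scaffold: 30
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
  - id: ev01_rnd_efflux
    node: millipedes
    copies: {Emi: 1, Tco: 1, Ato: 1, Nno: 1, Hho: 1}
    intronless: 0
    donor: Pseudomonas_putida
  - id: ev02_nadh_oxidoreductase
    node: helminthomorphs
    copies: {Tco: 2, Ato: 2, Nno: 2, Hho: 1}
    intronless: 4
    donor: Bacillus_subtilis
  - id: ev03_azld_domain
    node: helminthomorphs
    copies: {Tco: 2, Ato: 2, Nno: 1, Hho: 2}
    intronless: 4
    donor: Streptomyces_griseus
  - id: ev04_sulfatase_maturase
    node: helminthomorphs
    copies: {Tco: 1, Ato: 2, Nno: 2, Hho: 2}
    intronless: 4
    donor: Clostridium_acetobutylicum
  - id: ev05_a2m
    node: helminthomorphs
    copies: {Tco: 2, Ato: 1, Nno: 2, Hho: 2}
    intronless: 4
    donor: Escherichia_coli
  - id: ev06_sylf_domain
    node: helminthomorphs
    copies: {Tco: 2, Ato: 2, Nno: 2, Hho: 1}
    intronless: 4
    donor: Vibrio_cholerae
  - id: ev07_gh16_a
    node: helminthomorphs
    copies: {Tco: 2, Ato: 1, Nno: 2, Hho: 2}
    intronless: 4
    donor: Flavobacterium_johnsoniae
  - id: ev08_gh16_b
    node: helminthomorphs
    copies: {Tco: 1, Ato: 2, Nno: 2, Hho: 2}
    intronless: 4
    donor: Cellulophaga_lytica
  - id: ev09_gdh_a
    node: centipedes
    copies: {Ttu: 1, Lni: 1, Rim: 1, Sma: 1}
    intronless: 2
    donor: Pseudomonas_fluorescens
  - id: ev10_nrps
    node: centipedes
    copies: {Ttu: 1, Lni: 1, Rim: 1, Sma: 1}
    intronless: 2
    donor: Streptomyces_coelicolor
  - id: ev11_gdh_b
    node: pleurostigmomorphs
    copies: {Lni: 1, Rim: 1, Sma: 1}
    intronless: 0
    donor: Pseudomonas_aeruginosa
ablate_flanks: []
te:
  n_shared_families: 8
  n_unique_per_species: 2
  seq_len: [400, 1200]
  divergence: 0.10
expression:
  samples: [embryo, juvenile, adult_head, adult_trunk, gonad]
  expressed_events: [ev07_gh16_a, ev08_gh16_b]
  biased_samples: [gonad, adult_trunk]
  background_genes: 60
alignment:
  length: 300
  n_donor: 5
  n_metazoan: 5
regression:
  slope: 2.0
  intercept: 130.0
  noise_sd: 60.0
  te_mb_range: [20, 1500]
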