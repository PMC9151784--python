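# Methods

This note documents the models and procedures implemented in `xenosynt`,
the parameters that matter, the design choices made where conventions
diverge, and what the synthetic validation does and does not establish.

## Alien-index screening (`xenosynt.alien`)

Each gene's homology hits carry a precomputed `taxon_group`
(metazoan / non_metazoan) and `taxon_name`. After removing hits whose taxon
is in a user-supplied skip set (self-hit / recipient-lineage exclusion), the
best E-value per group is taken, a missing group scoring E = 1, and

    AI = ln(E_met + 1e-200) − ln(E_non + 1e-200).

The 1e-200 pseudocount keeps the log defined when a search engine reports
E = 0 (such E-values are also clamped to 1e-200 on file read, so the two
conventions coincide). Natural logarithms are used, so AI ≈ 230 for a gene
with a 1e-100 bacterial hit and no metazoan hit.

The candidate threshold defaults to 0 — any gene that looks more
non-metazoan than metazoan is screened in. This is deliberately permissive:
in this design the error control comes from the microsynteny stage, not
from the index cutoff, so the threshold is exposed as a knob rather than
tuned. Taxonomic assignment of subjects is treated as an upstream
responsibility (the package never resolves taxonomy itself, which would
require a database download).

## Microsynteny confirmation (`xenosynt.microsynteny`)

For each candidate, up to `width = 5` genes on each side on the same
scaffold form its flank block; candidates with no flanking genes at all
("lonely", the single-gene-scaffold case) are excluded before grouping,
since isolated contigs are the classic contamination signature.
Candidates are grouped into putative events by the orthogroup of the HGT
gene itself; candidates with no orthogroup cannot form cross-species
events and are reported as unconfirmed singletons.

Two species' blocks *match* when they share at least `min_shared = 2`
flanking orthogroups. Sides and gene order are ignored, species-specific
flanks never count, and the orthogroup of the HGT gene itself is excluded
from flank signatures so tandem copies cannot vouch for each other. A
species supports an event when at least one of its blocks matches a block
from another carrier (a connected-support rule rather than requiring all
pairs to match); the event is confident when supporting species reach
`min_species = 3`. The match criterion is the weakest rule that rejects
random backgrounds in simulation (two independent neighbourhoods of ≤ 10
genes essentially never share two orthogroups by chance at realistic
orthogroup-pool sizes); both knobs are exposed.

Intron status is descriptive, not a filter: a gene with one exon is
intron-less, two or more exons means introns present. Expression overlays
flag a gene expressed when its maximum TPM across samples reaches
`tpm_min = 1.0`, and report row Z-scores (sample n−1 standard deviation;
zero-variance rows map to zeros, the common heatmap convention).

## Macrosynteny (`xenosynt.macrosynteny`)

Anchors are reciprocal best hits at `evalue ≤ 1e-3`; "best" is lowest
E-value with ties broken by higher bitscore then lexicographic subject id
(ties are common once E-values hit the clamp floor, so the tie-break is part
of the contract). Anchoring is one-to-one by construction. Scaffolds are
ordered by descending length, then descending anchor count — the plotting
order of an Oxford dot plot.

Cell enrichment uses the exact hypergeometric upper tail with the anchor set
as population: N = all anchors, K = anchors on the row scaffold, n = anchors
on the column scaffold, k = the cell count. The population choice
(anchors, not all genes) matches what an Oxford grid displays; it is the
natural conditioning when the anchors themselves are the objects plotted.
The tail is an exact log-space sum of hypergeometric point masses via
log-gamma — no normal approximation — so it remains correct at
N ~ 10^4 anchors. BH adjustment runs across all non-empty cells;
significance defaults to q ≤ 0.05.

Because the test is exact and counts are discrete, the null type-I rate at
nominal 0.05 is slightly conservative; with ~ 20 expected anchors per cell
the empirical rate sits near 0.04 (verified by label-shuffling in the test
suite).

## TE families and genome-size modelling (`xenosynt.te`)

Two consensus sequences belong to one family when their best local
alignment reaches `identity ≥ 0.80` over `coverage ≥ 0.80` of the shorter
sequence, testing both strands. Alignment scoring is fixed at +1/−1 with
affine gaps −5 open / −1 extend (the first gapped position pays the open
penalty); only the two 80% thresholds are scientifically meaningful and
they are exposed as parameters. Identity is matches over aligned columns
(gap columns included); coverage is the aligned span on the shorter
sequence over its length. Alignment is delegated to Biopython's
`PairwiseAligner` in local mode; an independently written full-matrix
Gotoh implementation serves as the test oracle. Between co-optimal
alignments identity can differ by a column or two, so oracle agreement is
asserted at 0.03 absolute with exact score equality.

Clustering is greedy and longest-first against cluster representatives
only: each sequence joins the qualifying representative with the highest
identity (earliest cluster on exact ties), else founds a new family. This
mirrors the behaviour of greedy incremental clusterers used for TE
libraries while keeping the algorithm fully deterministic and auditable.

Share counts: a family carried by c species has share count c − 1; 0 is
unique, anything in 1..8 (for a nine-genome panel) is shared. Genome size
is modelled on TE content with `stats.pearson_regression` (raw megabases on
both axes; no transformation is applied, since the analysis this reproduces
reports the regression on raw values).

## Statistical kernel (`xenosynt.stats`)

* `hypergeom_tail` — exact upper tail by log-space summation of
  C(K,i)·C(N−K,n−i)/C(N,n) via `gammaln`, with the log-sum-exp trick.
* `bh_adjust` — Benjamini–Hochberg step-up; q-values returned in input
  order, monotone in rank order, capped at 1.
* `student_t_tail` — two-sided tail from the regularized incomplete beta,
  P(|T| ≥ t) = I_{df/(df+t²)}(df/2, ½). At t = 12.051 with 7 df this gives
  6.17986e-06.
* `pearson_regression` — product-moment r, t = r·√(n−2)/√(1−r²), p from the
  t tail, OLS slope/intercept. Degenerate inputs (constant x, n < 3) raise;
  constant y returns r = 0 with p = 1 (the fit is exact, the correlation
  undefined — this convention keeps pipelines running on degenerate panels).
* `row_zscore` — per-row (x − mean)/sd with the n−1 denominator;
  zero-variance rows map to zeros.

## Neighbour-joining confirmation (`xenosynt.phylo`)

Distances are p-distances with pairwise deletion (columns where either
sequence is gapped are skipped per pair); a pair with no comparable columns
is an error naming the pair. Saitou–Nei NJ joins the Q-minimising pair;
negative branch lengths are clamped to zero with the deficit moved to the
sister edge, preserving the path length of the joined pair. NJ is exact on
additive matrices, which the test suite exploits: random additive trees are
generated with known topology and must be recovered exactly.

Bootstrap supports resample alignment columns with replacement
(deterministic given the seed); support of a split in the full-data tree is
the fraction of replicate trees containing it. Donor placement walks every
internal edge with support ≥ 0.70 (a knob), takes the bipartition sides
containing the focal sequence, and accepts bacterial origin when the
smallest such side contains only non-metazoan leaves besides the focal
gene; with no sufficiently supported edge the result is "unresolved" and
conservative (not placed). Substitution-model-corrected distances and
maximum-likelihood confirmation are out of scope; the model knob is
reserved for future corrections.

## The synthetic generator (`xenosynt.simulate`)

The generator emulates the complete input side of the pipeline with planted
truth. In the packaged `myriapod9` scenario, nine genomes (four
centipede-like: Ttu, Lni, Rim, Sma; five millipede-like: Emi, Tco, Ato,
Nno, Hho) carry eleven HGT events at four clade nodes — one in all five
millipedes, seven in the four helminthomorph millipedes, two in all four
centipedes, one in the three pleurostigmomorph centipedes — totalling 65
member genes of which 32 are intron-less. Some carriers hold two tandem
copies of an event gene, which is how seven four-species events carry seven
genes each; the per-event copy and intron layout is recorded in the
scenario file and in the emitted `truth_events.tsv`.

Key generator behaviours:

* **E-value regimes** are log-uniform within bounds: native genes draw a
  strong metazoan best hit (1e-180..1e-20) and, with probability 0.3, a weak
  non-metazoan hit (1e-3..1); planted genes draw a strong bacterial hit
  (1e-180..1e-50) and, with probability 0.5, a weak metazoan hit. Only the
  ordering of the two groups matters to the screen, so the distribution
  shape is not a sensitive choice.
* **Neighbourhoods**: each carrier species receives the event block — five
  flank genes, the member gene(s), five more flank genes — spliced into a
  random position of a random scaffold; flank genes of one event share
  orthogroups across all carriers. Background gene order is uniformly
  random per scaffold, and background orthogroups span random species
  subsets (inclusion probability 0.7), giving the flank filter a realistic
  non-trivial background.
* **Ablations and contaminants**: `ablate_flanks` removes one event's flank
  conservation (its flank genes become species-specific), which must demote
  exactly that event; `contaminants_per_species` plants genes with
  HGT-like hit profiles but no orthogroup and either a single-gene scaffold
  or a random position — these must never become confident.
* **TE libraries**: shared families draw a base sequence (400–1200 bp) and
  give each carrier a copy mutated at half the configured pairwise
  divergence (default 0.10, i.e. ~90% pairwise identity — comfortably
  inside the 80/80 rule; at 0.30 pairwise the copies fall outside it and
  must split). Unique families are independent random sequences.
* **Alignments**: per event, a protein alignment with a bacterial clade
  (the focal gene nested inside it) and a distant metazoan clade, for the
  NJ confirmation stage.
* **Size panel**: TE content uniform in 20–1500 Mb across species and
  genome size = 130 + 2·TE + N(0, 60) Mb, spanning roughly the 150 Mb–3 Gb
  range seen across real myriapod assemblies.

Everything is deterministic given (scenario, seed) down to the output
bytes, which the test suite asserts.

What passing on synthetic data does *not* show: the generator separates the
two E-value regimes cleanly and plants perfectly conserved flanks, so
recall/precision of 1.0 here is a correctness check of the machinery, not
an estimate of performance on real annotations, where orthology errors,
fragmented scaffolds and genuinely ambiguous homology blur both signals.
The real-data regression (the published r = 0.98 over nine genomes)
requires the supplementary assembly-size table and is replaced here by a
recovery property on the planted line.

## Problem sizes and numerical choices

Default test/validation sizes were chosen to keep the whole suite
desk-scale: 5 scaffolds × 30 background genes per species in `myriapod9`
(~1,900 genes across the panel), 1,000 label-shuffle replicates at 2,000
anchors on a 10 × 10 grid for null calibration, 200 random pairs up to 2 kb
for the alignment oracle, 100 random additive trees (≤ 8 taxa) for NJ, and
100 nine-point panels for regression recovery. The ±2·SE recovery criterion
on 7 df corresponds to ~92% nominal coverage (the 95% t quantile is 2.36),
so the test asserts ≥ 85/100 panels per coefficient.

File formats are plain text; writers append record-count pragmas and an
end-of-data marker (`###` in GFF3, `# end` in TSVs) so that truncated
copies of their own output never parse silently, while files from other
tools (without the pragmas) are accepted as-is.

## Known limitations

* Orthogroup quality is taken as given; the pipeline never re-infers
  orthology, so errors in the input table propagate to event grouping.
* The "≥ 3 species" confidence rule counts carriers with a matched block
  under connected support; requiring all-pairs matching would be stricter
  and can be emulated by raising `min_shared`.
* Donor assignment is the majority best-hit taxon plus NJ placement; no
  attempt is made to date transfers or identify precise donor lineages.
* p-distance NJ without substitution correction underestimates deep
  divergences; for the within-gene confirmation trees used here the
  topology, not the depth, carries the signal.
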