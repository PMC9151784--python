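"""Synthetic multi-species input bundles with planted ground truth.

The generator emulates every input the pipeline consumes — GFF3 annotations,
taxon-annotated homology hit tables, an orthogroup table, TE consensus
libraries, expression matrices, per-event protein alignments and a
TE-content/genome-size panel — and records the planted truth so downstream
stages can be scored as planted-truth recovery.

HGT events are planted at named clade nodes: every carrier species receives
the configured number of gene copies embedded in a conserved neighbourhood of
flanking genes whose orthogroups are shared across carriers. Planted genes
get strong bacterial best hits and weak-or-absent metazoan hits; native genes
the reverse. Everything is deterministic given (scenario, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (GeneModel, GenomeAnnotation, HomologyHit, OrthogroupMap,
                 write_annotation, write_expression, write_hits, write_orthogroups)
from .te import TESequence

__all__ = ["SimulationTruth", "SyntheticBundle", "load_scenario",
           "simulate_dataset", "simulate_regression_panel", "mutate_sequence",
           "write_bundle"]

DNA = "ACGT"
AA = "ACDEFGHIKLMNPQRSTVWY"

METAZOAN_TAXA = ["Drosophila_melanogaster", "Tribolium_castaneum", "Daphnia_pulex",
                 "Ixodes_scapularis", "Limulus_polyphemus", "Crassostrea_gigas"]
BACTERIAL_TAXA = ["Pseudomonas_putida", "Bacillus_subtilis", "Escherichia_coli",
                  "Streptomyces_griseus", "Vibrio_cholerae", "Flavobacterium_johnsoniae"]
TE_CLASSES = ["LTR/Gypsy", "LTR/Copia", "LINE/L1", "DNA/TcMar", "DNA/hAT",
              "RC/Helitron", "SINE/tRNA"]


class ConfigError(ValueError):
    """Inconsistent scenario configuration."""


@dataclass
class PlantedEvent:
    event_id: str
    node: str
    carriers: list[str]
    genes: dict[str, list[str]]            # species -> member gene ids
    intron_flags: dict[str, bool]          # gene id -> has introns
    flank_orthogroups: list[str]
    donor_taxon: str
    conserved: bool = True

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes.values())


@dataclass
class SimulationTruth:
    species_tree: str
    clades: dict[str, list[str]]
    planted_events: list[PlantedEvent]
    te_family_truth: dict[str, frozenset]  # family -> species set
    regression_truth: tuple[float, float, float]  # slope, intercept, noise_sd
    contaminants: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    scenario: str
    seed: int
    annotations: dict[str, GenomeAnnotation]
    hits: dict[str, list[HomologyHit]]
    orthomap: OrthogroupMap
    te_libraries: dict[str, list[TESequence]]
    expression: pd.DataFrame
    alignments: dict[str, tuple[list[tuple[str, str]], dict[str, str]]]
    sizes: pd.DataFrame
    truth: SimulationTruth


def load_scenario(name_or_path) -> dict:
    """Load a scenario config: a packaged scenario name or a YAML path."""
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
    else:
        ref = importlib.resources.files("xenosynt.scenarios") / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise ConfigError(f"unknown scenario {name_or_path!r}")
        text = ref.read_text()
    cfg = yaml.safe_load(text)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    species = cfg["species"]
    if len(set(species)) != len(species):
        raise ConfigError("duplicate species ids")
    for cname, members in cfg["clades"].items():
        unknown = set(members) - set(species)
        if unknown:
            raise ConfigError(f"clade {cname}: unknown species {sorted(unknown)}")
    if cfg["flank_width"] > cfg["genes_per_scaffold"]:
        raise ConfigError("flank_width cannot exceed genes_per_scaffold")
    for ev in cfg["events"]:
        node = ev["node"]
        if node not in cfg["clades"]:
            raise ConfigError(f"event {ev['id']}: unknown clade node {node!r}")
        if set(ev["copies"]) != set(cfg["clades"][node]):
            raise ConfigError(f"event {ev['id']}: copies must cover exactly clade {node}")
        n_genes = sum(ev["copies"].values())
        if not 0 <= ev["intronless"] <= n_genes:
            raise ConfigError(f"event {ev['id']}: intronless out of range")


def simulate_regression_panel(rcfg: dict, species: list[str],
                              rng: np.random.Generator) -> pd.DataFrame:
    """Per-species TE content (Mb) and genome size (Mb) on a noisy line:
    genome = intercept + slope * te + N(0, noise_sd)."""
    te_mb = np.sort(rng.uniform(*rcfg["te_mb_range"], len(species)))
    genome_mb = rcfg["intercept"] + rcfg["slope"] * te_mb \
        + rng.normal(0.0, rcfg["noise_sd"], len(species))
    return pd.DataFrame({"species": species,
                         "te_mb": np.round(te_mb, 2),
                         "genome_mb": np.round(genome_mb, 2)})


def mutate_sequence(seq: str, divergence: float, seed: int) -> str:
    """Substitute each position with probability ``divergence``, uniformly over
    the three alternative nucleotides. Length-preserving; deterministic."""
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return _mutate(seq, divergence, rng, DNA)


def _mutate(seq: str, divergence: float, rng: np.random.Generator, alphabet: str) -> str:
    arr = list(seq)
    hit = rng.random(len(arr)) < divergence
    for i in np.flatnonzero(hit):
        choices = [c for c in alphabet if c != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = DNA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def _make_hit(rng, query, subject, evalue, group, taxon) -> HomologyHit:
    length = int(rng.integers(80, 400))
    pident = float(rng.uniform(30, 95))
    bitscore = round(max(25.0, -1.8 * np.log10(evalue) + float(rng.uniform(0, 20))), 1)
    return HomologyHit(query, subject, round(pident, 1), length,
                       int(length * (100 - pident) / 100), int(rng.integers(0, 4)),
                       1, length, 1, length, evalue, bitscore, group, taxon)


def simulate_dataset(config: dict | str, seed: int) -> SyntheticBundle:
    """Generate a complete input bundle for one scenario.

    ``config`` is a scenario dict (see the packaged YAML files) or a scenario
    name/path accepted by :func:`load_scenario`.
    """
    if not isinstance(config, dict):
        config = load_scenario(config)
    else:
        _validate(config)
    cfg = config
    rng = np.random.default_rng(seed)
    species = list(cfg["species"])
    n_bg = cfg["scaffolds_per_species"] * cfg["genes_per_scaffold"]
    ablate = set(cfg.get("ablate_flanks", []))

    # ---- background orthogroup structure -------------------------------
    og_members: dict[str, dict[str, list[str]]] = {}
    gene_og: dict[str, str] = {}
    for o in range(n_bg):
        og = f"OGB{o:05d}"
        carriers = [sp for sp in species if rng.random() < cfg["background_share_prob"]]
        if len(carriers) < 2:
            continue  # genes stay species-specific
        og_members[og] = {sp: [f"{sp}_bg{o:04d}"] for sp in carriers}
        for sp in carriers:
            gene_og[f"{sp}_bg{o:04d}"] = og

    # ---- planted events -------------------------------------------------
    events: list[PlantedEvent] = []
    width = cfg["flank_width"]
    for ev in cfg["events"]:
        eid = ev["id"]
        carriers = list(cfg["clades"][ev["node"]])
        conserved = ev.get("conserved", True) and eid not in ablate
        flank_ogs = [f"OGF_{eid}_{k}" for k in range(2 * width)]
        genes = {sp: [f"{sp}_{eid}_h{c}" for c in range(ev["copies"][sp])]
                 for sp in carriers}
        flat = [g for sp in carriers for g in genes[sp]]
        intron_flags = {g: i >= ev["intronless"] for i, g in enumerate(flat)}
        events.append(PlantedEvent(eid, ev["node"], carriers, genes, intron_flags,
                                   flank_ogs, ev["donor"], conserved))
        og_h = f"OGH_{eid}"
        og_members[og_h] = {sp: list(genes[sp]) for sp in carriers}
        for sp in carriers:
            for g in genes[sp]:
                gene_og[g] = og_h
            if conserved:
                for k, fog in enumerate(flank_ogs):
                    fg = f"{sp}_{eid}_f{k}"
                    og_members.setdefault(fog, {})[sp] = [fg]
                    gene_og[fg] = fog

    # ---- contaminants ---------------------------------------------------
    contaminants: dict[str, list[str]] = {sp: [] for sp in species}
    n_cont = int(cfg.get("contaminants_per_species", 0))
    lonely_cont: dict[str, list[str]] = {sp: [] for sp in species}
    placed_cont: dict[str, list[str]] = {sp: [] for sp in species}
    for sp in species:
        for i in range(n_cont):
            gid = f"{sp}_cont{i}"
            contaminants[sp].append(gid)
            (lonely_cont if rng.random() < 0.5 else placed_cont)[sp].append(gid)

    # ---- scaffold layout and coordinates --------------------------------
    annotations: dict[str, GenomeAnnotation] = {}
    for sp in species:
        bg = [f"{sp}_bg{o:04d}" for o in range(n_bg)]
        gps = cfg["genes_per_scaffold"]
        scaffold_genes: dict[str, list[str]] = {}
        for s in range(cfg["scaffolds_per_species"]):
            chunk = bg[s * gps:(s + 1) * gps]
            order = rng.permutation(len(chunk))
            scaffold_genes[f"{sp}_scf{s+1}"] = [chunk[i] for i in order]
        scf_ids = list(scaffold_genes)
        for evt in events:
            if sp not in evt.carriers:
                continue
            block = ([f"{sp}_{evt.event_id}_f{k}" for k in range(width)]
                     + evt.genes[sp]
                     + [f"{sp}_{evt.event_id}_f{k}" for k in range(width, 2 * width)])
            target = scf_ids[rng.integers(len(scf_ids))]
            pos = int(rng.integers(0, len(scaffold_genes[target]) + 1))
            scaffold_genes[target][pos:pos] = block
        for gid in placed_cont[sp]:
            target = scf_ids[rng.integers(len(scf_ids))]
            pos = int(rng.integers(0, len(scaffold_genes[target]) + 1))
            scaffold_genes[target].insert(pos, gid)
        for i, gid in enumerate(lonely_cont[sp]):
            scaffold_genes[f"{sp}_scfc{i+1}"] = [gid]

        intron_of: dict[str, bool] = {}
        for evt in events:
            if sp in evt.carriers:
                for g in evt.genes[sp]:
                    intron_of[g] = evt.intron_flags[g]
        genes: list[GeneModel] = []
        scaffolds: dict[str, int] = {}
        for scf, order in scaffold_genes.items():
            cursor = 0
            for gid in order:
                gap = int(rng.integers(200, 2001))
                length = int(rng.integers(1000, 8001))
                start = cursor + gap + 1
                end = start + length - 1
                cursor = end
                strand = "+" if rng.random() < 0.5 else "-"
                if gid in intron_of:
                    exons = 1 if not intron_of[gid] else int(rng.integers(2, 7))
                elif gid in contaminants[sp]:
                    exons = 1
                else:
                    exons = int(rng.integers(1, 9))
                genes.append(GeneModel(gid, scf, start, end, strand, exons))
            scaffolds[scf] = cursor + 500
        annotations[sp] = GenomeAnnotation(sp, scaffolds, genes)

    # ---- homology hit tables --------------------------------------------
    ecfg = cfg["evalue"]
    hits: dict[str, list[HomologyHit]] = {}
    hgt_of: dict[str, str] = {}
    for evt in events:
        for sp in evt.carriers:
            for g in evt.genes[sp]:
                hgt_of[g] = evt.donor_taxon
    for sp in species:
        rows: list[HomologyHit] = []
        for g in annotations[sp].genes:
            gid = g.gene_id
            if gid in hgt_of or gid in contaminants[sp]:
                donor = hgt_of.get(gid) or BACTERIAL_TAXA[int(rng.integers(len(BACTERIAL_TAXA)))]
                e_n = _loguniform(rng, *ecfg["hgt_nonmeta"])
                rows.append(_make_hit(rng, gid, f"WP_{int(rng.integers(10**8)):09d}.1",
                                      e_n, "non_metazoan", donor))
                if rng.random() < ecfg["hgt_meta_prob"]:
                    e_m = _loguniform(rng, *ecfg["hgt_meta"])
                    taxon = METAZOAN_TAXA[int(rng.integers(len(METAZOAN_TAXA)))]
                    rows.append(_make_hit(rng, gid, f"XP_{int(rng.integers(10**8)):09d}.1",
                                          e_m, "metazoan", taxon))
            else:
                e_m = _loguniform(rng, *ecfg["native_meta"])
                taxon = METAZOAN_TAXA[int(rng.integers(len(METAZOAN_TAXA)))]
                rows.append(_make_hit(rng, gid, f"XP_{int(rng.integers(10**8)):09d}.1",
                                      e_m, "metazoan", taxon))
                if rng.random() < ecfg["native_nonmeta_prob"]:
                    e_n = _loguniform(rng, *ecfg["native_nonmeta"])
                    bact = BACTERIAL_TAXA[int(rng.integers(len(BACTERIAL_TAXA)))]
                    rows.append(_make_hit(rng, gid, f"WP_{int(rng.integers(10**8)):09d}.1",
                                          e_n, "non_metazoan", bact))
        hits[sp] = rows

    # ---- orthogroup map --------------------------------------------------
    omap = OrthogroupMap(gene_og, species, {og: og_members[og] for og in sorted(og_members)})

    # ---- TE libraries ----------------------------------------------------
    tcfg = cfg["te"]
    te_truth: dict[str, frozenset] = {}
    te_libs: dict[str, list[TESequence]] = {sp: [] for sp in species}
    lo, hi = tcfg["seq_len"]
    for i in range(tcfg["n_shared_families"]):
        fam = f"TEfamS{i:03d}"
        size = int(rng.integers(2, len(species) + 1))
        carriers = sorted(rng.choice(species, size=size, replace=False).tolist())
        base = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        cls = TE_CLASSES[int(rng.integers(len(TE_CLASSES)))]
        te_truth[fam] = frozenset(carriers)
        for sp in carriers:
            copy = _mutate(base, tcfg["divergence"] / 2.0, rng, DNA)
            te_libs[sp].append(TESequence(f"{fam}_{sp}", sp, cls, copy))
    for sp in species:
        for i in range(tcfg["n_unique_per_species"]):
            fam = f"TEfamU_{sp}_{i}"
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            cls = TE_CLASSES[int(rng.integers(len(TE_CLASSES)))]
            te_truth[fam] = frozenset({sp})
            te_libs[sp].append(TESequence(f"{fam}_{sp}", sp, cls, seq))

    # ---- expression matrix ----------------------------------------------
    xcfg = cfg["expression"]
    samples = list(xcfg["samples"])
    expressed_events = set(xcfg["expressed_events"])
    biased = [samples.index(s) for s in xcfg["biased_samples"]]
    rows_x: dict[str, np.ndarray] = {}
    for evt in events:
        for sp in evt.carriers:
            for g in evt.genes[sp]:
                if evt.event_id in expressed_events:
                    v = rng.uniform(0.0, 0.5, len(samples))
                    for b in biased:
                        v[b] = rng.uniform(20, 80)
                else:
                    v = rng.uniform(0.0, 0.5, len(samples))
                rows_x[g] = np.round(v, 3)
    n_bg_expr = int(xcfg["background_genes"])
    for j in range(n_bg_expr):
        sp = species[j % len(species)]
        gid = f"{sp}_bg{j:04d}"
        rows_x[gid] = np.round(rng.lognormal(1.5, 1.2, len(samples)), 3)
    expression = pd.DataFrame.from_dict(rows_x, orient="index", columns=samples)
    expression.index.name = "gene_id"

    # ---- per-event alignments -------------------------------------------
    acfg = cfg["alignment"]
    alignments: dict[str, tuple[list[tuple[str, str]], dict[str, str]]] = {}
    for evt in events:
        root = _random_seq(rng, acfg["length"], AA)
        bact_anc = _mutate(root, 0.35, rng, AA)
        meta_anc = _mutate(root, 0.35, rng, AA)
        focal = evt.genes[evt.carriers[0]][0]
        recs = [(focal, _mutate(bact_anc, 0.08, rng, AA))]
        groups = {focal: "metazoan"}
        for i in range(acfg["n_donor"]):
            lab = f"bact_{evt.event_id}_{i}"
            recs.append((lab, _mutate(bact_anc, 0.10, rng, AA)))
            groups[lab] = "non_metazoan"
        for i in range(acfg["n_metazoan"]):
            lab = f"meta_{evt.event_id}_{i}"
            recs.append((lab, _mutate(meta_anc, 0.10, rng, AA)))
            groups[lab] = "metazoan"
        alignments[evt.event_id] = (recs, groups)

    # ---- TE-content vs genome-size panel --------------------------------
    sizes = simulate_regression_panel(cfg["regression"], species, rng)

    rcfg = cfg["regression"]
    truth = SimulationTruth(cfg["species_tree"], dict(cfg["clades"]), events,
                            te_truth,
                            (rcfg["slope"], rcfg["intercept"], rcfg["noise_sd"]),
                            contaminants)
    return SyntheticBundle(cfg["name"], seed, annotations, hits, omap, te_libs,
                           expression, alignments, sizes, truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle as the standard on-disk formats plus truth tables."""
    out = Path(outdir)
    (out / "gff").mkdir(parents=True, exist_ok=True)
    (out / "hits").mkdir(exist_ok=True)
    (out / "te").mkdir(exist_ok=True)
    (out / "alignments").mkdir(exist_ok=True)
    for sp, ann in bundle.annotations.items():
        write_annotation(ann, out / "gff" / f"{sp}.gff3")
        write_hits(bundle.hits[sp], out / "hits" / f"{sp}.tsv")
        with open(out / "te" / f"{sp}.fasta", "w") as fh:
            for t in bundle.te_libraries[sp]:
                fh.write(f">{t.seq_id}#{t.classification}\n{t.sequence}\n")
    write_orthogroups(bundle.orthomap, out / "orthogroups.tsv")
    write_expression(bundle.expression, out / "expression.tsv")
    bundle.sizes.to_csv(out / "sizes.tsv", sep="\t", index=False)
    for eid, (recs, groups) in bundle.alignments.items():
        with open(out / "alignments" / f"{eid}.faa", "w") as fh:
            for lab, seq in recs:
                fh.write(f">{lab}\n{seq}\n")
        with open(out / "alignments" / f"{eid}.groups.tsv", "w") as fh:
            for lab in groups:
                fh.write(f"{lab}\t{groups[lab]}\n")
    with open(out / "truth_events.tsv", "w") as fh:
        fh.write("event_id\tnode\tspecies\tgene_id\thas_introns\tdonor_taxon\tconserved\n")
        for evt in bundle.truth.planted_events:
            for sp in evt.carriers:
                for g in evt.genes[sp]:
                    fh.write(f"{evt.event_id}\t{evt.node}\t{sp}\t{g}\t"
                             f"{int(evt.intron_flags[g])}\t{evt.donor_taxon}\t"
                             f"{int(evt.conserved)}\n")
    with open(out / "truth_te.tsv", "w") as fh:
        fh.write("family_id\tspecies\n")
        for fam in sorted(bundle.truth.te_family_truth):
            for sp in sorted(bundle.truth.te_family_truth[fam]):
                fh.write(f"{fam}\t{sp}\n")
    slope, intercept, sd = bundle.truth.regression_truth
    with open(out / "truth_regression.tsv", "w") as fh:
        fh.write("slope\tintercept\tnoise_sd\n")
        fh.write(f"{slope}\t{intercept}\t{sd}\n")
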