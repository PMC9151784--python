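"""Microsynteny confirmation of HGT candidates.

A candidate is confirmed by conservation of its local gene neighbourhood:
the orthogroups of up to five genes on each side of the candidate are
compared across carrier species. Two species' flank blocks match when they
share at least ``min_shared`` flanking orthogroups (species-specific flanks
never match). An event is confident when at least ``min_species`` carriers
hold mutually matched blocks — the "found across at least three species"
rule. Candidates alone on their scaffold (no flanking genes at all) are
excluded up front, since contamination contigs typically carry nothing else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alien import AlienIndexRecord
from .io import GenomeAnnotation, OrthogroupMap
from .stats import row_zscore

__all__ = ["FlankBlock", "HGTCall", "extract_flanks", "block_match",
           "call_hgt_events", "intron_status", "expression_summary"]

log = logging.getLogger(__name__)


@dataclass
class FlankBlock:
    focal_gene: str
    upstream: list[str]      # nearest first
    downstream: list[str]    # nearest first
    signature: frozenset = frozenset()

    @property
    def lonely(self) -> bool:
        return not self.upstream and not self.downstream


@dataclass
class HGTCall:
    event_id: str
    hgt_orthogroup: str | None
    members: dict[str, list[str]]          # species -> gene ids
    supporting_species: int
    confident: bool
    intronless_count: int
    introned_count: int
    donor_taxon: str
    species_support: dict[str, bool] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def carrier_species(self) -> frozenset:
        return frozenset(self.members)


def extract_flanks(annotation: GenomeAnnotation, gene_id: str, width: int = 5) -> FlankBlock:
    """Up to ``width`` genes on each side of the focal gene, in scaffold order,
    nearest first; fewer near scaffold ends."""
    g = annotation.gene(gene_id)
    row = annotation.scaffold_genes(g.scaffold_id)
    idx = next(i for i, x in enumerate(row) if x.gene_id == gene_id)
    up = [x.gene_id for x in row[max(0, idx - width):idx]][::-1]
    down = [x.gene_id for x in row[idx + 1:idx + 1 + width]]
    return FlankBlock(gene_id, up, down)


def flank_signature(block: FlankBlock, orthomap: OrthogroupMap,
                    exclude: frozenset = frozenset()) -> FlankBlock:
    """Attach the set of orthogroups of the flanking genes; species-specific
    flanks (no orthogroup) contribute nothing. ``exclude`` removes orthogroups
    that must not count as context (e.g. the HGT orthogroup itself, so tandem
    copies cannot vouch for each other)."""
    ogs = set()
    for gid in (*block.upstream, *block.downstream):
        og = orthomap.get(gid)
        if og is not None and og not in exclude:
            ogs.add(og)
    block.signature = frozenset(ogs)
    return block


def block_match(block_a: FlankBlock, block_b: FlankBlock, min_shared: int = 2) \
        -> tuple[int, bool]:
    """Number of shared flanking orthogroups, and whether it reaches
    ``min_shared``. Sides and gene order are ignored."""
    shared = len(block_a.signature & block_b.signature)
    return shared, shared >= min_shared


def intron_status(annotation: GenomeAnnotation, gene_id: str) -> bool:
    """True iff the gene has at least one intron (two or more exons)."""
    return annotation.gene(gene_id).exon_count >= 2


def call_hgt_events(candidates: dict[str, list[AlienIndexRecord]],
                    annotations: dict[str, GenomeAnnotation],
                    orthomap: OrthogroupMap,
                    min_species: int = 3,
                    min_shared: int = 2,
                    flank_width: int = 5) -> list[HGTCall]:
    """Group per-species candidates into cross-species HGT events.

    Candidates are grouped by the orthogroup of the HGT gene itself; lonely
    candidates (no flanking gene on their scaffold) are dropped first. Within
    a group, a species supports the event when at least one of its candidate
    blocks matches (>= ``min_shared`` shared flank orthogroups) a block from
    another carrier species. The event is confident when supporting species
    reach ``min_species``. Candidates without an orthogroup are reported as
    unconfirmed singletons.
    """
    # orthogroup -> species -> [(gene_id, donor)]
    groups: dict[str, dict[str, list[tuple[str, str]]]] = {}
    singletons: list[tuple[str, str, str]] = []  # (species, gene, donor)
    for species in sorted(candidates):
        ann = annotations[species]
        for rec in candidates[species]:
            if rec.gene_id not in ann:
                raise KeyError(f"candidate {rec.gene_id} absent from {species} annotation")
            block = extract_flanks(ann, rec.gene_id, flank_width)
            if block.lonely:
                continue
            og = orthomap.get(rec.gene_id)
            if og is None:
                singletons.append((species, rec.gene_id, rec.donor_taxon))
                continue
            groups.setdefault(og, {}).setdefault(species, []).append(
                (rec.gene_id, rec.donor_taxon))

    calls: list[HGTCall] = []
    for og in sorted(groups):
        per_sp = groups[og]
        blocks: dict[str, list[FlankBlock]] = {}
        for sp, genes in per_sp.items():
            ann = annotations[sp]
            blocks[sp] = [
                flank_signature(extract_flanks(ann, gid, flank_width), orthomap,
                                exclude=frozenset({og}))
                for gid, _ in genes]
        support: dict[str, bool] = {}
        for sp in per_sp:
            matched = False
            for other in per_sp:
                if other == sp:
                    continue
                for ba in blocks[sp]:
                    for bb in blocks[other]:
                        if block_match(ba, bb, min_shared)[1]:
                            matched = True
                            break
                    if matched:
                        break
                if matched:
                    break
            support[sp] = matched
        supporting = sum(support.values())
        members = {sp: sorted(g for g, _ in per_sp[sp]) for sp in sorted(per_sp)}
        intronless = introned = 0
        for sp, genes in members.items():
            for gid in genes:
                if intron_status(annotations[sp], gid):
                    introned += 1
                else:
                    intronless += 1
        donors = [d for sp in per_sp for _, d in per_sp[sp] if d]
        donor = max(sorted(set(donors)), key=donors.count) if donors else ""
        calls.append(HGTCall(
            event_id=og, hgt_orthogroup=og, members=members,
            supporting_species=supporting,
            confident=supporting >= min_species,
            intronless_count=intronless, introned_count=introned,
            donor_taxon=donor, species_support=support))

    for sp, gid, donor in sorted(singletons):
        has_intron = intron_status(annotations[sp], gid)
        calls.append(HGTCall(
            event_id=f"singleton:{gid}", hgt_orthogroup=None,
            members={sp: [gid]}, supporting_species=1, confident=False,
            intronless_count=0 if has_intron else 1,
            introned_count=1 if has_intron else 0,
            donor_taxon=donor, species_support={sp: False}))
    return calls


def expression_summary(expr: pd.DataFrame, genes: list[str], tpm_min: float = 1.0) \
        -> tuple[dict[str, bool], pd.DataFrame]:
    """Expressed flags (max TPM >= tpm_min) and a row Z-score matrix for the
    requested genes. Genes absent from the matrix are flagged not-expressed
    with a warning and excluded from the Z matrix."""
    if expr.shape[1] < 1:
        raise ValueError("expression matrix has no samples")
    present = [g for g in genes if g in expr.index]
    for g in genes:
        if g not in expr.index:
            log.warning("gene %s absent from expression matrix; flagged not-expressed", g)
    flags = {g: False for g in genes}
    sub = expr.loc[present]
    for g in present:
        flags[g] = bool(sub.loc[g].max() >= tpm_min)
    if present and expr.shape[1] >= 2:
        z = pd.DataFrame(row_zscore(sub.to_numpy(float)), index=present,
                         columns=expr.columns)
    else:
        z = pd.DataFrame(np.empty((0, expr.shape[1])), columns=expr.columns)
    return flags, z
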