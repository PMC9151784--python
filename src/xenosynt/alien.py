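"""Alien-index HGT screening.

The alien index (AI) of a gene contrasts its best metazoan and best
non-metazoan homology E-values:

    AI = ln(best_e_metazoan + 1e-200) - ln(best_e_non_metazoan + 1e-200)

A missing group is scored as E = 1. Positive AI means the gene looks more
like its putative donor group (bacteria and other non-metazoans) than like
other animals; confidence is deferred to the microsynteny stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import HomologyHit

__all__ = ["AlienIndexRecord", "best_hits_by_group", "alien_index",
           "screen_candidates", "build_records", "PSEUDOCOUNT"]

PSEUDOCOUNT = 1e-200


@dataclass
class AlienIndexRecord:
    gene_id: str
    best_e_metazoan: float
    best_e_non_metazoan: float
    ai: float
    donor_taxon: str
    is_candidate: bool


def alien_index(e_meta: float, e_nonmeta: float) -> float:
    """AI = ln(e_meta + pc) - ln(e_nonmeta + pc); positive favours the donor."""
    if e_meta <= 0 or e_nonmeta <= 0:
        raise ValueError("E-values must be positive (clamp zeros on read)")
    if e_meta > 1 or e_nonmeta > 1:
        raise ValueError("E-values above 1 are not meaningful here")
    return math.log(e_meta + PSEUDOCOUNT) - math.log(e_nonmeta + PSEUDOCOUNT)


def best_hits_by_group(hits: list[HomologyHit], skip_taxa: set[str] = frozenset()) \
        -> dict[str, tuple[float, float, str]]:
    """Per query gene, the minimum E-value within each taxon group.

    Hits whose ``taxon_name`` is in ``skip_taxa`` are removed first (self /
    recipient-lineage exclusion). A group with no remaining hit scores 1.0.
    Returns gene_id -> (best_e_metazoan, best_e_non_metazoan, donor_taxon),
    the donor taxon being that of the best non-metazoan hit ("" if none).
    """
    best: dict[str, tuple[float, float, str]] = {}
    for h in hits:
        if h.taxon_name in skip_taxa:
            continue
        e_m, e_n, donor = best.get(h.query_id, (1.0, 1.0, ""))
        if h.taxon_group == "metazoan":
            if h.evalue < e_m:
                e_m = h.evalue
        else:
            if h.evalue < e_n:
                e_n, donor = h.evalue, h.taxon_name
        best[h.query_id] = (e_m, e_n, donor)
    return best


def build_records(hits: list[HomologyHit], skip_taxa: set[str] = frozenset(),
                  ai_threshold: float = 0.0) -> list[AlienIndexRecord]:
    """AlienIndexRecord per query gene present in the hit table."""
    best = best_hits_by_group(hits, skip_taxa)
    records = []
    for gene_id in sorted(best):
        e_m, e_n, donor = best[gene_id]
        ai = alien_index(e_m, e_n)
        records.append(AlienIndexRecord(gene_id, e_m, e_n, ai, donor, ai > ai_threshold))
    return records


def screen_candidates(records: list[AlienIndexRecord], ai_threshold: float = 0.0) \
        -> list[AlienIndexRecord]:
    """Records with AI strictly above the threshold, sorted by descending AI."""
    out = [r for r in records if r.ai > ai_threshold]
    out.sort(key=lambda r: (-r.ai, r.gene_id))
    return out
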