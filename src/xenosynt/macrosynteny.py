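"""Macrosynteny: ortholog anchoring by mutual best hits and Oxford-grid
scaffold-pair enrichment.

Anchors are reciprocal best hits between two genomes (lowest E-value, ties
broken by bitscore then subject id) passing an E-value cutoff. Anchor counts
per scaffold pair are tested for enrichment with a one-tailed hypergeometric
test over the anchor population, adjusted by Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import GenomeAnnotation, HomologyHit
from .stats import HypergeomTest, bh_adjust, hypergeom_tail

__all__ = ["OxfordGrid", "CellTest", "mutual_best_hits", "oxford_grid", "grid_enrichment"]


@dataclass
class CellTest:
    scaffold_a: str
    scaffold_b: str
    count: int
    test: HypergeomTest
    significant: bool | None = None


@dataclass
class OxfordGrid:
    species_pair: tuple[str, str]
    anchors: list[tuple[str, str, str, str]]  # gene_a, gene_b, scaffold_a, scaffold_b
    cell_counts: dict[tuple[str, str], int]
    row_order: list[str] = field(default_factory=list)   # scaffolds of species a
    col_order: list[str] = field(default_factory=list)   # scaffolds of species b
    tests: list[CellTest] = field(default_factory=list)


def _best_per_query(hits: list[HomologyHit], cutoff: float) -> dict[str, str]:
    """query -> best subject (lowest evalue, then highest bitscore, then
    lexicographically smallest subject id), restricted to evalue <= cutoff."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        if h.evalue > cutoff:
            continue
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (cur.evalue, -cur.bitscore, cur.subject_id):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def mutual_best_hits(hits_ab: list[HomologyHit], hits_ba: list[HomologyHit],
                     evalue_cutoff: float = 1e-3) -> list[tuple[str, str]]:
    """Reciprocal best-hit anchor pairs (a, b): b is a's best hit and a is b's,
    both at evalue <= cutoff. One-to-one by construction."""
    best_ab = _best_per_query(hits_ab, evalue_cutoff)
    best_ba = _best_per_query(hits_ba, evalue_cutoff)
    return sorted((a, b) for a, b in best_ab.items() if best_ba.get(b) == a)


def oxford_grid(anchors: list[tuple[str, str]], ann_a: GenomeAnnotation,
                ann_b: GenomeAnnotation) -> OxfordGrid:
    """Tally anchors per scaffold pair. Scaffolds are ordered by descending
    length, then descending anchor count, then id — the plotting order."""
    placed = []
    counts: dict[tuple[str, str], int] = {}
    per_a: dict[str, int] = {}
    per_b: dict[str, int] = {}
    for a, b in anchors:
        sa = ann_a.gene(a).scaffold_id
        sb = ann_b.gene(b).scaffold_id
        placed.append((a, b, sa, sb))
        counts[(sa, sb)] = counts.get((sa, sb), 0) + 1
        per_a[sa] = per_a.get(sa, 0) + 1
        per_b[sb] = per_b.get(sb, 0) + 1
    row_order = sorted(per_a, key=lambda s: (-ann_a.scaffolds[s], -per_a[s], s))
    col_order = sorted(per_b, key=lambda s: (-ann_b.scaffolds[s], -per_b[s], s))
    return OxfordGrid((ann_a.species_id, ann_b.species_id), placed, counts,
                      row_order, col_order)


def grid_enrichment(grid: OxfordGrid, alpha: float = 0.05) -> OxfordGrid:
    """Fill hypergeometric enrichment tests for every non-empty cell.

    Population N = total anchors; K = anchors on the row scaffold; n = anchors
    on the column scaffold; k = cell count. BH adjustment across all tested
    cells; a cell is significant when q <= alpha.
    """
    N = len(grid.anchors)
    if N == 0:
        grid.tests = []
        return grid
    per_a: dict[str, int] = {}
    per_b: dict[str, int] = {}
    for _, _, sa, sb in grid.anchors:
        per_a[sa] = per_a.get(sa, 0) + 1
        per_b[sb] = per_b.get(sb, 0) + 1
    cells = sorted(grid.cell_counts)
    tests = []
    for sa, sb in cells:
        k = grid.cell_counts[(sa, sb)]
        K, n = per_a[sa], per_b[sb]
        p = hypergeom_tail(N, K, n, k)
        tests.append(CellTest(sa, sb, k, HypergeomTest(N, K, n, k, p)))
    qs = bh_adjust([t.test.p_one_tailed for t in tests])
    for t, q in zip(tests, qs):
        t.test.q_bh = q
        t.significant = q <= alpha
    grid.tests = tests
    return grid
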