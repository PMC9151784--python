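"""TE consensus clustering into families and shared/unique classification.

Families follow the 80/80-style rule: two consensus sequences belong to one
family when their best local alignment (either strand) reaches at least 80%
identity over at least 80% of the shorter sequence. Clustering is greedy and
longest-first against cluster representatives, mirroring the behaviour of
greedy incremental clusterers. A family's share count is the number of
species beyond the first that carry it: 0 = unique, 1+ = shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

__all__ = ["ClusterParams", "TESequence", "TEFamilyCluster", "local_identity",
           "greedy_cluster", "share_counts", "share_summary"]

# local-alignment scoring: fixed, only the acceptance thresholds are knobs
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -5, -1


@dataclass(frozen=True)
class ClusterParams:
    identity_min: float = 0.80        # minimum identity over aligned columns
    short_coverage_min: float = 0.80  # minimum aligned fraction of the shorter seq
    both_strands: bool = True         # also try the reverse complement
    # alignment mode is always local

    def __post_init__(self):
        for v in (self.identity_min, self.short_coverage_min):
            if not 0 < v <= 1:
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class TESequence:
    seq_id: str
    species_id: str
    classification: str
    sequence: str


@dataclass
class TEFamilyCluster:
    family_id: str
    representative: str
    members: list[TESequence] = field(default_factory=list)
    species_set: frozenset = frozenset()
    share_count: int = 0
    status: str = "unique"


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


_ALIGNER = _aligner()


def _identity_cov(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """(identity, short_coverage, score) of the best local alignment a vs b."""
    alns = _ALIGNER.align(seq_a, seq_b)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0, 0.0
    best = alns[0]
    blocks_a, blocks_b = best.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0, float(alns.score)
    matches = 0
    matched_cols = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        matched_cols += a1 - a0
        for ca, cb in zip(seq_a[a0:a1], seq_b[b0:b1]):
            if ca == cb:
                matches += 1
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    columns = span_a + span_b - matched_cols
    identity = matches / columns if columns else 0.0
    short_len = min(len(seq_a), len(seq_b))
    coverage = (span_a if len(seq_a) <= len(seq_b) else span_b) / short_len
    return identity, coverage, float(alns.score)


def local_identity(seq_a: str, seq_b: str, both_strands: bool = True) \
        -> tuple[float, float]:
    """Identity and shorter-sequence coverage of the best local alignment.

    Scoring is +1 match, -1 mismatch, -5 gap open, -1 gap extend. With
    ``both_strands`` the reverse complement of ``seq_b`` is also tried and
    the higher-scoring orientation kept (forward on ties). Identity is
    matches / aligned columns (gap columns included); coverage is the aligned
    span on the shorter sequence divided by its length.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    ident, cov, score = _identity_cov(seq_a, seq_b)
    if both_strands:
        rc = str(Seq(seq_b).reverse_complement())
        ident_rc, cov_rc, score_rc = _identity_cov(seq_a, rc)
        if score_rc > score:
            ident, cov = ident_rc, cov_rc
    return ident, cov


def greedy_cluster(library: list[TESequence], params: ClusterParams = ClusterParams()) \
        -> list[TEFamilyCluster]:
    """Greedy longest-first clustering against representatives.

    Sequences are visited in order of decreasing length (ties by id). Each
    sequence joins the best-matching existing family whose representative it
    matches at the identity/coverage thresholds, else founds a new family.
    Deterministic given the ordering and tie rules (highest identity wins;
    earlier family on exact ties).
    """
    for s in library:
        if not s.sequence:
            raise ValueError(f"empty sequence {s.seq_id}")
    ordered = sorted(library, key=lambda s: (-len(s.sequence), s.seq_id))
    clusters: list[TEFamilyCluster] = []
    reps: list[TESequence] = []
    for seq in ordered:
        best_i, best_ident = -1, -1.0
        for i, rep in enumerate(reps):
            ident, cov = local_identity(seq.sequence, rep.sequence, params.both_strands)
            if ident >= params.identity_min and cov >= params.short_coverage_min:
                if ident > best_ident:
                    best_i, best_ident = i, ident
        if best_i >= 0:
            clusters[best_i].members.append(seq)
        else:
            fam = TEFamilyCluster(f"TEfam{len(clusters)+1:04d}", seq.seq_id, [seq])
            clusters.append(fam)
            reps.append(seq)
    return clusters


def share_counts(families: list[TEFamilyCluster], panel: list[str]) \
        -> list[TEFamilyCluster]:
    """Fill species sets, share counts and unique/shared status.

    share_count = |species carrying the family| - 1; 0 means unique to one
    species, 1..len(panel)-1 means shared.
    """
    panel_set = set(panel)
    for fam in families:
        species = frozenset(m.species_id for m in fam.members)
        outside = species - panel_set
        if outside:
            raise ValueError(f"family {fam.family_id}: species outside panel: {sorted(outside)}")
        fam.species_set = species
        fam.share_count = len(species) - 1
        fam.status = "unique" if fam.share_count == 0 else "shared"
    return families


def share_summary(families: list[TEFamilyCluster]) -> pd.DataFrame:
    """Per-species, per-classification tallies of unique vs shared families."""
    rows = []
    for fam in families:
        classes = sorted({m.classification for m in fam.members})
        cls = classes[0] if len(classes) == 1 else "Mixed"
        for sp in sorted(fam.species_set):
            rows.append({"species": sp, "classification": cls,
                         "status": fam.status, "family_id": fam.family_id})
    if not rows:
        return pd.DataFrame(columns=["species", "classification", "status", "n_families"])
    df = pd.DataFrame(rows)
    return (df.groupby(["species", "classification", "status"])
              .size().reset_index(name="n_families"))
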