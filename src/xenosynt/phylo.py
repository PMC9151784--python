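"""Neighbour-joining donor confirmation.

Distance trees are built from p-distances (pairwise deletion) with the
Saitou–Nei neighbour-joining algorithm, bootstrap supports come from column
resampling, and a candidate's bacterial origin is confirmed when the smallest
well-supported clade around it contains only non-metazoan leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = ["DistanceMatrix", "SupportedTree", "DonorPlacement", "read_alignment",
           "p_distance_matrix", "neighbor_joining", "bootstrap_support",
           "donor_placement"]

GAP_CHARS = frozenset("-.")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("matrix must be symmetric with zero diagonal")


@dataclass
class _Node:
    label: str | None = None
    children: list = field(default_factory=list)  # (child _Node, branch length)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset:
        if self.is_leaf:
            return frozenset({self.label})
        out = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)


@dataclass
class SupportedTree:
    """Unrooted NJ tree, stored rooted at the final three-way join.

    ``support`` maps canonical nontrivial splits (the side not containing the
    first leaf label) to bootstrap proportions; None until bootstrapping.
    """

    root: _Node
    labels: list[str]
    support: dict[frozenset, float] | None = None

    def _canon(self, side: frozenset) -> frozenset:
        all_leaves = frozenset(self.labels)
        return side if self.labels[0] not in side else all_leaves - side

    def splits(self) -> set[frozenset]:
        """Canonical nontrivial bipartitions induced by internal edges."""
        out = set()
        all_leaves = frozenset(self.labels)

        def walk(node):
            for child, _ in node.children:
                lv = child.leaves()
                if 1 < len(lv) < len(all_leaves) - 1:
                    out.add(self._canon(lv))
                walk(child)
        walk(self.root)
        return out

    def focal_sides(self, focal: str) -> list[tuple[frozenset, float | None]]:
        """For every internal edge, the bipartition side containing ``focal``
        (if it has >= 2 leaves), with that split's support."""
        all_leaves = frozenset(self.labels)
        sides = []
        for split in self.splits():
            supp = None if self.support is None else self.support.get(split, 0.0)
            side = split if focal in split else all_leaves - split
            if len(side) >= 2:
                sides.append((side, supp))
        return sides

    def newick(self, with_support: bool = True) -> str:
        def fmt(node, length=None):
            if node.is_leaf:
                core = node.label
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                if with_support and self.support is not None:
                    lv = node.leaves()
                    if 1 < len(lv) < len(self.labels) - 1:
                        s = self.support.get(self._canon(lv))
                        if s is not None:
                            label = f"{s:.3f}"
                core = f"({inner}){label}"
            return core if length is None else f"{core}:{length:.6f}"
        return fmt(self.root) + ";"


def read_alignment(path) -> list[tuple[str, str]]:
    """Aligned FASTA -> list of (label, sequence); ragged input is an error."""
    recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise ValueError(f"{path}: no sequences")
    lengths = {len(s) for _, s in recs}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged alignment (lengths {sorted(lengths)})")
    return recs


def _encode(alignment: list[tuple[str, str]]) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels = [l for l, _ in alignment]
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for _, s in alignment])
    gap = np.zeros_like(mat, dtype=bool)
    for ch in GAP_CHARS:
        gap |= mat == ord(ch)
    return labels, mat, gap


def _pdist_from_encoded(mat: np.ndarray, gap: np.ndarray, cols=None) -> np.ndarray:
    if cols is not None:
        mat, gap = mat[:, cols], gap[:, cols]
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        ok = ~gap[i] & ~gap[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & ok
        comp = ok.sum(axis=1)
        if np.any(comp == 0):
            j = int(np.argmax(comp == 0)) + i + 1
            raise ValueError(f"no comparable columns between sequences {i} and {j}")
        d[i, i + 1:] = d[i + 1:, i] = diff.sum(axis=1) / comp
    return d


def p_distance_matrix(alignment: list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise proportion of differing sites, over columns where neither
    sequence has a gap (pairwise deletion)."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 taxa")
    lengths = {len(s) for _, s in alignment}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    labels, mat, gap = _encode(alignment)
    try:
        d = _pdist_from_encoded(mat, gap)
    except ValueError as exc:
        # re-raise naming the pair by label
        msg = str(exc)
        if "sequences" in msg:
            i, j = (int(x) for x in msg.rstrip().split("sequences ")[1].split(" and "))
            raise ValueError(f"no comparable columns between {labels[i]} and {labels[j]}") from None
        raise
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> SupportedTree:
    """Saitou–Nei NJ. Iteratively joins the pair minimising the Q-criterion;
    negative branch lengths are clamped to zero with the deficit moved to the
    sister edge. Exact on additive matrices."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = {i: _Node(label=l) for i, l in enumerate(dm.labels)}
    d = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, bq = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < bq - 1e-12:
                    bq, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        u = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        nodes[nxt] = u
        for k in active:
            if k in (i, j):
                continue
            duk = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
            d[nxt, k] = d[k, nxt] = duk
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    i, j, k = active
    li = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root = _Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return SupportedTree(root, list(dm.labels))


def bootstrap_support(alignment: list[tuple[str, str]], replicates: int = 1000,
                      seed: int = 0) -> SupportedTree:
    """NJ tree from the full alignment with split supports from column
    resampling. Deterministic given the seed."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    labels, mat, gap = _encode(alignment)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    L = mat.shape[1]
    tree = neighbor_joining(DistanceMatrix(labels, _pdist_from_encoded(mat, gap)))
    target = tree.splits()
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, L, L)
        try:
            d = _pdist_from_encoded(mat, gap, cols)
        except ValueError:
            continue  # a replicate without comparable columns carries no signal
        rep = neighbor_joining(DistanceMatrix(labels, d))
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    tree.support = {s: c / replicates for s, c in counts.items()}
    return tree


@dataclass
class DonorPlacement:
    placed: bool
    status: str                  # "placed" | "not_donor" | "unresolved"
    clade: frozenset = frozenset()
    support: float = 0.0

    def __bool__(self) -> bool:
        return self.placed


def donor_placement(tree: SupportedTree, group_of: dict[str, str], focal: str,
                    min_support: float = 0.70) -> DonorPlacement:
    """True iff the smallest supported clade containing the focal gene holds
    only non-metazoan leaves besides the focal gene itself.

    Considers every internal edge with bootstrap support >= ``min_support``;
    among the bipartition sides containing the focal leaf, the smallest wins.
    No sufficiently supported side at all -> unresolved (False).
    """
    if focal not in tree.labels:
        raise KeyError(f"focal label {focal!r} not in tree")
    if tree.support is None:
        raise ValueError("tree has no bootstrap supports; run bootstrap_support first")
    supported = [(side, s) for side, s in tree.focal_sides(focal)
                 if s is not None and s >= min_support]
    if not supported:
        return DonorPlacement(False, "unresolved")
    side, supp = min(supported, key=lambda t: (len(t[0]), sorted(t[0])))
    others = side - {focal}
    ok = all(group_of.get(l) == "non_metazoan" for l in others)
    return DonorPlacement(ok, "placed" if ok else "not_donor", side, supp)
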