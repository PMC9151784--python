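"""p-distances, neighbour joining, bootstrap supports and donor placement."""

import numpy as np
import pytest

from xenosynt.phylo import (DistanceMatrix, bootstrap_support, donor_placement,
                            neighbor_joining, p_distance_matrix)


def random_additive_tree(n_taxa, rng):
    """Random binary topology with positive branch lengths; returns the leaf
    distance matrix and the set of true nontrivial splits (canonical side
    excluding taxon 0)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-leaf star, attach remaining leaves to random edges
    nodes = {i: labels[i] for i in range(n_taxa)}
    edges = {}  # (u,v) -> length, undirected keys sorted
    nxt = n_taxa

    def add_edge(u, v, ln):
        edges[(min(u, v), max(u, v))] = ln

    center = nxt
    nxt += 1
    for i in range(3):
        add_edge(i, center, float(rng.uniform(0.2, 1.0)))
    for leaf in range(3, n_taxa):
        e = list(edges)[int(rng.integers(len(edges)))]
        ln = edges.pop(e)
        mid = nxt
        nxt += 1
        split = float(rng.uniform(0.2, 0.8))
        add_edge(e[0], mid, ln * split)
        add_edge(e[1], mid, ln * (1 - split))
        add_edge(leaf, mid, float(rng.uniform(0.2, 1.0)))
    # all-pairs distances over the tree
    import collections
    adj = collections.defaultdict(list)
    for (u, v), ln in edges.items():
        adj[u].append((v, ln))
        adj[v].append((u, ln))
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    # true splits: remove each internal edge, collect leaf side
    splits = set()
    for (u, v) in edges:
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, _ in adj[x]:
                if y != v and y not in seen and (min(x, y), max(x, y)) != (min(u, v), max(u, v)):
                    seen.add(y)
                    stack.append(y)
        side = frozenset(labels[i] for i in seen if i < n_taxa)
        if 1 < len(side) < n_taxa - 1:
            if labels[0] in side:
                side = frozenset(labels) - side
            splits.add(side)
    return DistanceMatrix(labels, d), splits


class TestPDistance:
    def test_identical_and_quarter(self):
        dm = p_distance_matrix([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGA")])
        assert dm.d[0, 1] == 0.0
        assert dm.d[0, 2] == 0.25

    def test_pairwise_deletion(self):
        dm = p_distance_matrix([("a", "AC-T"), ("b", "ACGT"), ("c", "ACGT")])
        assert dm.d[0, 1] == 0.0  # 3 comparable sites, all equal

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            p_distance_matrix([("a", "ACGT"), ("b", "ACG"), ("c", "ACGT")])

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            p_distance_matrix([("a", "AC--"), ("b", "--GT"), ("c", "ACGT")])


class TestNeighborJoining:
    def test_four_taxon_additive(self):
        # d(AB)=2, d(CD)=2, all cross distances 4 -> split AB|CD, internal edge 2
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert tree.splits() == {frozenset({"C", "D"})}

    def test_three_taxa_lengths(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {c.label: ln for c, ln in tree.root.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 2.0})

    def test_zero_matrix_star(self):
        d = np.zeros((4, 4))
        tree = neighbor_joining(DistanceMatrix(list("abcd"), d))
        total = 0.0

        def walk(n):
            nonlocal total
            for c, ln in n.children:
                total += ln
                walk(c)
        walk(tree.root)
        assert total == 0.0

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            dm, true_splits = random_additive_tree(n, rng)
            assert neighbor_joining(dm).splits() == true_splits

    def test_leaf_relabelling_invariance(self):
        rng = np.random.default_rng(23)
        dm, _ = random_additive_tree(6, rng)
        perm = rng.permutation(6)
        dm2 = DistanceMatrix([dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)])
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm2)

        def total_len(t):
            s = 0.0

            def walk(n):
                nonlocal s
                for c, ln in n.children:
                    s += ln
                    walk(c)
            walk(t.root)
            return s
        assert total_len(t1) == pytest.approx(total_len(t2))

        def norm(tree):
            # canonicalize against a fixed leaf, independent of label order
            leaves = frozenset(tree.labels)
            return {s if "t0" not in s else leaves - s for s in tree.splits()}
        assert norm(t1) == norm(t2)


def two_clade_alignment(rng, n_per_clade=4, length=500):
    from xenosynt.simulate import AA, _mutate, _random_seq
    root = _random_seq(rng, length, AA)
    anc1 = _mutate(root, 0.4, rng, AA)
    anc2 = _mutate(root, 0.4, rng, AA)
    recs = []
    for i in range(n_per_clade):
        recs.append((f"x{i}", _mutate(anc1, 0.05, rng, AA)))
    for i in range(n_per_clade):
        recs.append((f"y{i}", _mutate(anc2, 0.05, rng, AA)))
    return recs


class TestBootstrap:
    def test_strong_split_high_support(self):
        rng = np.random.default_rng(31)
        recs = two_clade_alignment(rng)
        tree = bootstrap_support(recs, replicates=100, seed=2)
        split = frozenset({"y0", "y1", "y2", "y3"})
        assert tree.support[split] >= 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(37)
        recs = two_clade_alignment(rng, n_per_clade=3, length=200)
        t1 = bootstrap_support(recs, replicates=50, seed=9)
        t2 = bootstrap_support(recs, replicates=50, seed=9)
        assert t1.support == t2.support

    def test_single_replicate_binary_supports(self):
        rng = np.random.default_rng(41)
        recs = two_clade_alignment(rng, n_per_clade=3, length=200)
        tree = bootstrap_support(recs, replicates=1, seed=3)
        assert set(tree.support.values()) <= {0.0, 1.0}

    def test_replicates_domain(self):
        with pytest.raises(ValueError):
            bootstrap_support([("a", "AA"), ("b", "AA"), ("c", "AA")], replicates=0)


class TestDonorPlacement:
    def make_tree(self, rng, focal_with="bacteria"):
        from xenosynt.simulate import AA, _mutate, _random_seq
        root = _random_seq(rng, 400, AA)
        banc, manc = _mutate(root, 0.4, rng, AA), _mutate(root, 0.4, rng, AA)
        focal_src = banc if focal_with == "bacteria" else manc
        recs = [("focal", _mutate(focal_src, 0.05, rng, AA))]
        groups = {"focal": "metazoan"}
        for i in range(4):
            recs.append((f"b{i}", _mutate(banc, 0.06, rng, AA)))
            groups[f"b{i}"] = "non_metazoan"
            recs.append((f"m{i}", _mutate(manc, 0.06, rng, AA)))
            groups[f"m{i}"] = "metazoan"
        return bootstrap_support(recs, replicates=100, seed=5), groups

    def test_focal_in_bacterial_clade(self):
        tree, groups = self.make_tree(np.random.default_rng(43))
        assert donor_placement(tree, groups, "focal").placed

    def test_focal_among_metazoans(self):
        tree, groups = self.make_tree(np.random.default_rng(47), focal_with="metazoa")
        res = donor_placement(tree, groups, "focal")
        assert not res.placed and res.status == "not_donor"

    def test_unresolved_when_no_support(self):
        tree, groups = self.make_tree(np.random.default_rng(53))
        res = donor_placement(tree, groups, "focal", min_support=1.01)
        assert not res.placed and res.status == "unresolved"

    def test_missing_focal(self):
        tree, groups = self.make_tree(np.random.default_rng(59))
        with pytest.raises(KeyError):
            donor_placement(tree, groups, "ghost")

    def test_all_panel_events_confirm_bacterial_origin(self, panel_bundle, panel_result):
        confident_ogs = {c.hgt_orthogroup for c in panel_result.confident}
        for eid, (recs, groups) in panel_bundle.alignments.items():
            if f"OGH_{eid}" not in confident_ogs:
                continue
            tree = bootstrap_support(recs, replicates=100, seed=13)
            assert donor_placement(tree, groups, recs[0][0]).placed
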