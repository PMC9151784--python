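"""Flank extraction, block matching and cross-species HGT event calling."""

import numpy as np
import pandas as pd
import pytest

from xenosynt.alien import AlienIndexRecord
from xenosynt.io import GeneModel, GenomeAnnotation, OrthogroupMap
from xenosynt.microsynteny import (FlankBlock, block_match, call_hgt_events,
                                   expression_summary, extract_flanks,
                                   intron_status)
from xenosynt.pipeline import run_hgt_pipeline
from xenosynt.simulate import simulate_dataset


def ann_with_genes(n, species="sp", scaffold="s1"):
    genes = [GeneModel(f"{species}_g{i}", scaffold, 1000 * i + 1, 1000 * i + 500, "+", 1)
             for i in range(n)]
    return GenomeAnnotation(species, {scaffold: 1000 * n + 1000}, genes)


def cand(gene_id, donor="Bacillus_subtilis"):
    return AlienIndexRecord(gene_id, 1.0, 1e-80, 184.2, donor, True)


class TestExtractFlanks:
    def test_boundary_truncation(self):
        ann = ann_with_genes(10)
        b = extract_flanks(ann, "sp_g2", width=5)
        assert b.upstream == ["sp_g1", "sp_g0"]          # nearest first
        assert b.downstream == [f"sp_g{i}" for i in range(3, 8)]

    def test_sole_gene_is_lonely(self):
        ann = ann_with_genes(1)
        assert extract_flanks(ann, "sp_g0").lonely

    def test_zero_width(self):
        ann = ann_with_genes(5)
        assert extract_flanks(ann, "sp_g2", width=0).lonely

    def test_unknown_gene(self):
        with pytest.raises(KeyError):
            extract_flanks(ann_with_genes(3), "nope")


class TestBlockMatch:
    def test_intersection(self):
        a = FlankBlock("x", [], [], frozenset({"A", "B", "C"}))
        b = FlankBlock("y", [], [], frozenset({"B", "C", "D"}))
        assert block_match(a, b, 2) == (2, True)

    def test_disjoint(self):
        a = FlankBlock("x", [], [], frozenset({"A"}))
        b = FlankBlock("y", [], [], frozenset({"B"}))
        assert block_match(a, b, 1) == (0, False)

    def test_species_specific_flanks_never_match(self):
        a = FlankBlock("x", [], [], frozenset())
        assert block_match(a, a, 1) == (0, False)


class TestIntronStatus:
    @pytest.mark.parametrize("exons,expected", [(1, False), (2, True), (5, True)])
    def test_exon_rule(self, exons, expected):
        ann = GenomeAnnotation("sp", {"s1": 10000},
                               [GeneModel("g", "s1", 1, 500, "+", exons)])
        assert intron_status(ann, "g") is expected


def three_species_setup(matched=3):
    """Three single-scaffold species, each carrying the candidate 'X' with
    flanking genes; `matched` species share flank orthogroups."""
    annotations, candidates = {}, {}
    assignments = {}
    for s in range(3):
        sp = f"sp{s}"
        genes = []
        for i in range(5):
            gid = f"{sp}_f{i}" if i != 2 else f"{sp}_X"
            genes.append(GeneModel(gid, "s1", 1000 * i + 1, 1000 * i + 500, "+", 1))
        annotations[sp] = GenomeAnnotation(sp, {"s1": 9000}, genes)
        candidates[sp] = [cand(f"{sp}_X")]
        assignments[f"{sp}_X"] = "OGX"
        for i in (0, 1, 3, 4):
            og = f"OGF{i}" if s < matched else f"OGF{i}_{sp}"
            assignments[f"{sp}_f{i}"] = og
    return annotations, candidates, OrthogroupMap(assignments)


class TestCallHGTEvents:
    def test_three_matched_species_confident(self):
        ann, cands, om = three_species_setup(matched=3)
        calls = call_hgt_events(cands, ann, om)
        assert len(calls) == 1 and calls[0].confident
        assert calls[0].supporting_species == 3

    def test_two_matched_species_not_confident(self):
        ann, cands, om = three_species_setup(matched=2)
        calls = call_hgt_events(cands, ann, om)
        assert len(calls) == 1 and not calls[0].confident
        assert calls[0].supporting_species == 2

    def test_species_order_invariance(self):
        ann, cands, om = three_species_setup(matched=3)
        rev_c = dict(reversed(list(cands.items())))
        a = call_hgt_events(cands, ann, om)
        b = call_hgt_events(rev_c, ann, om)
        assert [(c.event_id, c.confident, c.supporting_species) for c in a] == \
               [(c.event_id, c.confident, c.supporting_species) for c in b]

    def test_species_specific_candidate_is_singleton(self):
        ann, cands, om = three_species_setup(matched=3)
        om.assignments.pop("sp0_X")
        calls = call_hgt_events(cands, ann, om)
        singles = [c for c in calls if c.event_id.startswith("singleton:")]
        assert len(singles) == 1 and not singles[0].confident

    def test_panel_recovers_planted_events_exactly(self, panel_bundle, panel_result):
        confident = panel_result.confident
        truth = panel_bundle.truth.planted_events
        got = {frozenset((sp, g) for sp in c.members for g in c.members[sp])
               for c in confident}
        want = {frozenset((sp, g) for sp in e.carriers for g in e.genes[sp])
                for e in truth}
        assert got == want

    def test_panel_intron_split_matches_planted(self, panel_bundle, panel_result):
        intronless = sum(c.intronless_count for c in panel_result.confident)
        introned = sum(c.introned_count for c in panel_result.confident)
        want_less = sum(1 for e in panel_bundle.truth.planted_events
                        for g, has in e.intron_flags.items() if not has)
        assert (intronless, introned) == (want_less, 65 - want_less)

    def test_ablated_event_demoted_exactly(self, panel_cfg):
        cfg = dict(panel_cfg)
        cfg["ablate_flanks"] = ["ev04_sulfatase_maturase"]
        res = run_hgt_pipeline(simulate_dataset(cfg, 3))
        confident_ogs = {c.hgt_orthogroup for c in res.confident}
        all_ogs = {c.hgt_orthogroup for c in res.calls}
        assert "OGH_ev04_sulfatase_maturase" in all_ogs
        assert "OGH_ev04_sulfatase_maturase" not in confident_ogs
        assert len(confident_ogs) == 10  # every other event stays confident


class TestExpressionSummary:
    def test_all_zero_row_not_expressed(self):
        expr = pd.DataFrame([[0.0, 0.0, 0.0]], index=["g1"], columns=list("abc"))
        flags, _ = expression_summary(expr, ["g1"])
        assert flags == {"g1": False}

    def test_expressed_with_z_pattern(self):
        expr = pd.DataFrame([[0.0, 0.0, 5.0, 5.0]], index=["g1"], columns=list("abcd"))
        flags, z = expression_summary(expr, ["g1"], tpm_min=1.0)
        assert flags["g1"]
        assert np.all(z.loc["g1", ["a", "b"]] < 0) and np.all(z.loc["g1", ["c", "d"]] > 0)

    def test_absent_gene_flagged_with_warning(self, caplog):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=list("ab"))
        with caplog.at_level("WARNING"):
            flags, _ = expression_summary(expr, ["g1", "ghost"])
        assert flags["ghost"] is False
        assert any("ghost" in r.message for r in caplog.records)

    def test_planted_stage_bias_gives_positive_z(self, panel_bundle, panel_cfg):
        expr = panel_bundle.expression
        biased = panel_cfg["expression"]["biased_samples"]
        for e in panel_bundle.truth.planted_events:
            if e.event_id not in panel_cfg["expression"]["expressed_events"]:
                continue
            genes = [g for sp in e.carriers for g in e.genes[sp]]
            flags, z = expression_summary(expr, genes)
            assert all(flags[g] for g in genes)
            assert (z[biased].to_numpy() > 0).all()
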