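"""Duplication-node calling, event filtering criteria, WGD assignment and
retained-gene summaries."""

import itertools

import numpy as np
import pytest

from wgdkit import retention as R
from wgdkit.io import parse_tree, leaf_species
from wgdkit.simulate import SimulationParams, WgdEvent, simulate_genome


def _candidates(newick, og="OG1"):
    return R.find_duplication_nodes(parse_tree(newick), og)


class TestFindDuplicationNodes:
    def test_species_overlap_is_duplication(self):
        events = _candidates("((MCA|g1,MCA|g2)0.9,EG|g3);")
        assert len(events) == 1
        assert events[0].support == 0.9

    def test_no_overlap_no_duplication(self):
        assert _candidates("((MCA|g1,EG|g2)0.9,VV|g3);") == []

    def test_percent_support_normalised(self):
        events = _candidates("((MCA|g1,MCA|g2)95,EG|g3);")
        assert events[0].support == 0.95

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_node_intersection_check(self, seed, small_dataset):
        # exhaustive check on simulator trees: a binary node is called iff
        # its child clades share a species
        ogs = sorted(small_dataset.gene_trees)
        og = ogs[seed % len(ogs)]
        tree = parse_tree(small_dataset.gene_trees[og])
        called = {e.node_id for e in R.find_duplication_nodes(tree, og)}
        expected = set()
        for idx, node in enumerate(tree.preorder_internal_node_iter()):
            clades = [
                {leaf_species(l.taxon.label) for l in child.leaf_iter()}
                for child in node.child_nodes()
            ]
            if any(a & b for a, b in itertools.combinations(clades, 2)):
                expected.add(f"n{idx}")
        assert called == expected

    def test_unrooted_tree_rejected(self):
        tree = parse_tree("((MCA|g1,MCA|g2)0.9,EG|g3);")
        tree.is_rooted = False
        with pytest.raises(R.RetentionError, match="midpoint"):
            R.find_duplication_nodes(tree)


GENUS = ("MCA", "MDO")


def _filtered(newick, members, **kw):
    events = _candidates(newick)
    defaults = dict(
        orthogroup_members={"OG1": members},
        focal_species="MCA",
        focal_genus=GENUS,
    )
    defaults.update(kw)
    return R.filter_events(events, **defaults)


class TestFilterEvents:
    def test_small_orthogroup_rejected(self):
        events = _filtered(
            "((MCA|g1,MCA|g2)0.9,EG|g3);", {"MCA": ["g1", "g2"], "EG": ["g3"]}
        )
        assert events[0].status == R.REJECTED_COMPOSITION

    def test_support_exactly_half_kept(self):
        events = _filtered(
            "(((MCA|g1,MDO|g2)0.8,(MCA|g3,MDO|g4)0.8)0.5,EG|g5);",
            {"MCA": ["g1", "g3"], "MDO": ["g2", "g4"], "EG": ["g5"]},
        )
        statuses = {e.node_id: e.status for e in events}
        assert "candidate" in statuses.values()

    def test_low_support_rejected(self):
        events = _filtered(
            "(((MCA|g1,MDO|g2)0.8,(MCA|g3,MDO|g4)0.8)0.4,EG|g5);",
            {"MCA": ["g1", "g3"], "MDO": ["g2", "g4"], "EG": ["g5"]},
        )
        assert R.REJECTED_SUPPORT in {e.status for e in events}

    def test_all_focal_genus_rejected(self):
        events = _filtered(
            "((MCA|g1,MCA|g2)0.9,(MCA|g3,(MDO|g4,MDO|g5)0.9)0.9);",
            {"MCA": ["g1", "g2", "g3"], "MDO": ["g4", "g5"]},
        )
        assert {e.status for e in events} == {R.REJECTED_COMPOSITION}

    def test_child_without_focal_gene_rejected(self):
        events = _filtered(
            "((MDO|g1,(MDO|g2,MDO|g3)0.9)0.9,(EG|g4,MCA|g5)0.9);",
            {"MDO": ["g1", "g2", "g3"], "EG": ["g4"], "MCA": ["g5"]},
        )
        assert all(e.status == R.REJECTED_COMPOSITION for e in events)


def _accepted_pipeline_event(mean_ks=0.3, wgd="sigma"):
    event = R.DuplicationEvent(
        "OG1", "n0", 0.9,
        frozenset({"MCA|a1", "MDO|b1"}), frozenset({"MCA|a2", "MDO|b2"}),
        frozenset({"MCA", "MDO"}), frozenset({"MCA", "MDO"}),
        mean_ks=mean_ks, wgd=wgd, status=R.ACCEPTED,
    )
    return event


class TestTandemAndKs:
    def _event(self):
        e = R.DuplicationEvent(
            "OG1", "n0", 0.9,
            frozenset({"MCA|a1"}), frozenset({"MCA|a2"}),
            frozenset({"MCA"}), frozenset({"MCA"}),
            status="candidate",
        )
        return e

    def test_tandem_cross_pair_rejected(self):
        events = R.drop_tandem_events(
            [self._event()], {frozenset(("a1", "a2"))}, "MCA"
        )
        assert events[0].status == R.REJECTED_TANDEM

    def test_non_tandem_kept(self):
        events = R.drop_tandem_events([self._event()], set(), "MCA")
        assert events[0].status == "candidate"

    def test_mean_ks_is_arithmetic_mean(self):
        e = R.DuplicationEvent(
            "OG1", "n0", 0.9,
            frozenset({"MCA|a1", "MCA|a2"}), frozenset({"MCA|b1"}),
            frozenset({"MCA"}), frozenset({"MCA"}),
            status="candidate",
        )
        table = {frozenset(("a1", "b1")): 0.2, frozenset(("a2", "b1")): 0.4}
        out = R.event_mean_ks(
            [e], lambda a, b: table.get(frozenset((a, b))), "MCA"
        )
        assert out[0].mean_ks == pytest.approx(0.3)
        assert out[0].status == "candidate"

    def test_out_of_bounds_mean_rejected(self):
        e = self._event()
        out = R.event_mean_ks([e], lambda a, b: 1.6, "MCA")
        assert out[0].status == R.REJECTED_KS

    def test_no_valid_pair_rejected(self):
        e = self._event()
        out = R.event_mean_ks([e], lambda a, b: None, "MCA")
        assert out[0].status == R.REJECTED_KS


class TestAssignToWgd:
    def _event(self, mean_ks=0.3):
        return R.DuplicationEvent(
            "OG1", "n0", 0.9,
            frozenset({"MCA|a1"}), frozenset({"MCA|a2"}),
            frozenset({"MCA"}), frozenset({"MCA"}),
            mean_ks=mean_ks, status="candidate",
        )

    def test_young_anchor_gives_sigma(self):
        out = R.assign_to_wgd(
            [self._event()], {frozenset(("a1", "a2")): ("young", 0.3)}, "MCA"
        )
        assert out[0].wgd == "sigma" and out[0].status == R.ACCEPTED

    def test_no_anchor_is_nonsyntenic(self):
        out = R.assign_to_wgd([self._event()], {}, "MCA")
        assert out[0].status == R.REJECTED_NONSYNTENIC

    def test_conflict_resolved_by_nearest_ks(self):
        e = R.DuplicationEvent(
            "OG1", "n0", 0.9,
            frozenset({"MCA|a1", "MCA|a2"}), frozenset({"MCA|b1"}),
            frozenset({"MCA"}), frozenset({"MCA"}),
            mean_ks=1.0, status="candidate",
        )
        anchors = {
            frozenset(("a1", "b1")): ("young", 0.3),
            frozenset(("a2", "b1")): ("old", 1.05),
        }
        out = R.assign_to_wgd([e], anchors, "MCA")
        assert out[0].wgd == "rho"


class TestRetainedGeneSets:
    def test_printed_ratio_examples(self):
        assert R.round_half_up_percent(8608, 40938) == 21.0
        assert R.round_half_up_percent(3858, 40938) == 9.4

    def test_empty_events(self):
        summary = R.retained_gene_sets([], "MCA", 100)
        assert summary.sigma_genes == set() and summary.rho_genes == set()
        assert summary.to_dict()["sigma"]["percent"] == 0.0

    def test_union_deduplicates_shared_genes(self):
        e1 = _accepted_pipeline_event(wgd="sigma")
        e2 = _accepted_pipeline_event(wgd="rho")
        summary = R.retained_gene_sets([e1, e2], "MCA", 10)
        assert summary.sigma_genes == {"a1", "a2"}
        assert summary.rho_genes == {"a1", "a2"}
        assert summary.union_genes == {"a1", "a2"}

    def test_every_event_has_one_terminal_status(self, small_dataset):
        from wgdkit.pipeline import Pipeline, PipelineConfig

        cfg = PipelineConfig(simulate=small_dataset.params)
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            pipe = Pipeline(cfg, tmp)
            events = pipe.events()
        statuses = {e.status for e in events}
        assert "candidate" not in statuses
        valid = {
            R.ACCEPTED, R.REJECTED_SUPPORT, R.REJECTED_TANDEM, R.REJECTED_KS,
            R.REJECTED_COMPOSITION, R.REJECTED_NONSYNTENIC,
        }
        assert statuses <= valid
        for e in events:
            if e.status == R.ACCEPTED:
                assert e.support >= 0.5
                assert 0.05 < e.mean_ks < 1.50
                assert e.wgd in ("sigma", "rho")
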