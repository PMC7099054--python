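"""Lineage trees: parsimony, egression calling, suspect-lineage discard."""

import numpy as np
import pandas as pd
import pytest

from bcrpipe import lineage
from bcrpipe.clonal import cluster_clones
from bcrpipe.lineage import (
    build_lineage,
    call_egressions,
    discard_suspect_lineages,
    find_multicompartment_clones,
    read_gml,
    write_gml,
)

GERMLINE = "ACGTACGTACGTACGTACGTACGTACGTACGT"  # 32 nt stand-in V
TAIL = "GGGCCCTTT"  # shared junction/constant stand-in


def _mutate(seq, positions, base=None):
    out = list(seq)
    for p in positions:
        out[p] = base or ("A" if out[p] != "A" else "C")
    return "".join(out)


def _members(rows):
    return pd.DataFrame(
        [
            {
                "sequence_id": sid,
                "compartment": comp,
                "sequence": seq,
                "duplicate_count": dup,
            }
            for sid, comp, seq, dup in rows
        ]
    )


class TestMulticompartmentClones:
    def test_requires_both_compartments(self):
        records = pd.DataFrame(
            {
                "sequence_id": ["a", "b", "c"],
                "donor_id": "d",
                "compartment": ["blood", "blood", "synovium"],
                "v_call": "IGHV1-2*01",
                "j_call": "IGHJ4",
                "junction_aa": ["CARDY", "CARDY", "CWWWF"],
                "junction_length": [5, 5, 5],
                "duplicate_count": 1,
            }
        )
        clusters = cluster_clones(records)
        assert find_multicompartment_clones(clusters) == []

    def test_single_member_each_side_included(self):
        records = pd.DataFrame(
            {
                "sequence_id": ["a", "b"],
                "donor_id": "d",
                "compartment": ["blood", "synovium"],
                "v_call": "IGHV1-2*01",
                "j_call": "IGHJ4",
                "junction_aa": ["CARDY", "CARDY"],
                "junction_length": [5, 5],
                "duplicate_count": 1,
            }
        )
        clusters = cluster_clones(records)
        assert len(find_multicompartment_clones(clusters)) == 1


class TestBuildLineage:
    def test_two_independent_mutations_give_star(self):
        s1 = _mutate(GERMLINE, [3]) + TAIL
        s2 = _mutate(GERMLINE, [10]) + TAIL
        tree = build_lineage(
            _members([("s1", "blood", s1, 2), ("s2", "blood", s2, 2)]), GERMLINE
        )
        assert tree.parsimony_score == 2
        assert set(tree.graph.successors("germline")) == {"s1", "s2"}

    def test_nested_mutations_give_chain(self):
        s1 = _mutate(GERMLINE, [3]) + TAIL
        s2 = _mutate(GERMLINE, [3, 10]) + TAIL
        tree = build_lineage(
            _members([("s1", "blood", s1, 2), ("s2", "blood", s2, 2)]), GERMLINE
        )
        assert tree.parsimony_score == 2
        assert list(tree.graph.successors("germline")) == ["s1"]
        assert list(tree.graph.successors("s1")) == ["s2"]

    def test_identical_duplicates_collapse_to_one_node(self):
        seq = _mutate(GERMLINE, [5]) + TAIL
        tree = build_lineage(
            _members([("a", "blood", seq, 2), ("b", "blood", seq, 3)]), GERMLINE
        )
        observed = [
            d for _, d in tree.graph.nodes(data=True) if d["tissue"] == "blood"
        ]
        assert len(observed) == 1
        assert observed[0]["duplicate_count"] == 5

    def test_single_member_trivial_tree(self):
        seq = _mutate(GERMLINE, [5]) + TAIL
        tree = build_lineage(_members([("a", "blood", seq, 2)]), GERMLINE)
        assert tree.warnings
        assert tree.graph.number_of_nodes() == 2

    def test_mutation_counts_annotated(self):
        s1 = _mutate(GERMLINE, [3, 7, 9]) + TAIL
        tree = build_lineage(_members([("s1", "synovium", s1, 2)]), GERMLINE)
        assert tree.graph.nodes["s1"]["mutation_count"] == 3
        assert tree.graph.nodes["germline"]["mutation_count"] == 0

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_heuristic_matches_exhaustive_optimum(self, n_leaves):
        """Stepwise-addition + re-insertion reaches the exhaustive parsimony
        optimum on random small clones."""
        rng = np.random.default_rng(n_leaves)
        rows = []
        for i in range(n_leaves):
            k = int(rng.integers(1, 5))
            positions = rng.choice(len(GERMLINE), size=k, replace=False)
            rows.append((f"s{i}", "blood", _mutate(GERMLINE, positions) + TAIL, 2))
        members = _members(rows)
        exhaustive = build_lineage(members, GERMLINE, max_exhaustive=7)
        heuristic = build_lineage(members, GERMLINE, max_exhaustive=1)
        assert heuristic.parsimony_score == exhaustive.parsimony_score

    def test_score_never_exceeds_star_topology(self):
        rng = np.random.default_rng(99)
        rows = []
        for i in range(6):
            positions = rng.choice(len(GERMLINE), size=3, replace=False)
            rows.append((f"s{i}", "blood", _mutate(GERMLINE, positions) + TAIL, 2))
        tree = build_lineage(_members(rows), GERMLINE)
        star_score = sum(
            sum(a != b for a, b in zip(seq[: len(GERMLINE)], GERMLINE))
            for _, _, seq, _ in rows
        )
        assert tree.parsimony_score <= star_score


class TestEgression:
    def test_all_blood_tree_has_no_events(self):
        s1 = _mutate(GERMLINE, [3]) + TAIL
        s2 = _mutate(GERMLINE, [3, 10]) + TAIL
        tree = build_lineage(
            _members([("s1", "blood", s1, 2), ("s2", "blood", s2, 2)]), GERMLINE
        )
        assert call_egressions(tree) == []

    def test_synovium_to_blood_chain_is_one_event(self):
        parent = _mutate(GERMLINE, [3]) + TAIL
        child = _mutate(GERMLINE, [3, 10]) + TAIL
        tree = build_lineage(
            _members([("p", "synovium", parent, 2), ("c", "blood", child, 2)]),
            GERMLINE,
        )
        events = call_egressions(tree)
        assert len(events) == 1
        assert events[0].source_id == "p" and events[0].target_id == "c"

    def test_blood_to_synovium_is_not_an_event(self):
        parent = _mutate(GERMLINE, [3]) + TAIL
        child = _mutate(GERMLINE, [3, 10]) + TAIL
        tree = build_lineage(
            _members([("p", "blood", parent, 2), ("c", "synovium", child, 2)]),
            GERMLINE,
        )
        assert call_egressions(tree) == []

    def test_event_through_inferred_node(self):
        """A synovial ancestor and blood descendant separated by an inferred
        intermediate still count as one egression."""
        parent = _mutate(GERMLINE, [3]) + TAIL
        mid_a = _mutate(GERMLINE, [3, 10, 15]) + TAIL
        mid_b = _mutate(GERMLINE, [3, 10, 20]) + TAIL
        tree = build_lineage(
            _members(
                [
                    ("p", "synovium", parent, 2),
                    ("a", "blood", mid_a, 2),
                    ("b", "blood", mid_b, 2),
                ]
            ),
            GERMLINE,
        )
        events = call_egressions(tree)
        sources = {e.source_id for e in events}
        assert sources <= {"p"} and len(events) >= 1

    def test_planted_egression_recovered_via_pipeline(self, reference):
        from bcrpipe.pipeline import run_paired_pipeline
        from bcrpipe.simulate import PairedCompartmentSpec, simulate_paired_compartments

        spec = PairedCompartmentSpec(egression_clones=2, n_reads=800)
        records = run_paired_pipeline(spec, seed=17, reference=reference)
        clusters = cluster_clones(records)
        clones = find_multicompartment_clones(clusters)
        events_by_clone = {}
        for clone_id in clones:
            members = clusters.records[clusters.records["clone_id"] == clone_id]
            germline_v = reference[members["v_call"].iloc[0]].nt_sequence
            tree = build_lineage(members, germline_v, clone_id=clone_id)
            events_by_clone[clone_id] = call_egressions(tree)
        with_events = [c for c, ev in events_by_clone.items() if ev]
        assert len(with_events) == 2


class TestDiscardAndExport:
    def _tree(self, sid="s1", tissue="blood"):
        seq = _mutate(GERMLINE, [4]) + TAIL
        return build_lineage(_members([(sid, tissue, seq, 2)]), GERMLINE,
                             clone_id="clone1")

    def test_no_flags_keeps_everything(self):
        trees = [self._tree("a"), self._tree("b")]
        kept, discarded = discard_suspect_lineages(trees, set())
        assert len(kept) == 2 and not discarded

    def test_single_flagged_member_discards_whole_tree(self):
        trees = [self._tree("a"), self._tree("b")]
        kept, discarded = discard_suspect_lineages(trees, {"b"})
        assert [t for t in kept] == trees[:1]
        assert discarded == ["clone1"]

    def test_all_flagged_empty_output(self):
        trees = [self._tree("a")]
        kept, discarded = discard_suspect_lineages(trees, {"a"})
        assert kept == [] and len(discarded) == 1

    def test_gml_round_trip(self, tmp_path):
        parent = _mutate(GERMLINE, [3]) + TAIL
        child = _mutate(GERMLINE, [3, 10]) + TAIL
        tree = build_lineage(
            _members([("p", "synovium", parent, 2), ("c", "blood", child, 3)]),
            GERMLINE,
            clone_id="cloneX",
        )
        path = tmp_path / "tree.gml"
        write_gml(tree, path)
        again = read_gml(path)
        assert again.clone_id == "cloneX"
        assert again.parsimony_score == tree.parsimony_score
        assert set(again.graph.nodes) == set(tree.graph.nodes)
        for node in tree.graph.nodes:
            for attr in ("tissue", "mutation_count", "duplicate_count", "sequence"):
                assert again.graph.nodes[node][attr] == tree.graph.nodes[node][attr]
        assert set(again.graph.edges) == set(tree.graph.edges)
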