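"""B-cell clone lineage trees and synovium-to-blood egression calling.

Multi-compartmental clones (members in both blood and synovium of one donor)
are reconstructed as maximum-parsimony trees rooted at the germline V: for
clones with at most ``max_exhaustive`` unique sequences every tree topology is
scored (Fitch counting) and the optimum kept; larger clones use stepwise
addition followed by leaf re-insertion refinement. Ancestral sequences are
reconstructed, zero-change edges collapsed (an inferred node identical to an
observed sequence takes that sequence's identity), so observed sequences may
sit at internal nodes, as in genotype-network style BCR lineages.

The junction has no germline state; junction positions are treated as unknown
in the root and resolved by parsimony. Tissue is never imputed for inferred
nodes: an egression event is a transition from an observed synovial node to an
observed blood node connected directly or through inferred-only nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from bcrpipe.clonal import ClonalClusterSet

MAX_EXHAUSTIVE_LEAVES = 7

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 15}
_BIT_BASE = {1: "A", 2: "C", 4: "G", 8: "T"}


def find_multicompartment_clones(clusters: ClonalClusterSet) -> list[str]:
    """Clone ids with at least one blood and one synovial member."""
    present = clusters.records.groupby("clone_id")["compartment"].agg(set)
    return sorted(
        clone_id
        for clone_id, compartments in present.items()
        if {"blood", "synovium"} <= compartments
    )


# ---------------------------------------------------------------------------
# Fitch parsimony over leaf topologies


def _seq_to_bits(seq: str, columns: np.ndarray) -> np.ndarray:
    return np.array([_BASE_BITS.get(seq[c], 15) for c in columns], dtype=np.uint8)


def _fitch_sets(tree, leaf_bits: list[np.ndarray]):
    """Bottom-up Fitch: returns (state-set array, mutation count) plus the
    per-node set annotations as a nested structure mirroring the tree."""
    if isinstance(tree, int):
        return leaf_bits[tree], 0, tree
    left_bits, left_score, left_ann = _fitch_sets(tree[0], leaf_bits)
    right_bits, right_score, right_ann = _fitch_sets(tree[1], leaf_bits)
    inter = left_bits & right_bits
    union = left_bits | right_bits
    empty = inter == 0
    bits = np.where(empty, union, inter)
    score = left_score + right_score + int(empty.sum())
    return bits, score, (left_ann, right_ann, bits)


def _fitch_score(tree, leaf_bits: list[np.ndarray], root_bits: np.ndarray) -> int:
    bits, score, _ = _fitch_sets(tree, leaf_bits)
    return score + int(((bits & root_bits) == 0).sum())


def _insertions(tree, leaf: int):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        for sub in _insertions(tree[0], leaf):
            yield (sub, tree[1])
        for sub in _insertions(tree[1], leaf):
            yield (tree[0], sub)


def _all_topologies(n_leaves: int):
    """All rooted binary leaf topologies on leaves 0..n-1 (the root edge leads
    to the germline); (2n-3)!! trees for n >= 2."""

    def gen(k: int):
        if k == 1:
            yield 0
            return
        for tree in gen(k - 1):
            yield from _insertions(tree, k - 1)

    yield from gen(n_leaves)


def _leaves_of(tree) -> list[int]:
    return [tree] if isinstance(tree, int) else _leaves_of(tree[0]) + _leaves_of(tree[1])


def _best_topology_exhaustive(leaf_bits, root_bits):
    best, best_score = None, None
    for tree in _all_topologies(len(leaf_bits)):
        score = _fitch_score(tree, leaf_bits, root_bits)
        if best_score is None or score < best_score:
            best, best_score = tree, score
    return best, best_score


def _best_topology_heuristic(leaf_bits, root_bits, max_rounds: int = 5):
    """Stepwise addition, then repeated removal/re-insertion of each leaf."""
    n = len(leaf_bits)
    tree = 0
    for leaf in range(1, n):
        tree = min(
            _insertions(tree, leaf),
            key=lambda t: _fitch_score(t, leaf_bits, root_bits),
        )
    score = _fitch_score(tree, leaf_bits, root_bits)
    for _ in range(max_rounds):
        improved = False
        for leaf in range(n):
            pruned = _remove_leaf(tree, leaf)
            if pruned is None:
                continue
            candidate = min(
                _insertions(pruned, leaf),
                key=lambda t: _fitch_score(t, leaf_bits, root_bits),
            )
            cand_score = _fitch_score(candidate, leaf_bits, root_bits)
            if cand_score < score:
                tree, score = candidate, cand_score
                improved = True
        if not improved:
            break
    return tree, score


def _remove_leaf(tree, leaf: int):
    """Tree with one leaf pruned (None when the tree is that single leaf)."""
    if isinstance(tree, int):
        return None if tree == leaf else tree
    left, right = tree
    if left == leaf:
        return right
    if right == leaf:
        return left
    new_left = _remove_leaf(left, leaf)
    new_right = _remove_leaf(right, leaf)
    if new_left is None:
        return new_right
    if new_right is None:
        return new_left
    return (new_left, new_right)


# ---------------------------------------------------------------------------
# tree assembly


@dataclass
class LineageTree:
    """Rooted lineage tree; ``graph`` is a DiGraph directed away from the
    germline root. Node attributes: ``tissue`` (blood/synovium/germline/
    inferred), ``mutation_count``, ``duplicate_count``, ``sequence``."""

    clone_id: str
    graph: nx.DiGraph
    root: str
    parsimony_score: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_observed(self) -> int:
        return sum(
            1
            for _, d in self.graph.nodes(data=True)
            if d["tissue"] in ("blood", "synovium")
        )

    def observed_ids(self) -> set[str]:
        return {
            str(d.get("sequence_id", n))
            for n, d in self.graph.nodes(data=True)
            if d["tissue"] in ("blood", "synovium")
        }


def _assign_states(ann, root_state: np.ndarray):
    """Top-down Fitch assignment preferring the parent's state."""
    if isinstance(ann, int):
        return None
    left_ann, right_ann, bits = ann
    avail = bits & root_state
    pick = np.where(avail > 0, avail, bits).astype(np.uint8)
    # resolve to a single base: the lowest set bit of the available states
    state = (pick & (~pick + np.uint8(1))).astype(np.uint8)
    return state, left_ann, right_ann


def build_lineage(
    records: pd.DataFrame,
    germline_v: str,
    clone_id: str = "",
    max_exhaustive: int = MAX_EXHAUSTIVE_LEAVES,
) -> LineageTree:
    """Maximum-parsimony lineage tree for one clone.

    ``records`` are the clone's member sequences (one row per unique sequence
    and compartment, with ``sequence``, ``compartment``, ``duplicate_count``,
    ``sequence_id``); all member sequences must share one length. The tree is
    rooted at the germline V segment; junction/J positions are unknown in the
    root and resolved by parsimony.
    """
    members = (
        records.groupby(["sequence", "compartment"], as_index=False)
        .agg(
            sequence_id=("sequence_id", "first"),
            duplicate_count=("duplicate_count", "sum"),
        )
        .sort_values(["sequence", "compartment", "sequence_id"])
        .reset_index(drop=True)
    )
    warnings: list[str] = []
    lengths = members["sequence"].str.len()
    modal = int(lengths.mode().iloc[0])
    if (lengths != modal).any():
        warnings.append(f"dropped {int((lengths != modal).sum())} off-length members")
        members = members[lengths == modal].reset_index(drop=True)

    length = modal
    root_seq = germline_v + "N" * (length - len(germline_v))
    seqs = members["sequence"].tolist()

    graph = nx.DiGraph()
    root = "germline"

    def node_attrs(seq: str, tissue: str, sequence_id: str, dup: int) -> dict:
        v_part = seq[: len(germline_v)]
        mut = sum(a != b for a, b in zip(v_part, germline_v))
        return {
            "tissue": tissue,
            "sequence_id": sequence_id,
            "mutation_count": mut,
            "duplicate_count": dup,
            "sequence": seq,
        }

    graph.add_node(root, **{**node_attrs(root_seq, "germline", "germline", 0),
                            "mutation_count": 0})

    if len(members) == 0:
        return LineageTree(clone_id, graph, root, 0, warnings + ["empty clone"])
    if len(members) == 1:
        row = members.iloc[0]
        graph.add_node(
            row.sequence_id,
            **node_attrs(row.sequence, row.compartment, row.sequence_id,
                         int(row.duplicate_count)),
        )
        graph.add_edge(root, row.sequence_id)
        warnings.append("single-member clone: trivial tree")
        score = graph.nodes[row.sequence_id]["mutation_count"]
        return LineageTree(clone_id, graph, root, score, warnings)

    # variable columns only (wildcard root positions count when leaves vary)
    arr = np.array([list(s) for s in seqs])
    root_arr = np.array(list(root_seq))
    variable = np.nonzero(
        (arr != arr[0]).any(axis=0) | ((root_arr != arr[0]) & (root_arr != "N"))
    )[0]
    leaf_bits = [_seq_to_bits(s, variable) for s in seqs]
    root_bits = _seq_to_bits(root_seq, variable)

    if len(members) <= max_exhaustive:
        topology, score = _best_topology_exhaustive(leaf_bits, root_bits)
    else:
        topology, score = _best_topology_heuristic(leaf_bits, root_bits)

    # ancestral reconstruction over the variable columns
    _, _, ann = _fitch_sets(topology, leaf_bits)

    counter = itertools.count()
    # non-variable columns are identical across all leaves (and match the
    # germline wherever the root is not a wildcard): use them as the template
    base_chars = arr[0].copy()

    def realize(ann_node, parent_state: np.ndarray, parent_name: str) -> None:
        if isinstance(ann_node, int):
            row = members.iloc[ann_node]
            name = str(row.sequence_id)
            graph.add_node(
                name,
                **node_attrs(row.sequence, row.compartment, name,
                             int(row.duplicate_count)),
            )
            graph.add_edge(parent_name, name)
            return
        state, left_ann, right_ann = _assign_states(ann_node, parent_state)
        chars = base_chars.copy()
        chars[variable] = [_BIT_BASE[int(b)] for b in state]
        seq = "".join(chars)
        name = f"inferred_{next(counter)}"
        graph.add_node(name, **node_attrs(seq, "inferred", name, 0))
        graph.add_edge(parent_name, name)
        realize(left_ann, state, name)
        realize(right_ann, state, name)

    if isinstance(ann, int):  # n == 1 handled above; defensive
        realize(ann, root_bits, root)
    else:
        state, left_ann, right_ann = _assign_states(ann, root_bits)
        # the germline root adopts parsimony states at wildcard positions
        root_chars = base_chars.copy()
        wildcard = root_arr[variable] == "N"
        root_state = np.where(wildcard, state, root_bits)
        root_chars[variable] = [_BIT_BASE[int(b)] for b in root_state]
        graph.nodes[root]["sequence"] = "".join(root_chars)
        chars = base_chars.copy()
        chars[variable] = [_BIT_BASE[int(b)] for b in state]
        seq = "".join(chars)
        name = f"inferred_{next(counter)}"
        graph.add_node(name, **node_attrs(seq, "inferred", name, 0))
        graph.add_edge(root, name)
        realize(left_ann, state, name)
        realize(right_ann, state, name)

    _collapse_zero_edges(graph, root)
    return LineageTree(clone_id, graph, root, int(score), warnings)


def _collapse_zero_edges(graph: nx.DiGraph, root: str) -> None:
    """Contract zero-change edges: inferred nodes identical to their parent
    vanish; an inferred parent identical to an observed child is replaced by
    that child."""
    changed = True
    while changed:
        changed = False
        for parent, child in list(graph.edges()):
            if not graph.has_edge(parent, child):
                continue
            p, c = graph.nodes[parent], graph.nodes[child]
            if p["sequence"] != c["sequence"]:
                continue
            if c["tissue"] == "inferred":
                # child folds into parent
                for grandchild in list(graph.successors(child)):
                    graph.add_edge(parent, grandchild)
                graph.remove_node(child)
                changed = True
            elif p["tissue"] == "inferred":
                # observed child replaces its inferred parent
                grandparents = list(graph.predecessors(parent))
                for sibling in list(graph.successors(parent)):
                    if sibling != child:
                        graph.add_edge(child, sibling)
                graph.remove_node(parent)
                for grandparent in grandparents:
                    graph.add_edge(grandparent, child)
                changed = True


# ---------------------------------------------------------------------------
# egression calling


@dataclass(frozen=True)
class EgressionEvent:
    clone_id: str
    source_id: str  # observed synovial node
    target_id: str  # observed blood node


def call_egressions(tree: LineageTree) -> list[EgressionEvent]:
    """Directed synovium -> blood transitions between observed nodes,
    connected directly or through inferred-only intermediate nodes."""
    events = []
    for node, data in tree.graph.nodes(data=True):
        if data["tissue"] != "blood":
            continue
        ancestor = node
        while True:
            parents = list(tree.graph.predecessors(ancestor))
            if not parents:
                ancestor = None
                break
            ancestor = parents[0]
            if tree.graph.nodes[ancestor]["tissue"] != "inferred":
                break
        if ancestor is not None and tree.graph.nodes[ancestor]["tissue"] == "synovium":
            events.append(
                EgressionEvent(
                    tree.clone_id,
                    str(tree.graph.nodes[ancestor]["sequence_id"]),
                    str(data["sequence_id"]),
                )
            )
    return sorted(events, key=lambda e: (e.source_id, e.target_id))


def discard_suspect_lineages(
    trees: Iterable[LineageTree], suspect_ids: set[str]
) -> tuple[list[LineageTree], list[str]]:
    """Drop whole trees containing any sequence flagged for suspected index
    misassignment; returns (kept trees, discarded clone ids)."""
    kept, discarded = [], []
    for tree in trees:
        if tree.observed_ids() & set(suspect_ids):
            discarded.append(tree.clone_id)
        else:
            kept.append(tree)
    return kept, discarded


# ---------------------------------------------------------------------------
# export


def write_gml(tree: LineageTree, path) -> None:
    graph = tree.graph.copy()
    for _, data in graph.nodes(data=True):
        data["tissue"] = str(data["tissue"])
        data["sequence_id"] = str(data["sequence_id"])
        data["mutation_count"] = int(data["mutation_count"])
        data["duplicate_count"] = int(data["duplicate_count"])
        data["sequence"] = str(data["sequence"])
    graph.graph["clone_id"] = tree.clone_id
    graph.graph["parsimony_score"] = int(tree.parsimony_score)
    nx.write_gml(graph, str(path))


def read_gml(path) -> LineageTree:
    graph = nx.read_gml(str(path), label="id")
    graph = nx.relabel_nodes(
        graph, {n: graph.nodes[n]["sequence_id"] for n in graph.nodes}
    )
    root = next(n for n, d in graph.nodes(data=True) if d["tissue"] == "germline")
    return LineageTree(
        clone_id=graph.graph.get("clone_id", ""),
        graph=graph,
        root=root,
        parsimony_score=int(graph.graph.get("parsimony_score", 0)),
    )
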