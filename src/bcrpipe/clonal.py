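"""Clonal clustering, repertoire overlap and public-clone sharing.

Clonal clusters are built by grouping records on (V gene, J gene, junction
length) and single-linkage clustering of CDR3 amino-acid sequences within a
Hamming distance of 1; chaining across intermediate junctions is therefore
possible by construction. The repertoire overlap score between two samples is
the total read count (both samples) falling in clusters that contain at least
one record from each sample, divided by the summed read counts of both
samples — 0 for disjoint repertoires, 1 for identical ones.

Sequence *sharing* between paired compartments uses a stricter identity — the
CDR3 nucleotide sequence plus V and J genes — applied to duplicate-collapsed,
non-singleton records.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass


import numpy as np
import pandas as pd

from bcrpipe.annotate import gene_of


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _cluster_junctions(junctions: list[str], max_hamming: int) -> dict[str, int]:
    """Single-linkage components over equal-length junctions; cluster indices
    are ordered by each component's lexicographically smallest member."""
    uf = _UnionFind(len(junctions))
    if max_hamming == 1:
        buckets: dict[tuple[int, str], int] = {}
        for idx, junction in enumerate(junctions):
            for pos in range(len(junction)):
                key = (pos, junction[:pos] + junction[pos + 1:])
                if key in buckets:
                    uf.union(buckets[key], idx)
                else:
                    buckets[key] = idx
    else:
        for i, j in itertools.combinations(range(len(junctions)), 2):
            if hamming(junctions[i], junctions[j]) <= max_hamming:
                uf.union(i, j)
    components: dict[int, list[str]] = {}
    for idx, junction in enumerate(junctions):
        components.setdefault(uf.find(idx), []).append(junction)
    ordered = sorted(components.values(), key=min)
    return {j: ci for ci, members in enumerate(ordered) for j in members}


@dataclass
class ClonalClusterSet:
    """Records labeled with their clonal cluster (``clone_id`` column)."""

    records: pd.DataFrame
    max_hamming: int = 1

    def cluster_read_counts(self) -> pd.Series:
        return self.records.groupby("clone_id")["duplicate_count"].sum()

    @property
    def n_clusters(self) -> int:
        return self.records["clone_id"].nunique()


def cluster_clones(
    records: pd.DataFrame, max_hamming: int = 1
) -> ClonalClusterSet:
    """Assign every record a deterministic ``clone_id`` of the form
    ``v_gene|j_gene|junction_length|index``. Records without a junction are
    dropped (their count is recoverable from the input length)."""
    usable = records[records["junction_aa"].notna()].copy()
    usable["_v_gene"] = usable["v_call"].map(gene_of)
    usable["_j_gene"] = usable["j_call"].map(gene_of)
    clone_ids = pd.Series(index=usable.index, dtype=object)
    for (v_gene, j_gene, length), group in usable.groupby(
        ["_v_gene", "_j_gene", "junction_length"], sort=False
    ):
        junctions = sorted(set(group["junction_aa"]))
        assignment = _cluster_junctions(junctions, max_hamming)
        prefix = f"{v_gene}|{j_gene}|{int(length)}|"
        clone_ids.loc[group.index] = [
            f"{prefix}{assignment[j]:04d}" for j in group["junction_aa"]
        ]
    usable = usable.drop(columns=["_v_gene", "_j_gene"])
    usable["clone_id"] = clone_ids
    return ClonalClusterSet(usable, max_hamming)


def cluster_clones_bruteforce(
    records: pd.DataFrame, max_hamming: int = 1
) -> ClonalClusterSet:
    """All-pairs union-find reference implementation (identical contract to
    :func:`cluster_clones`); kept as the independent oracle for the
    near-linear bucketed clustering."""
    usable = records[records["junction_aa"].notna()].copy()
    usable["_v_gene"] = usable["v_call"].map(gene_of)
    usable["_j_gene"] = usable["j_call"].map(gene_of)
    clone_ids = pd.Series(index=usable.index, dtype=object)
    for (v_gene, j_gene, length), group in usable.groupby(
        ["_v_gene", "_j_gene", "junction_length"], sort=False
    ):
        junctions = sorted(set(group["junction_aa"]))
        uf = _UnionFind(len(junctions))
        for i, j in itertools.combinations(range(len(junctions)), 2):
            if hamming(junctions[i], junctions[j]) <= max_hamming:
                uf.union(i, j)
        comps: dict[int, list[int]] = {}
        for i in range(len(junctions)):
            comps.setdefault(uf.find(i), []).append(i)
        ordered = sorted(comps.values(), key=lambda ids: junctions[ids[0]])
        assignment = {
            junctions[i]: ci for ci, ids in enumerate(ordered) for i in ids
        }
        prefix = f"{v_gene}|{j_gene}|{int(length)}|"
        clone_ids.loc[group.index] = [
            f"{prefix}{assignment[j]:04d}" for j in group["junction_aa"]
        ]
    usable = usable.drop(columns=["_v_gene", "_j_gene"])
    usable["clone_id"] = clone_ids
    return ClonalClusterSet(usable, max_hamming)


# ---------------------------------------------------------------------------
# overlap


def _joint_cluster(
    sample_a: pd.DataFrame, sample_b: pd.DataFrame, max_hamming: int
) -> pd.DataFrame:
    a = sample_a.copy()
    a["_sample"] = "a"
    b = sample_b.copy()
    b["_sample"] = "b"
    union = pd.concat([a, b], ignore_index=True)
    return cluster_clones(union, max_hamming).records


def overlap_score(
    sample_a: pd.DataFrame, sample_b: pd.DataFrame, max_hamming: int = 1
) -> float:
    """Clonal overlap between two samples, clustered jointly so shared
    clusters are well defined. Reads are ``duplicate_count`` sums."""
    if sample_a.empty or sample_b.empty:
        raise ValueError("overlap score undefined for an empty sample")
    union = _joint_cluster(sample_a, sample_b, max_hamming)
    presence = union.groupby("clone_id")["_sample"].nunique()
    shared = presence[presence == 2].index
    numerator = union[union["clone_id"].isin(shared)]["duplicate_count"].sum()
    denominator = union["duplicate_count"].sum()
    return float(numerator / denominator)


def shared_sequence_table(
    sample_a: pd.DataFrame, sample_b: pd.DataFrame
) -> dict[str, int]:
    """Private/shared unique-sequence counts between two samples.

    Identity is the CDR3 nucleotide sequence plus V gene and J gene. Apply
    duplicate collapsing with ``min_duplicates=2`` beforehand for the
    non-singleton accounting used in paired blood/synovium comparisons.
    """

    def keys(sample: pd.DataFrame) -> set:
        return {
            (row.junction, gene_of(row.v_call), gene_of(row.j_call))
            for row in sample.itertuples()
            if isinstance(row.junction, str)
        }

    ka, kb = keys(sample_a), keys(sample_b)
    return {
        "private_a": len(ka - kb),
        "private_b": len(kb - ka),
        "shared": len(ka & kb),
    }


def public_sharing(
    cohort: dict[str, pd.DataFrame], max_hamming: int = 1
) -> pd.DataFrame:
    """Symmetric matrix of pairwise clonal overlap scores across donors."""
    donors = list(cohort)
    if len(donors) < 2:
        raise ValueError("public sharing requires at least 2 donors")
    matrix = pd.DataFrame(
        np.zeros((len(donors), len(donors))), index=donors, columns=donors
    )
    for i, a in enumerate(donors):
        for b in donors[i + 1:]:
            score = overlap_score(cohort[a], cohort[b], max_hamming)
            matrix.loc[a, b] = matrix.loc[b, a] = score
    np.fill_diagonal(matrix.values, 1.0)
    return matrix
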