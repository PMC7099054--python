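"""Paired-end read quality trimming and overlap merging.

Reads are Q30-trimmed at the 3' end and then merged into contigs by scanning
candidate overlap offsets between mate 1 and the reverse complement of mate 2.
A pair is rejected (a counted outcome, not an error) when the best overlap is
shorter than 15 bp or its mismatch ratio — mismatches divided by overlap
length, as in FLASH — reaches 0.25. Both thresholds are arguments, with these
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

DEFAULT_MIN_OVERLAP = 15
DEFAULT_MAX_MISMATCH_RATIO = 0.25
DEFAULT_QUALITY_THRESHOLD = 30

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class ReadPair:
    pair_id: str
    read1: str
    qual1: str
    read2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.read1) != len(self.qual1) or len(self.read2) != len(self.qual2):
            raise ValueError(f"{self.pair_id}: sequence/quality length mismatch")


@dataclass
class MergedContig:
    pair_id: str
    sequence: str
    overlap_len: int
    mismatch_ratio: float


@dataclass
class MergeRejection:
    pair_id: str
    reason: str  # "no_overlap", "mismatch_ratio", "empty_after_trim"
    overlap_len: int = 0
    mismatch_ratio: float = float("nan")


def _phred(qual: str) -> np.ndarray:
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33
    if arr.size and arr.min() < 0:
        raise ValueError("quality string contains characters below Phred+33 '!'")
    return arr


def _trim_index(quals: np.ndarray, q_threshold: int) -> int:
    """3' trim point: the position maximizing the running sum of
    (threshold - quality) over the suffix (BWA-style). Returns the kept
    length; the full length when no suffix sum is positive."""
    if quals.size == 0:
        return 0
    deficit = q_threshold - quals
    suffix = np.cumsum(deficit[::-1])[::-1]
    j = int(np.argmax(suffix))
    return j if suffix[j] > 0 else quals.size


def quality_trim(
    pair: ReadPair, q_threshold: int = DEFAULT_QUALITY_THRESHOLD, *, hard_cut: bool = False
) -> ReadPair:
    """Trim low-quality 3' tails from both mates.

    Default is the running-sum criterion of :func:`_trim_index`; with
    ``hard_cut=True`` each mate is instead cut at its first base below the
    threshold. Never lengthens a read.
    """
    out = []
    for seq, qual in ((pair.read1, pair.qual1), (pair.read2, pair.qual2)):
        q = _phred(qual)
        if hard_cut:
            below = np.nonzero(q < q_threshold)[0]
            k = int(below[0]) if below.size else len(seq)
        else:
            k = _trim_index(q, q_threshold)
        out.append((seq[:k], qual[:k]))
    return ReadPair(pair.pair_id, out[0][0], out[0][1], out[1][0], out[1][1])


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
) -> MergedContig | MergeRejection:
    """Merge one (already trimmed) pair into a contig.

    Mate 2 is reverse-complemented, then every overlap length from
    ``min(len1, len2)`` down to ``min_overlap`` is scored; the offset with the
    lowest mismatch ratio wins, ties going to the longest overlap. Disagreeing
    overlap positions take the higher-quality base (mate 1 on quality ties).
    """
    if not pair.read1 or not pair.read2:
        return MergeRejection(pair.pair_id, "empty_after_trim")
    r1 = pair.read1.upper()
    r2 = reverse_complement(pair.read2)
    q1 = _phred(pair.qual1)
    q2 = _phred(pair.qual2)[::-1]
    a1 = np.frombuffer(r1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(r2.encode(), dtype=np.uint8)
    max_o = min(len(r1), len(r2))
    if max_o < min_overlap:
        return MergeRejection(pair.pair_id, "no_overlap")

    best_o, best_ratio, best_mism = 0, np.inf, 0
    for o in range(max_o, min_overlap - 1, -1):
        mism = int((a1[len(r1) - o:] != a2[:o]).sum())
        ratio = mism / o
        if ratio < best_ratio:
            best_o, best_ratio, best_mism = o, ratio, mism
            if mism == 0:
                break
    if best_o < min_overlap:
        return MergeRejection(pair.pair_id, "no_overlap")
    if best_ratio >= max_mismatch_ratio:
        return MergeRejection(pair.pair_id, "mismatch_ratio", best_o, best_ratio)

    start = len(r1) - best_o
    if best_mism:
        ov = [
            r1[start + i] if q1[start + i] >= q2[i] else r2[i]
            for i in range(best_o)
        ]
        sequence = r1[:start] + "".join(ov) + r2[best_o:]
    else:
        sequence = r1 + r2[best_o:]
    return MergedContig(pair.pair_id, sequence, best_o, best_ratio)


def merge_pairs(
    pairs: Iterable[ReadPair],
    q_threshold: int = DEFAULT_QUALITY_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
) -> tuple[list[MergedContig], list[MergeRejection]]:
    """Trim and merge a batch of pairs; returns (contigs, rejections).

    Pairs whose mates all share one length are merged with a vectorized scan
    equivalent to :func:`merge_pair`; odd-length pairs fall back to the scalar
    path. The outputs preserve input order within each list.
    """
    contigs: list[MergedContig] = []
    rejections: list[MergeRejection] = []
    uniform: list[ReadPair] = []
    for pair in pairs:
        trimmed = quality_trim(pair, q_threshold)
        if not trimmed.read1 or not trimmed.read2:
            rejections.append(MergeRejection(pair.pair_id, "empty_after_trim"))
        else:
            uniform.append(trimmed)
    if not uniform:
        return contigs, rejections

    lengths = {(len(p.read1), len(p.read2)) for p in uniform}
    if len(lengths) != 1:
        for p in uniform:
            result = merge_pair(p, min_overlap, max_mismatch_ratio)
            (contigs if isinstance(result, MergedContig) else rejections).append(result)
        return contigs, rejections

    n = len(uniform)
    l1, l2 = lengths.pop()
    a1 = np.frombuffer(
        "".join(p.read1.upper() for p in uniform).encode(), dtype=np.uint8
    ).reshape(n, l1)
    a2 = np.vstack(
        [
            np.frombuffer(reverse_complement(p.read2).encode(), dtype=np.uint8)
            for p in uniform
        ]
    )
    max_o = min(l1, l2)
    best_o = np.zeros(n, dtype=np.int32)
    best_ratio = np.full(n, np.inf)
    unresolved = np.ones(n, dtype=bool)
    if max_o >= min_overlap:
        for o in range(max_o, min_overlap - 1, -1):
            idx = np.nonzero(unresolved)[0]
            if idx.size == 0:
                break
            mism = (a1[idx, l1 - o:] != a2[idx, :o]).sum(axis=1)
            ratio = mism / o
            better = ratio < best_ratio[idx]
            best_ratio[idx[better]] = ratio[better]
            best_o[idx[better]] = o
            unresolved[idx[mism == 0]] = False

    for i, p in enumerate(uniform):
        o = int(best_o[i])
        ratio = float(best_ratio[i])
        if o < min_overlap:
            rejections.append(MergeRejection(p.pair_id, "no_overlap"))
        elif ratio >= max_mismatch_ratio:
            rejections.append(MergeRejection(p.pair_id, "mismatch_ratio", o, ratio))
        elif ratio == 0.0:
            seq = p.read1.upper() + a2[i, o:].tobytes().decode()
            contigs.append(MergedContig(p.pair_id, seq, o, 0.0))
        else:
            result = merge_pair(p, min_overlap, max_mismatch_ratio)
            assert isinstance(result, MergedContig)
            contigs.append(result)
    return contigs, rejections


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Load mate FASTQ files into :class:`ReadPair` objects (Phred+33)."""
    from Bio import SeqIO

    pairs = []
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1 in SeqIO.parse(str(path1), "fastq"):
        rec2 = next(it2)
        pairs.append(
            ReadPair(
                pair_id=rec1.id,
                read1=str(rec1.seq),
                qual1="".join(
                    chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
                ),
                read2=str(rec2.seq),
                qual2="".join(
                    chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
                ),
            )
        )
    if next(it2, None) is not None:
        raise ValueError("mate files have unequal record counts")
    return pairs
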