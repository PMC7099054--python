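"""Contig annotation: germline V assignment, mutation counting, junction and
isotype extraction, duplicate collapsing and the donor-inclusion filter.

V-allele assignment aligns every reference allele globally-in-germline /
locally-in-read (edlib infix mode) and keeps the best-scoring allele, ties
broken by fewest differences then lexicographic allele name; assignments below
a 70% identity floor are dropped. The V mutation count is the number of
nucleotide differences between the read and its predicted germline V segment
over the aligned V region only — junction and J content never count. Indel
events (rare; the simulator plants none) each count once.

Annotated records are plain pandas DataFrames using AIRR Rearrangement column
names (``sequence_id``, ``v_call``, ``j_call``, ``junction_aa``,
``duplicate_count`` ...) plus namespaced extras such as ``v_mutation_count``
and ``compartment``, and round-trip through TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from bcrpipe.germline import GermlineAllele, GermlineReference, translate_motif
from bcrpipe.preprocess import MergedContig

MIN_CONTIG_LENGTH = 100
MAX_DISTANCE_FRACTION = 0.30  # 70% identity floor
DEFAULT_MIN_READS = 25_000
MAX_JUNCTION_SCAN_CODONS = 45
MIN_JUNCTION_AA = 5

AIRR_COLUMNS = [
    "sequence_id", "donor_id", "compartment", "isotype", "sequence",
    "v_call", "j_call", "junction", "junction_aa", "junction_length",
    "productive", "v_mutation_count", "v_identity", "duplicate_count",
    "v_sequence_start", "v_sequence_end",
    "motif_avy_intact", "motif_nhs_intact", "suspect",
]


#: a substitution-style window is rejected when it needs this many more
#: differences than the edit-distance alignment (indicates a genuine indel)
_INDEL_MARGIN = 15


@dataclass
class VAlignment:
    """Result of aligning a germline V allele into a contig.

    ``start``/``end`` are the edlib infix location (contig coordinates,
    half-open). ``window_start``/``window_end`` delimit the best
    *substitution* window — the germline-length contig window with the fewest
    mismatches near the edlib location — which is the coordinate frame used
    for mutation counting, junction extraction and motif checks whenever the
    alignment is substitution-only.
    """

    v_call: str
    allele: GermlineAllele
    contig: str
    distance: int  # edit distance germline vs aligned read segment
    start: int  # contig coordinates, 0-based half-open
    end: int
    cigar: Optional[str] = None

    def __post_init__(self) -> None:
        germline = self.allele.nt_sequence
        length = len(germline)
        g = np.frombuffer(germline.encode(), dtype=np.uint8)
        c = np.frombuffer(self.contig.encode(), dtype=np.uint8)
        max_start = len(self.contig) - length
        candidates: set[int] = set()
        for anchor in (self.start, self.end - length):
            for s in range(anchor - 3, anchor + 4):
                if 0 <= s <= max_start:
                    candidates.add(s)
        best_s, best_m = self.start, None
        for s in sorted(candidates):
            mism = int((c[s : s + length] != g).sum())
            if best_m is None or mism < best_m:
                best_s, best_m = s, mism
        self.window_start = best_s
        self.window_end = best_s + length
        self.window_mismatches = length if best_m is None else best_m
        self.has_indel = self.window_mismatches > self.distance + _INDEL_MARGIN

    @property
    def identity(self) -> float:
        return 1.0 - self.distance / len(self.allele.nt_sequence)

    @property
    def segment_length(self) -> int:
        return self.end - self.start

    @property
    def v_end(self) -> int:
        """Contig coordinate one past the V segment (substitution frame when
        available, edlib location otherwise)."""
        return self.end if self.has_indel else self.window_end


def gene_of(v_call: str) -> str:
    """Gene part of an allele call (``IGHV4-34*01`` -> ``IGHV4-34``)."""
    return v_call.split("*")[0]


def family_of(v_call: str) -> str:
    match = re.match(r"(IGH[VDJ]\d+)", v_call)
    return match.group(1) if match else v_call


def assign_v_allele(
    contig: str,
    ref: GermlineReference,
    max_distance_fraction: float = MAX_DISTANCE_FRACTION,
) -> Optional[VAlignment]:
    """Best germline V allele for a contig, or None when unassignable."""
    contig = contig.upper()
    if len(contig) < MIN_CONTIG_LENGTH:
        return None
    best_name, best_dist = None, None
    for name in sorted(ref.alleles):
        germline = ref[name].nt_sequence
        limit = int(max_distance_fraction * len(germline))
        k = limit if best_dist is None else min(limit, best_dist)
        res = edlib.align(germline, contig, mode="HW", task="distance", k=k)
        dist = res["editDistance"]
        if dist < 0:
            continue
        if best_dist is None or dist < best_dist:
            best_name, best_dist = name, dist
    if best_name is None:
        return None
    allele = ref[best_name]
    res = edlib.align(allele.nt_sequence, contig, mode="HW", task="path")
    start, end_inclusive = res["locations"][0]
    return VAlignment(
        v_call=best_name,
        allele=allele,
        contig=contig,
        distance=res["editDistance"],
        start=start,
        end=end_inclusive + 1,
        cigar=res["cigar"],
    )


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def count_mutations(alignment: VAlignment) -> int:
    """Number of nucleotide differences between the read and its predicted
    germline V segment, over the aligned V region only.

    Substitution-only alignments are counted as mismatches over the best
    germline-length window (positions downstream of the V never count); when
    the alignment genuinely needs indels, substitutions count individually
    and each indel event (run) counts once, from the alignment path.
    """
    if not alignment.has_indel:
        return alignment.window_mismatches
    if not alignment.cigar:
        return alignment.distance
    total = 0
    for length, op in _CIGAR_RE.findall(alignment.cigar):
        if op == "X":
            total += int(length)
        elif op in "ID":
            total += 1  # one event per run
    return total


def mutated_positions(alignment: VAlignment, contig: Optional[str] = None) -> np.ndarray:
    """Germline-coordinate positions of substitutions (substitution-frame
    alignments only; returns an empty array when indels are present)."""
    contig = (contig or alignment.contig).upper()
    if alignment.has_indel:
        return np.empty(0, dtype=np.int64)
    germline = alignment.allele.nt_sequence
    segment = contig[alignment.window_start : alignment.window_end]
    a = np.frombuffer(segment.encode(), dtype=np.uint8)
    b = np.frombuffer(germline.encode(), dtype=np.uint8)
    return np.nonzero(a != b)[0]


@dataclass
class JunctionResult:
    junction: str
    junction_aa: str
    productive: bool
    j_end: int  # contig coordinate one past the junction's final (Trp) codon


def extract_junction(
    alignment: VAlignment, contig: str
) -> Optional[JunctionResult]:
    """Junction from the conserved V Cys (IMGT 104) through the J Trp.

    The junction is translated in the V reading frame; the J anchor is the
    first downstream Trp followed by the W-G-x-G motif. Returns None when no
    anchor is found within the scan window or the junction is shorter than
    5 amino acids; out-of-frame/stop-containing junctions come back flagged
    nonproductive.
    """
    contig = contig.upper()
    cys_start = alignment.v_end - 3
    if cys_start < 0:
        return None
    window = contig[cys_start : cys_start + 3 * MAX_JUNCTION_SCAN_CODONS]
    window = window[: 3 * (len(window) // 3)]
    if len(window) < 3 * MIN_JUNCTION_AA:
        return None
    aas = str(Seq(window).translate())
    for j in range(1, len(aas) - 3):
        if aas[j] == "W" and aas[j + 1] == "G" and aas[j + 3] == "G":
            junction_aa = aas[: j + 1]
            if len(junction_aa) < MIN_JUNCTION_AA:
                return None
            junction = window[: 3 * (j + 1)]
            productive = "*" not in junction_aa
            return JunctionResult(
                junction, junction_aa, productive, cys_start + 3 * (j + 1)
            )
    return None


def assign_j_gene(
    contig: str, junction: JunctionResult, ref: GermlineReference, max_mismatch: int = 2
) -> Optional[str]:
    """J gene by matching the post-junction region (including the junction's
    Trp codon) against the reference J segments."""
    contig = contig.upper()
    start = junction.j_end - 3
    best_name, best_mism = None, None
    for name in sorted(ref.j_segments):
        j_nt = ref.j_segments[name]
        segment = contig[start : start + len(j_nt)]
        if len(segment) < len(j_nt):
            continue
        mism = sum(a != b for a, b in zip(segment, j_nt))
        if best_mism is None or mism < best_mism:
            best_name, best_mism = name, mism
    if best_name is None or best_mism > max_mismatch:
        return None
    return best_name.split("*")[0]


def assign_isotype(
    contig: str, ref: GermlineReference, max_mismatch: int = 2
) -> Optional[str]:
    """Isotype from the constant-region stub at the contig 3' end; the best
    stub wins if within ``max_mismatch`` mismatches, otherwise undetermined."""
    contig = contig.upper()
    best, best_dist = None, None
    for isotype in sorted(ref.constant_region_stubs):
        stub = ref.constant_region_stubs[isotype]
        tail = contig[-(len(stub) + 10):]
        res = edlib.align(stub, tail, mode="HW", task="distance", k=max_mismatch)
        dist = res["editDistance"]
        if dist < 0:
            continue
        if best_dist is None or dist < best_dist:
            best, best_dist = isotype, dist
        elif dist == best_dist:
            best = None  # ambiguous
    return best


@dataclass
class AnnotationLog:
    """Counts of contigs dropped per reason."""

    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())


def annotate_contigs(
    contigs: Iterable[MergedContig | str],
    ref: GermlineReference,
    *,
    donor_id: str = "",
    compartment: str = "blood",
    collapse_identical: bool = True,
    compute_motifs: bool = True,
) -> tuple[pd.DataFrame, AnnotationLog]:
    """Annotate merged contigs into an AIRR-style record table.

    Identical contig sequences are collapsed first (``duplicate_count`` =
    number of contributing reads) so each unique sequence is aligned once.
    Unassignable, junction-less or isotype-less sequences are dropped with a
    per-reason count in the returned log (weighted by reads).
    """
    seqs: list[str] = []
    ids: list[str] = []
    for c in contigs:
        if isinstance(c, MergedContig):
            seqs.append(c.sequence.upper())
            ids.append(c.pair_id)
        else:
            seqs.append(c.upper())
            ids.append(f"contig{len(ids)}")

    log = AnnotationLog()
    if collapse_identical:
        counts: dict[str, int] = {}
        first_id: dict[str, str] = {}
        for sid, seq in zip(ids, seqs):
            if seq not in counts:
                first_id[seq] = sid
            counts[seq] = counts.get(seq, 0) + 1
        unique = [(first_id[s], s, n) for s, n in counts.items()]
    else:
        unique = [(sid, s, 1) for sid, s in zip(ids, seqs)]

    records = []
    for sid, seq, dup in unique:
        alignment = assign_v_allele(seq, ref)
        if alignment is None:
            log.drop("unassignable_v", dup)
            continue
        junction = extract_junction(alignment, seq)
        if junction is None:
            log.drop("no_junction", dup)
            continue
        j_gene = assign_j_gene(seq, junction, ref)
        if j_gene is None:
            log.drop("no_j_gene", dup)
            continue
        isotype = assign_isotype(seq, ref)
        if isotype is None:
            log.drop("isotype_undetermined", dup)
            continue
        n_mut = count_mutations(alignment)
        allele = alignment.allele
        avy = nhs = pd.NA
        if compute_motifs and allele.gene == "IGHV4-34" and not alignment.has_indel:
            segment = seq[alignment.window_start : alignment.window_end]
            avy = translate_motif(allele, segment, "AVY")
            nhs = translate_motif(allele, segment, "NHS")
        records.append(
            {
                "sequence_id": sid,
                "donor_id": donor_id,
                "compartment": compartment,
                "isotype": isotype,
                "sequence": seq,
                "v_call": alignment.v_call,
                "j_call": j_gene,
                "junction": junction.junction,
                "junction_aa": junction.junction_aa,
                "junction_length": len(junction.junction_aa),
                "productive": junction.productive,
                "v_mutation_count": n_mut,
                "v_identity": alignment.identity,
                "duplicate_count": dup,
                "v_sequence_start": alignment.start,
                "v_sequence_end": alignment.end,
                "motif_avy_intact": avy,
                "motif_nhs_intact": nhs,
                "suspect": False,
            }
        )
    df = pd.DataFrame(records, columns=AIRR_COLUMNS)
    return df, log


def collapse_duplicates(
    records: pd.DataFrame, min_duplicates: int = 1
) -> pd.DataFrame:
    """Merge identical nucleotide sequences within a donor+compartment,
    summing ``duplicate_count``; with ``min_duplicates`` > 1, drop sequences
    below that total (the paired blood/synovium pathway uses 2)."""
    if records.empty:
        out = records.copy()
    else:
        keys = ["donor_id", "compartment", "sequence"]
        agg = {c: "first" for c in records.columns if c not in keys}
        agg["duplicate_count"] = "sum"
        out = (
            records.groupby(keys, as_index=False, sort=False)
            .agg(agg)
            .reindex(columns=records.columns)
        )
    return out[out["duplicate_count"] >= min_duplicates].reset_index(drop=True)


@dataclass
class DonorRepertoire:
    """Annotated repertoire of one donor (one compartment)."""

    donor_id: str
    group_label: str
    records: pd.DataFrame

    @property
    def total_reads(self) -> int:
        return int(self.records["duplicate_count"].sum()) if len(self.records) else 0


def apply_donor_filter(
    repertoire: DonorRepertoire | pd.DataFrame | int,
    min_reads: int = DEFAULT_MIN_READS,
) -> bool:
    """Donor-inclusion decision: True (include) iff the repertoire holds at
    least ``min_reads`` total reads after processing."""
    if isinstance(repertoire, DonorRepertoire):
        total = repertoire.total_reads
    elif isinstance(repertoire, pd.DataFrame):
        total = int(repertoire["duplicate_count"].sum()) if len(repertoire) else 0
    else:
        total = int(repertoire)
    return total >= min_reads


def write_airr(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_airr(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"junction_aa": str, "junction": str})
    for col in ("motif_avy_intact", "motif_nhs_intact"):
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    return df
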