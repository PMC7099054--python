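"""Generate the bundled synthetic IGHV mini-reference.

Run from the repository root:

    python scripts/build_reference.py

Writes ``src/bcrpipe/data/synthetic_ighv_reference.fasta`` plus its JSON
sidecar. The output is deterministic (fixed seed) and committed to the
repository; this script exists for provenance and regeneration.

The alleles are synthetic: random codons on the IMGT positional scaffold
(104 IMGT positions; conserved 1st-CYS at 23, W at 41, 2nd-CYS at 104; a few
gapped positions per allele in CDR1/CDR2). IGHV4-34*01 carries the AVY motif
at IMGT 24-26 and the NHS motif at IMGT 57-59. Random alleles are mutually
distant (pairwise Hamming distance is checked below), which keeps V-allele
assignment unambiguous at realistic mutation loads.
"""

from __future__ import annotations

import itertools
import sys
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bcrpipe.germline import (  # noqa: E402
    GAP_CHAR,
    IMGT_MOTIFS,
    IMGT_REGIONS,
    GermlineAllele,
    GermlineReference,
    write_reference,
)

BUILD_SEED = 20240917
N_IMGT_POSITIONS = 104
CONSERVED = {23: "C", 41: "W", 104: "C"}
V4_34_FIXED = {24: "A", 25: "V", 26: "Y", 57: "N", 58: "H", 59: "S"}

# one allele per gene; families IGHV1-IGHV7 all represented
GENES = [
    "IGHV1-2", "IGHV1-18", "IGHV1-46", "IGHV1-69",
    "IGHV2-5", "IGHV2-26", "IGHV2-70",
    "IGHV3-7", "IGHV3-15", "IGHV3-23", "IGHV3-30", "IGHV3-48",
    "IGHV4-4", "IGHV4-34", "IGHV4-39", "IGHV4-59",
    "IGHV5-10-1", "IGHV5-51",
    "IGHV6-1",
    "IGHV7-4-1", "IGHV7-81",
]

# candidate gapped IMGT positions (inside CDR1/CDR2, never conserved/motif)
GAP_PATTERNS = [
    (31, 32, 33, 60, 61),
    (32, 33, 34, 61, 62),
    (31, 32, 60, 61, 62),
    (33, 34, 35, 60, 62),
]

J_SEGMENTS_AA = {"IGHJ4*01": "WGQGTLVTVSS", "IGHJ6*01": "WGQGTTVTVSS"}
CONSTANT_STUBS = {"IgG": "GCCTCCACCAAGGGCCCATCG", "IgM": "GGGAGTGCATCCGCCCCAACC"}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    CODONS_BY_AA.setdefault(aa, []).append(codon)


def random_codon(rng: np.random.Generator, aa: str) -> str:
    options = CODONS_BY_AA[aa]
    return options[rng.integers(len(options))]


def build_allele(gene: str, rng: np.random.Generator) -> GermlineAllele:
    family = "IGHV" + gene[4:].split("-")[0]
    gaps = set(GAP_PATTERNS[rng.integers(len(GAP_PATTERNS))])
    fixed = dict(CONSERVED)
    if gene == "IGHV4-34":
        fixed.update(V4_34_FIXED)
    assert not gaps & set(fixed)

    gapped_codons: list[str] = []
    for pos in range(1, N_IMGT_POSITIONS + 1):
        if pos in gaps:
            gapped_codons.append(GAP_CHAR * 3)
        else:
            aa = fixed.get(pos) or AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
            gapped_codons.append(random_codon(rng, aa))
    imgt_gapped = "".join(gapped_codons)
    nt_sequence = imgt_gapped.replace(GAP_CHAR, "")

    def ungapped_nt(imgt_pos: int) -> int:
        """Ungapped nt offset of the first base of an IMGT position."""
        return 3 * sum(1 for p in range(1, imgt_pos) if p not in gaps)

    region_bounds = {
        name: (ungapped_nt(lo), ungapped_nt(hi + 1))
        for name, (lo, hi) in IMGT_REGIONS.items()
    }
    motif_sites = {}
    if gene == "IGHV4-34":
        motif_sites = {
            name: (ungapped_nt(lo), ungapped_nt(hi + 1))
            for name, (lo, hi) in IMGT_MOTIFS.items()
        }
    return GermlineAllele(
        allele_name=f"{gene}*01",
        family=family,
        gene=gene,
        nt_sequence=nt_sequence,
        imgt_gapped=imgt_gapped,
        region_bounds=region_bounds,
        motif_sites=motif_sites,
    )


def main() -> None:
    rng = np.random.default_rng(BUILD_SEED)
    alleles = {}
    for gene in GENES:
        allele = build_allele(gene, rng)
        alleles[allele.allele_name] = allele

    j_segments = {
        name: "".join(random_codon(rng, aa) if i else "TGG"
                      for i, aa in enumerate(seq_aa))
        for name, seq_aa in J_SEGMENTS_AA.items()
    }
    for name, nt in j_segments.items():
        assert str(Seq(nt).translate()) == J_SEGMENTS_AA[name]

    # sanity: alleles must be mutually distant over their common prefix
    for a, b in itertools.combinations(alleles.values(), 2):
        n = min(len(a.nt_sequence), len(b.nt_sequence))
        dist = sum(x != y for x, y in zip(a.nt_sequence[:n], b.nt_sequence[:n]))
        assert dist > 100, (a.allele_name, b.allele_name, dist)

    ref = GermlineReference(
        alleles=alleles,
        version_tag="bcrpipe-synthetic-1",
        j_segments=j_segments,
        constant_region_stubs=CONSTANT_STUBS,
    )
    out = Path(__file__).resolve().parents[1] / "src" / "bcrpipe" / "data"
    out.mkdir(parents=True, exist_ok=True)
    write_reference(ref, out / "synthetic_ighv_reference.fasta")
    print(f"wrote {len(alleles)} alleles, {len(j_segments)} J segments to {out}")


if __name__ == "__main__":
    main()
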