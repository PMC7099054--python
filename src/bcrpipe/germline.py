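"""Germline IGHV reference: alleles, IMGT-gapped alignments and motif coordinates.

The package ships a small frozen *synthetic* mini-reference (see
``bcrpipe/data/synthetic_ighv_reference.fasta`` and its JSON sidecar) spanning
families IGHV1–IGHV7 and including IGHV4-34*01 with its FR1 AVY motif
(IMGT amino acids 24–26) and CDR2 NHS N-glycosylation motif (IMGT 57–59).
Allele sequences are computer-generated, not curated IMGT entries; they follow
the IMGT positional scaffold (conserved 1st-CYS at position 23, W at 41,
2nd-CYS at 104) so that region and motif coordinates behave like the real thing.

Coordinate convention: all intervals are 0-based, half-open, in nucleotides on
the *ungapped* germline sequence. IMGT positions exist only in the gapped
string, from which the ungapped intervals are derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from Bio.Seq import Seq

GAP_CHAR = "."

#: IMGT amino-acid intervals (1-based, inclusive) of the V regions.
IMGT_REGIONS = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
}

#: IMGT amino-acid intervals of the IGHV4-34 motifs.
IMGT_MOTIFS = {"AVY": (24, 26), "NHS": (57, 59)}


class ReferenceError(ValueError):
    """Malformed or inconsistent germline reference."""


class UnsupportedMotifError(KeyError):
    """Motif not annotated on the queried allele."""


@dataclass(frozen=True)
class GermlineAllele:
    """One germline V-segment allele.

    ``region_bounds`` and ``motif_sites`` are 0-based half-open nucleotide
    intervals on ``nt_sequence`` (the ungapped sequence).
    """

    allele_name: str
    family: str
    gene: str
    nt_sequence: str
    imgt_gapped: str
    region_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)
    motif_sites: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.imgt_gapped.replace(GAP_CHAR, "") != self.nt_sequence:
            raise ReferenceError(
                f"{self.allele_name}: degapped IMGT alignment does not equal "
                "the ungapped sequence"
            )
        self._check_regions()
        self._check_motifs()

    def _check_regions(self) -> None:
        prev_end = 0
        for name in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
            if name not in self.region_bounds:
                raise ReferenceError(f"{self.allele_name}: missing region {name}")
            start, end = self.region_bounds[name]
            if start != prev_end or end <= start:
                raise ReferenceError(
                    f"{self.allele_name}: region {name} does not tile the V"
                )
            prev_end = end
        if prev_end != len(self.nt_sequence):
            raise ReferenceError(
                f"{self.allele_name}: regions do not cover the full V sequence"
            )

    def _check_motifs(self) -> None:
        for motif, (start, end) in self.motif_sites.items():
            if end - start != 9 or start % 3:
                raise ReferenceError(
                    f"{self.allele_name}: motif {motif} is not a codon-aligned "
                    "9 nt interval"
                )
        if self.gene == "IGHV4-34":
            for motif, region in (("AVY", "FR1"), ("NHS", "CDR2")):
                if motif not in self.motif_sites:
                    raise ReferenceError(
                        f"{self.allele_name}: IGHV4-34 allele lacks {motif} site"
                    )
                mstart, mend = self.motif_sites[motif]
                rstart, rend = self.region_bounds[region]
                if not (rstart <= mstart and mend <= rend):
                    raise ReferenceError(
                        f"{self.allele_name}: {motif} site outside {region}"
                    )

    def motif_residues(self, motif: str) -> str:
        """Germline amino-acid residues of an annotated motif."""
        if motif not in self.motif_sites:
            raise UnsupportedMotifError(motif)
        start, end = self.motif_sites[motif]
        return str(Seq(self.nt_sequence[start:end]).translate())


@dataclass
class GermlineReference:
    """A set of germline V alleles plus the minimal J/constant annotation
    needed for junction extraction and isotype assignment."""

    alleles: dict[str, GermlineAllele]
    version_tag: str = "unversioned"
    j_segments: dict[str, str] = field(default_factory=dict)
    constant_region_stubs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ReferenceError("reference contains no alleles")

    @property
    def families(self) -> set[str]:
        return {a.family for a in self.alleles.values()}

    def genes(self) -> set[str]:
        return {a.gene for a in self.alleles.values()}

    def __getitem__(self, allele_name: str) -> GermlineAllele:
        return self.alleles[allele_name]

    def __len__(self) -> int:
        return len(self.alleles)


def _parse_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ReferenceError(f"duplicate allele name in FASTA: {record.id}")
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        raise ReferenceError(f"no FASTA records parsed from {path}")
    return seqs


def _sidecar_path(fasta_path: Path) -> Path:
    return fasta_path.with_suffix(".json")


def load_reference(path: Optional[str | Path] = None) -> GermlineReference:
    """Load a germline reference from a FASTA file plus its JSON sidecar.

    ``path`` points at the FASTA; the sidecar is the same stem with a
    ``.json`` suffix. With ``path=None`` the bundled synthetic mini-reference
    is loaded.
    """
    if path is None:
        data_dir = resources.files("bcrpipe") / "data"
        fasta_path = Path(str(data_dir / "synthetic_ighv_reference.fasta"))
    else:
        fasta_path = Path(path)
    seqs = _parse_fasta(fasta_path)
    with open(_sidecar_path(fasta_path)) as fh:
        meta = json.load(fh)

    alleles: dict[str, GermlineAllele] = {}
    for name, seq in seqs.items():
        try:
            entry = meta["alleles"][name]
        except KeyError:
            raise ReferenceError(f"no sidecar metadata for allele {name}") from None
        alleles[name] = GermlineAllele(
            allele_name=name,
            family=entry["family"],
            gene=entry["gene"],
            nt_sequence=seq,
            imgt_gapped=entry["imgt_gapped"],
            region_bounds={k: tuple(v) for k, v in entry["region_bounds"].items()},
            motif_sites={k: tuple(v) for k, v in entry.get("motif_sites", {}).items()},
        )
    return GermlineReference(
        alleles=alleles,
        version_tag=meta.get("version_tag", "unversioned"),
        j_segments=dict(meta.get("j_segments", {})),
        constant_region_stubs=dict(meta.get("constant_region_stubs", {})),
    )


def write_reference(ref: GermlineReference, fasta_path: str | Path) -> None:
    """Write a reference back to FASTA + JSON sidecar (inverse of
    :func:`load_reference`)."""
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        for name, allele in sorted(ref.alleles.items()):
            fh.write(f">{name}\n{allele.nt_sequence}\n")
    meta = {
        "version_tag": ref.version_tag,
        "alleles": {
            name: {
                "family": a.family,
                "gene": a.gene,
                "imgt_gapped": a.imgt_gapped,
                "region_bounds": {k: list(v) for k, v in a.region_bounds.items()},
                "motif_sites": {k: list(v) for k, v in a.motif_sites.items()},
            }
            for name, a in sorted(ref.alleles.items())
        },
        "j_segments": ref.j_segments,
        "constant_region_stubs": ref.constant_region_stubs,
    }
    with open(_sidecar_path(fasta_path), "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def translate_motif(
    allele: GermlineAllele,
    observed_nt: str,
    motif: str,
    *,
    sequon: bool = False,
) -> Optional[bool]:
    """Is a germline motif intact in an observed sequence?

    ``observed_nt`` must be aligned to the allele's ungapped coordinates (same
    positions, substitutions only) and cover the motif interval. Intactness is
    judged at the amino-acid level, so synonymous substitutions never disrupt a
    motif. For ``motif="NHS"`` with ``sequon=True`` the N-X-S/T glycosylation
    sequon is accepted instead of the exact germline residues.

    Returns ``True``/``False``, or ``None`` when an ambiguous base (N) inside
    the motif makes the call indeterminate.
    """
    if motif not in allele.motif_sites:
        raise UnsupportedMotifError(
            f"motif {motif!r} not annotated on {allele.allele_name}"
        )
    start, end = allele.motif_sites[motif]
    if len(observed_nt) < end:
        raise ValueError("observed sequence does not cover the motif interval")
    codons = observed_nt[start:end].upper()
    if "N" in codons:
        return None
    observed_aa = str(Seq(codons).translate())
    if motif == "NHS" and sequon:
        return (
            observed_aa[0] == "N"
            and observed_aa[2] in "ST"
            and observed_aa[1] != "P"
        )
    return observed_aa == allele.motif_residues(motif)
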