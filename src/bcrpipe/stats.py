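"""Per-donor repertoire statistics.

All "per sequencing read" statistics weight each record by its
``duplicate_count`` (read-weighted); clone-weighted variants collapse to
clonotypes — identical CDR3 amino-acid sequence with the same predicted
germline V allele — with each clonotype contributing once at the mean
mutation count of its reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from bcrpipe.annotate import gene_of, family_of

HYPO_THRESHOLD = 5  # hypomutated = fewer than this many V mutations
DOMINANT_CLONOTYPE_PCT = 0.5


def _select(records: pd.DataFrame, isotype: Optional[str]) -> pd.DataFrame:
    if isotype is None:
        return records
    return records[records["isotype"] == isotype]


# ---------------------------------------------------------------------------
# mutation-count statistics


def mutation_distribution(
    records: pd.DataFrame,
    isotype: Optional[str] = None,
    weighting: str = "read",
) -> pd.Series:
    """Histogram of V mutation counts.

    ``weighting="read"``: each read contributes once (``duplicate_count``
    expanded). ``weighting="clone"``: each clonotype contributes once at the
    read-weighted mean mutation count of its members (fractional bins).
    """
    sub = _select(records, isotype)
    if sub.empty:
        return pd.Series(dtype=np.int64)
    if weighting == "read":
        return (
            sub.groupby("v_mutation_count")["duplicate_count"].sum().sort_index()
        )
    if weighting == "clone":
        means = clone_mean_mutations(sub)
        return means.value_counts().sort_index()
    raise ValueError(f"unknown weighting {weighting!r}")


def clone_mean_mutations(records: pd.DataFrame) -> pd.Series:
    """Read-weighted mean mutation count per clonotype (CDR3 aa + V allele)."""
    weighted = records["v_mutation_count"] * records["duplicate_count"]
    grouped = records.assign(_w=weighted).groupby(["junction_aa", "v_call"])
    return grouped["_w"].sum() / grouped["duplicate_count"].sum()


def mean_mutations(
    records: pd.DataFrame, isotype: Optional[str] = None
) -> Optional[float]:
    sub = _select(records, isotype)
    if sub.empty:
        return None
    w = sub["duplicate_count"].to_numpy(float)
    return float(np.average(sub["v_mutation_count"].to_numpy(float), weights=w))


def pct_hypomutated(
    records: pd.DataFrame,
    isotype: Optional[str] = None,
    threshold: int = HYPO_THRESHOLD,
) -> Optional[float]:
    """Percentage of reads with fewer than ``threshold`` V mutations
    (read-weighted); None for an empty selection."""
    sub = _select(records, isotype)
    if sub.empty:
        return None
    w = sub["duplicate_count"].to_numpy(float)
    below = (sub["v_mutation_count"] < threshold).to_numpy(float)
    return float(100.0 * (below @ w) / w.sum())


def skewness(values, weights=None) -> Optional[float]:
    """Adjusted Fisher-Pearson standardized moment coefficient
    G1 = sqrt(n(n-1))/(n-2) * m3 / m2^(3/2), with m2 and m3 the biased sample
    moments. Requires n >= 3 and nonzero variance; returns None otherwise."""
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    n = w.sum()
    if n < 3:
        return None
    mean = (x @ w) / n
    d = x - mean
    m2 = (w @ d**2) / n
    m3 = (w @ d**3) / n
    # guard against zero variance, including floating-point residue from
    # constant samples
    if m2 <= 1e-13 * (mean * mean + 1.0):
        return None
    return float(np.sqrt(n * (n - 1)) / (n - 2) * m3 / m2**1.5)


# ---------------------------------------------------------------------------
# clonotypes and the Gini index


def clonotype_table(
    records: pd.DataFrame,
    isotype: Optional[str] = None,
    by_mutation_count: bool = False,
    collapsed: bool = False,
) -> pd.DataFrame:
    """Read counts per clonotype (identical CDR3 aa, same V allele).

    ``by_mutation_count`` additionally separates clonotypes by the per-read V
    mutation count (the clone definition used for frequency scatterplots).
    ``collapsed=True`` counts unique sequences instead of reads.
    """
    sub = _select(records, isotype)
    keys = ["junction_aa", "v_call"]
    if by_mutation_count:
        keys.append("v_mutation_count")
    if sub.empty:
        return pd.DataFrame(columns=keys + ["read_count"])
    if collapsed:
        counted = sub.groupby(keys, sort=False).size().rename("read_count")
    else:
        counted = sub.groupby(keys, sort=False)["duplicate_count"].sum().rename(
            "read_count"
        )
    return counted.reset_index()


def gini_index(read_counts) -> Optional[float]:
    """Clonality Gini index over clonotype read counts, by the formula
    G = 2 * sum_i(i * y_i) / (n * sum_i y_i) - (n + 1)/n with the counts y_i
    sorted ascending and ranked 1..n. 0 means all clonotypes equally
    abundant. None for an empty table."""
    y = np.sort(np.asarray(read_counts, dtype=float))
    n = y.size
    if n == 0:
        return None
    ranks = np.arange(1, n + 1, dtype=float)
    return float(2.0 * (ranks @ y) / (n * y.sum()) - (n + 1.0) / n)


def clonotype_frequencies(
    table: pd.DataFrame,
    dominant_pct: float = DOMINANT_CLONOTYPE_PCT,
    hypo_threshold: int = HYPO_THRESHOLD,
) -> pd.DataFrame:
    """Per-clonotype percentage of the repertoire, with dominant-clonotype
    flags (> ``dominant_pct`` per cent of reads) and, when the table carries
    mutation counts, a hypomutated/hypermutated split."""
    if table.empty:
        return table.assign(frequency_pct=[], dominant=[])
    out = table.copy()
    out["frequency_pct"] = 100.0 * out["read_count"] / out["read_count"].sum()
    out["dominant"] = out["frequency_pct"] > dominant_pct
    mutation_col = next(
        (c for c in ("v_mutation_count", "mean_mutations") if c in out.columns), None
    )
    if mutation_col is not None:
        out["compartment_class"] = np.where(
            out[mutation_col] < hypo_threshold, "hypomutated", "hypermutated"
        )
    return out


# ---------------------------------------------------------------------------
# V-gene usage and motifs


def v_gene_usage(
    records: pd.DataFrame, gene: str, isotype: Optional[str] = None
) -> Optional[float]:
    """Percentage of isotype reads whose V call maps to ``gene``
    (read-weighted); None for an empty selection."""
    sub = _select(records, isotype)
    if sub.empty:
        return None
    w = sub["duplicate_count"].to_numpy(float)
    hit = (sub["v_call"].map(gene_of) == gene).to_numpy(float)
    return float(100.0 * (hit @ w) / w.sum())


def family_mean_mutations(
    records: pd.DataFrame, isotype: Optional[str] = None
) -> pd.Series:
    """Read-weighted mean mutation count per germline IGHV family."""
    sub = _select(records, isotype)
    if sub.empty:
        return pd.Series(dtype=float)
    sub = sub.assign(
        family=sub["v_call"].map(family_of),
        _w=sub["v_mutation_count"] * sub["duplicate_count"],
    )
    grouped = sub.groupby("family")
    return grouped["_w"].sum() / grouped["duplicate_count"].sum()


def motif_intact_pct(
    records: pd.DataFrame, isotype: Optional[str], motif: str
) -> Optional[float]:
    """Percentage of IGHV4-34 reads of the isotype in which the motif is
    intact. Indeterminate calls (ambiguous bases) are excluded from both
    numerator and denominator; None when no determinate IGHV4-34 read exists.
    """
    col = {"AVY": "motif_avy_intact", "NHS": "motif_nhs_intact"}[motif]
    sub = _select(records, isotype)
    sub = sub[(sub["v_call"].map(gene_of) == "IGHV4-34") & sub[col].notna()]
    if sub.empty:
        return None
    w = sub["duplicate_count"].to_numpy(float)
    intact = sub[col].astype(bool).to_numpy(float)
    return float(100.0 * (intact @ w) / w.sum())


# ---------------------------------------------------------------------------
# mutation targeting


def mutation_targeting_profile(
    records: pd.DataFrame,
    reference,
    isotype: Optional[str] = None,
) -> np.ndarray:
    """Read-weighted frequency of mutation at each germline V position
    (ungapped allele coordinates), normalized by per-position coverage."""
    from bcrpipe.annotate import mutated_positions, VAlignment

    sub = _select(records, isotype)
    max_len = max((len(a.nt_sequence) for a in reference.alleles.values()), default=0)
    hits = np.zeros(max_len)
    coverage = np.zeros(max_len)
    for row in sub.itertuples():
        allele = reference[row.v_call]
        length = len(allele.nt_sequence)
        alignment = VAlignment(
            v_call=row.v_call,
            allele=allele,
            contig=row.sequence,
            distance=int(row.v_mutation_count),
            start=int(row.v_sequence_start),
            end=int(row.v_sequence_end),
        )
        positions = mutated_positions(alignment)
        coverage[:length] += row.duplicate_count
        hits[positions] += row.duplicate_count
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(coverage > 0, hits / np.maximum(coverage, 1), 0.0)
    return profile


# ---------------------------------------------------------------------------
# per-donor summary


@dataclass
class RepertoireSummary:
    donor_id: str
    isotype: str
    total_reads: int
    n_records: int
    mean_mutations: Optional[float]
    skewness: Optional[float]
    pct_hypomutated: Optional[float]
    gini: Optional[float]
    v4_34_pct: Optional[float]
    avy_intact_pct: Optional[float]
    nhs_intact_pct: Optional[float]
    max_clonotype_freq: Optional[float]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_repertoire(
    records: pd.DataFrame, donor_id: str = "", isotype: str = "IgG"
) -> RepertoireSummary:
    sub = _select(records, isotype)
    table = clonotype_table(sub)
    gini = gini_index(table["read_count"]) if len(table) else None
    max_freq = (
        float(100.0 * table["read_count"].max() / table["read_count"].sum())
        if len(table)
        else None
    )
    skew = (
        skewness(sub["v_mutation_count"], sub["duplicate_count"])
        if len(sub)
        else None
    )
    return RepertoireSummary(
        donor_id=donor_id,
        isotype=isotype,
        total_reads=int(sub["duplicate_count"].sum()) if len(sub) else 0,
        n_records=len(sub),
        mean_mutations=mean_mutations(sub),
        skewness=skew,
        pct_hypomutated=pct_hypomutated(sub),
        gini=gini,
        v4_34_pct=v_gene_usage(sub, "IGHV4-34"),
        avy_intact_pct=motif_intact_pct(sub, None, "AVY"),
        nhs_intact_pct=motif_intact_pct(sub, None, "NHS"),
        max_clonotype_freq=max_freq,
    )


def summarize_cohort(
    repertoires: dict[str, pd.DataFrame], isotype: str = "IgG"
) -> pd.DataFrame:
    """One summary row per donor; input maps donor_id -> record table."""
    rows = [
        summarize_repertoire(records, donor_id, isotype).as_dict()
        for donor_id, records in repertoires.items()
    ]
    return pd.DataFrame(rows)
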