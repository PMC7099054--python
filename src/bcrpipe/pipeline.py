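"""End-to-end convenience wrappers: simulate -> merge -> annotate.

These tie the stage modules together the way an analysis run uses them:
simulated paired-end reads are trimmed and merged, merged contigs are
annotated against the bundled germline reference, and the annotated table
feeds the statistics, clonality and lineage modules.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from bcrpipe.annotate import DonorRepertoire, annotate_contigs, collapse_duplicates
from bcrpipe.germline import GermlineReference, load_reference
from bcrpipe.preprocess import merge_pairs
from bcrpipe.simulate import (
    DonorPreset,
    DonorSimulation,
    PairedCompartmentSpec,
    simulate_donor,
    simulate_paired_compartments,
)


def process_simulation(
    sim: DonorSimulation,
    reference: Optional[GermlineReference] = None,
    compartment: str = "blood",
) -> tuple[pd.DataFrame, dict]:
    """Merge and annotate a simulated donor; returns (records, stage log)."""
    reference = reference or load_reference()
    contigs, rejections = merge_pairs(sim.reads)
    records, log = annotate_contigs(
        contigs, reference, donor_id=sim.donor_id, compartment=compartment
    )
    # propagate simulator misassignment flags onto annotated records
    if sim.truth["suspect"].any():
        suspect_variants = set(
            sim.truth.loc[sim.truth["suspect"], "sequence_id"].str.rsplit(
                "#", n=1
            ).str[0]
        )
        records["suspect"] = (
            records["sequence_id"].str.rsplit("#", n=1).str[0].isin(suspect_variants)
        )
    stage_log = {
        "n_read_pairs": len(sim.reads),
        "n_merged": len(contigs),
        "n_merge_rejected": len(rejections),
        "annotation_dropped": dict(log.dropped),
    }
    return records, stage_log


def run_donor_pipeline(
    preset: DonorPreset | str,
    seed: int,
    *,
    n_reads: Optional[int] = None,
    reference: Optional[GermlineReference] = None,
    group_label: Optional[str] = None,
) -> DonorRepertoire:
    """Simulate one donor and run the full read-to-records pipeline."""
    reference = reference or load_reference()
    sim = simulate_donor(preset, seed, reference=reference, n_reads=n_reads)
    records, _ = process_simulation(sim, reference)
    return DonorRepertoire(
        donor_id=sim.donor_id,
        group_label=group_label or sim.preset_name,
        records=records,
    )


def run_cohort_pipeline(
    preset: DonorPreset | str,
    seeds: list[int],
    *,
    n_reads: Optional[int] = None,
    reference: Optional[GermlineReference] = None,
) -> list[DonorRepertoire]:
    """One simulated donor per seed, each through the full pipeline."""
    reference = reference or load_reference()
    return [
        run_donor_pipeline(preset, seed, n_reads=n_reads, reference=reference)
        for seed in seeds
    ]


def run_paired_pipeline(
    spec: PairedCompartmentSpec,
    seed: int,
    *,
    reference: Optional[GermlineReference] = None,
    min_duplicates: int = 2,
) -> pd.DataFrame:
    """Simulate a paired blood/synovium donor, run both compartments through
    the pipeline and return one combined record table with the
    duplication-count filter applied (default: keep duplicate_count >= 2)."""
    reference = reference or load_reference()
    sim = simulate_paired_compartments(spec, seed, reference=reference)
    blood, _ = process_simulation(sim.blood, reference, compartment="blood")
    synovium, _ = process_simulation(sim.synovium, reference, compartment="synovium")
    combined = pd.concat([blood, synovium], ignore_index=True)
    return collapse_duplicates(combined, min_duplicates=min_duplicates)
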