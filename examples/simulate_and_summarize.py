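"""Simulate one early-RA donor repertoire and summarize it.

Builds 5,000 IgG read pairs with the ERA donor preset, runs quality trimming,
overlap merging and germline annotation, then prints the per-donor repertoire
summary. The hypomutated percentage (reads with fewer than 5 V mutations) is
the statistic that separates RA donors from healthy controls; the Gini index
measures clonal dominance (0 = perfectly even repertoire).
"""

from bcrpipe import stats
from bcrpipe.pipeline import run_donor_pipeline

donor = run_donor_pipeline("ERA", seed=1, n_reads=5000)
summary = stats.summarize_repertoire(donor.records, donor.donor_id, "IgG")

print(f"donor {summary.donor_id}: {summary.total_reads} IgG reads, "
      f"{summary.n_records} unique sequences")
print(f"  mean V mutations per read : {summary.mean_mutations:.2f}")
print(f"  skewness (adj. Fisher-Pearson): {summary.skewness:.2f}")
print(f"  % hypomutated (<5 mutations)  : {summary.pct_hypomutated:.2f}")
print(f"  Gini index over clonotypes    : {summary.gini:.3f}")
print(f"  % IGHV4-34 usage              : {summary.v4_34_pct:.2f}")
print(f"  largest clonotype             : {summary.max_clonotype_freq:.2f}% of reads")
print()
print("A healthy-control donor would show ~2.8% hypomutated reads and")
print("~0.65% IGHV4-34 usage; the ERA preset targets 12.6% and 2.41%.")
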