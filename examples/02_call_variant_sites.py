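"""Pile up one breed's alignments and classify every covered site.

Sites need >= 10 fragments to be callable; a site is polymorphic when
the minor allele holds >= 10% of reads with both-strand Q20 support
and the top two alleles cover >= 90% of reads.
"""

from breedtx.pileup import CallingThresholds, build_pileup, call_all
from breedtx.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=1), "example_output/sim")
table = build_pileup(ds.sam_paths["breed1"], CallingThresholds())
calls, summary = call_all(table)

print(calls["status"].value_counts().to_dict())
print(f"surveyed {summary['n_surveyed']:,} bases; "
      f"{summary['n_polymorphic']} polymorphic ({summary['percent_polymorphic']}%)")
# The percentage is the pool's within-breed SNP rate over reliably
# covered bases — the analogue of a pooled-library SNP survey.
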