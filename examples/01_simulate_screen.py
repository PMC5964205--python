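"""Simulate a gene-trap screen and look at its ground truth.

Generates a toy genome with multi-exon genes, plants transposon integration
events of four classes (true intronic traps, anti-oriented and intergenic
decoys, control-shared false positives), and emits nrLAM-PCR style FASTQ
files for two screen arms x three replicate reactions.
"""

import pandas as pd

from lamtrap import SimConfig, simulate_run

cfg = SimConfig(seed=7)
manifest = simulate_run(cfg, "scratch/example_sim")

events = pd.read_csv("scratch/example_sim/truth/events.tsv", sep="\t")
print(f"simulated {manifest['n_events']} integration events:")
print(events["event_class"].value_counts().to_string())
print()
reads = pd.read_csv("scratch/example_sim/truth/reads.tsv", sep="\t")
print(f"{len(reads)} reads across {reads.groupby(['arm','replicate']).ngroups} "
      "FASTQ files (arm x replicate)")
# Each event contributes one junction; each original molecule one distinct
# flank length; PCR duplicates repeat lengths and are removed downstream.
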