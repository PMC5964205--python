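"""Predict gene-trap fusion viability and truncation for insertion sites.

For an intronic, co-oriented insertion the splice acceptor captures the
host's upstream exons; the intron phase (upstream coding nt mod 3) decides
which of the three C-padding vector variants puts the reporter in frame, and
the retained N-terminal fragment is upstream_cds_nt // 3 residues.
"""

from lamtrap import SimConfig, locate_insertion, predict_fusion, simulate_run
from lamtrap import read_annotation
import pandas as pd

simulate_run(SimConfig(seed=7), "scratch/example_sim")
annotation = read_annotation("scratch/example_sim/annotation.gtf")
events = pd.read_csv("scratch/example_sim/truth/events.tsv", sep="\t")

print("site              class          viable variant truncation/protein")
for _, ev in events.head(12).iterrows():
    ctx = locate_insertion(annotation, ev["chrom"], int(ev["pos"]),
                           ev["orientation"])
    pred = predict_fusion(ctx)
    plen = (ctx.transcript.protein_length_aa
            if ctx.transcript is not None else "-")
    variants = ",".join(map(str, sorted(pred.matching_variants))) or "-"
    print(f"{ev['chrom']}:{ev['pos']:<9} {ev['event_class']:<14} "
          f"{str(pred.viable):<6} {variants:<7} {pred.truncation_aa}/{plen}")
# true_trap rows are viable with exactly one matching frame variant;
# anti-oriented and intergenic decoys can never produce a fusion protein.
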