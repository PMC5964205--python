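"""End-to-end orchestration: trim -> map -> blocks -> call -> filter -> report.

Every stage's record counts are logged and written to the QC report; every
intermediate (per-sample alignments, master blocks, site calls, discards) is
persisted as plain text under the run directory, so any stage can be rerun or
audited in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import genome_models as gm
from . import hit_filtering as hf
from . import readproc, site_calling
from .cassette import TOL2_TAG

log = logging.getLogger("lamtrap")


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    #: fastq path -> {"arm": ..., "replicate": ...}
    manifest: dict[str, dict[str, str]]
    outdir: str = "lamtrap_run"
    tag: str = TOL2_TAG
    max_tag_mismatch: int = readproc.DEFAULT_MAX_TAG_MISMATCH
    min_flank: int = readproc.DEFAULT_MIN_FLANK
    mapper: str = "builtin"  # builtin | import (manifest lists BED/SAM)
    max_map_mismatch: int = readproc.DEFAULT_MAX_MAP_MISMATCH
    junction_tolerance: int = site_calling.DEFAULT_JUNCTION_TOLERANCE
    min_stack: int = site_calling.DEFAULT_MIN_STACK
    ledger: hf.FilterLedger = field(default_factory=hf.FilterLedger)
    seed: int = 0

    def validate(self) -> None:
        seen = Counter()
        for path, meta in self.manifest.items():
            if "arm" not in meta or "replicate" not in meta:
                raise ValueError(
                    f"manifest entry {path}: needs arm and replicate"
                )
            seen[(meta["arm"], meta["replicate"])] += 1
        dupes = [k for k, v in seen.items() if v > 1]
        if dupes:
            raise ValueError(
                f"multiple files map to the same (arm, replicate): {dupes}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "ledger" in d and isinstance(d["ledger"], dict):
            d["ledger"] = hf.FilterLedger(**d["ledger"])
        return cls(**d)


@dataclass
class RunResult:
    outdir: Path
    hit_table: pd.DataFrame
    stats: dict


def _read_sample(cfg: PipelineConfig, genome, mapper, path, meta, stats):
    arm, rep = meta["arm"], meta["replicate"]
    sample = f"{arm}_{rep}"
    if cfg.mapper == "import":
        alignments = readproc.import_alignments(
            path, arm=arm, replicate=rep,
            chrom_lengths={c: len(s) for c, s in genome.items()},
        )
        stats["samples"][sample] = {
            "imported": len(alignments),
        }
        return alignments
    trimmed, rejected = readproc.trim_fastq(
        path, arm=arm, replicate=rep,
        tag=cfg.tag, max_mismatch=cfg.max_tag_mismatch,
        min_flank=cfg.min_flank,
    )
    reasons = Counter(r.reason for r in rejected)
    alignments, map_rejected = mapper.map_all(trimmed)
    map_reasons = Counter(r.reason for r in map_rejected)
    stats["samples"][sample] = {
        "reads_total": len(trimmed) + len(rejected),
        "trimmed": len(trimmed),
        "rejected": dict(reasons),
        "mapped": len(alignments),
        "map_rejected": dict(map_reasons),
    }
    log.info(
        "%s: %d reads, %d trimmed, %d mapped",
        sample, len(trimmed) + len(rejected), len(trimmed), len(alignments),
    )
    return alignments


def run_pipeline(cfg: PipelineConfig) -> RunResult:
    """Run every stage and write the run directory.

    Returns the final hit table and the per-stage statistics.  A missing
    control arm skips control subtraction with a prominent warning.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    stats: dict = {"samples": {}}
    genome = gm.read_genome(cfg.genome)
    annotation = gm.read_annotation(cfg.annotation)
    mapper = (
        readproc.FlankMapper(genome, max_mismatch=cfg.max_map_mismatch)
        if cfg.mapper == "builtin" and cfg.manifest
        else None
    )

    all_alignments: list[readproc.FlankAlignment] = []
    for path, meta in sorted(cfg.manifest.items()):
        alignments = _read_sample(cfg, genome, mapper, path, meta, stats)
        readproc.write_bed(
            out / "alignments" / f"{meta['arm']}_{meta['replicate']}.bed",
            alignments,
        )
        all_alignments.extend(alignments)

    blocks = site_calling.build_master_blocks(all_alignments)
    stats["master_blocks"] = len(blocks)
    with open(out / "master_blocks.bed", "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t"
                f"{b.block_id}\t{len(b.members)}\t+\n"
            )

    calls = site_calling.call_sites(
        blocks,
        junction_tolerance=cfg.junction_tolerance,
        min_stack=cfg.min_stack,
    )
    _write_site_calls(out / "site_calls.tsv", calls)
    arms_present = {c.arm for c in calls}
    stats["site_calls"] = {
        arm: sum(c.arm == arm for c in calls) for arm in sorted(arms_present)
    }
    concordance = site_calling.replicate_concordance(calls)
    stats["replicate_concordance"] = concordance

    experimental = [c for c in calls if c.arm == "experimental"]
    control = [c for c in calls if c.arm == "control"]
    control_available = any(
        meta["arm"] == "control" for meta in cfg.manifest.values()
    )
    if not control_available:
        log.warning(
            "control arm absent from manifest: control subtraction SKIPPED"
        )
    annotated = hf.annotate_sites(experimental, annotation, cfg.ledger)
    survivors, trace = hf.apply_filters(
        annotated, control, cfg.ledger, control_available=control_available
    )
    trace.to_csv(out / "filter_trace.tsv", sep="\t", index=False)
    discards = trace[trace["first_failed"] != ""]
    discards.to_csv(out / "discards.tsv", sep="\t", index=False)
    stats["filters"] = {
        "input_sites": len(annotated),
        "survivors": len(survivors),
        "discarded_by": dict(Counter(discards["first_failed"])),
    }

    records = hf.sites_to_records(survivors)
    hits = hf.aggregate_hits(records) if not records.empty else records
    hf.export_hit_table(hits).to_csv(
        out / "hit_table.tsv", sep="\t", index=False
    )
    stats["hits"] = {
        "n_sites": int(len(hits)),
        "n_genes": int(hits["gene_id"].nunique()) if len(hits) else 0,
        "n_high_confidence_genes": (
            int(hits.loc[hits["tier"] == "high_confidence", "gene_id"]
                .nunique())
            if len(hits)
            else 0
        ),
    }

    qc = {
        "seed": cfg.seed,
        "replicate_concordance": concordance,
        "stats": stats,
    }
    (out / "qc_report.json").write_text(json.dumps(qc, indent=1))
    resolved = cfg.to_dict()
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(resolved))
    log.info(
        "pipeline done: %d blocks, %d experimental sites, %d hits",
        len(blocks), len(experimental), len(hits),
    )
    return RunResult(out, hits, stats)


def _write_site_calls(path, calls) -> None:
    with open(path, "w") as fh:
        fh.write(
            "block_id\tarm\tchrom\tjunction_pos_1based\tstrand\t"
            "A\tB\tC\tunique_lengths_total\tmedian_read_sample\tstack_ok\n"
        )
        for c in calls:
            fh.write(
                f"{c.block_id}\t{c.arm}\t{c.chrom}\t{c.junction_pos + 1}\t"
                f"{c.strand}\t{c.counts.get('A', 0)}\t{c.counts.get('B', 0)}"
                f"\t{c.counts.get('C', 0)}\t{c.unique_lengths_total}\t"
                f"{c.median_read_sample}\t{c.stack_ok}\n"
            )


def config_for_sim_run(
    sim_dir: str | os.PathLike, outdir: str | os.PathLike, **overrides
) -> PipelineConfig:
    """Pipeline config consuming a simulator run directory's manifest."""
    sim_dir = Path(sim_dir)
    with open(sim_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    fastq = {
        str(sim_dir / rel): {"arm": meta["arm"], "replicate": meta["replicate"]}
        for rel, meta in manifest["fastq"].items()
    }
    return PipelineConfig(
        genome=str(sim_dir / manifest["genome"]),
        annotation=str(sim_dir / manifest["annotation"]),
        manifest=fastq,
        outdir=str(outdir),
        seed=manifest.get("seed", 0),
        **overrides,
    )


# ---------------------------------------------------------------------------
# evaluation against simulator truth


def evaluate_run(
    run_dir: str | os.PathLike,
    truth_dir: str | os.PathLike,
    junction_tolerance: int = site_calling.DEFAULT_JUNCTION_TOLERANCE,
    min_molecules: int = 3,
) -> dict:
    """Compare a pipeline run's hit table with the simulator's ground truth.

    A true trap is *eligible* when at least ``min_molecules`` of its molecules
    survived replicate subsampling in the experimental arm (distinct flank
    lengths pooled over replicates among emitted reads) — sites below that
    cannot pass the read-count filter by construction.  Reports recall over
    eligible true traps and the number of recovered decoys of each class.
    """
    run_dir, truth_dir = Path(run_dir), Path(truth_dir)
    hits = pd.read_csv(run_dir / "hit_table.tsv", sep="\t")
    events = pd.read_csv(truth_dir / "events.tsv", sep="\t")
    reads = pd.read_csv(truth_dir / "reads.tsv", sep="\t")

    pooled = (
        reads[reads["arm"] == "experimental"]
        .groupby("event_id")["flank_length"]
        .nunique()
    )
    events["surviving_molecules"] = (
        events["event_id"].map(pooled).fillna(0).astype(int)
    )

    hit_positions = [
        (str(row["Chr"]), int(row["Insertion site (genomic position)"]) - 1)
        for _, row in hits.iterrows()
    ]

    def recovered(ev) -> bool:
        return any(
            c == ev["chrom"] and abs(p - int(ev["pos"])) <= junction_tolerance
            for c, p in hit_positions
        )

    events["recovered"] = events.apply(recovered, axis=1)
    true_traps = events[events["event_class"] == "true_trap"]
    eligible = true_traps[true_traps["surviving_molecules"] >= min_molecules]
    decoys = events[events["event_class"] != "true_trap"]
    decoy_hits = decoys[decoys["recovered"]]
    n_eligible = int(len(eligible))
    report = {
        "n_true_traps": int(len(true_traps)),
        "n_eligible_true_traps": n_eligible,
        "n_recovered_true_traps": int(eligible["recovered"].sum()),
        "recall_eligible_pct": (
            100.0 * float(eligible["recovered"].mean()) if n_eligible else None
        ),
        "n_decoy_hits": int(len(decoy_hits)),
        "decoy_hits_by_class": dict(
            Counter(decoy_hits["event_class"])
        ),
        "n_hits": int(len(hits)),
    }
    return report
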