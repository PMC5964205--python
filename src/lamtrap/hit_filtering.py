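"""The screen's filter ledger and the final hit table.

Candidate sites pass, in reporting order: a minimum pooled unique-length read
count, the co-orientation / pyramid-stack test, subtraction of sites present
in the negative-control arm, and a genic / fusion-viability requirement.  The
filters are independent predicates (any application order yields the same
survivor set); only the attribution of a discard to its first failing filter
depends on the order.  Surviving sites are aggregated per gene: genes with two
or more independently identified sites are flagged high-confidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from . import genome_models as gm
from .site_calling import SiteCall

FILTER_ORDER = ("min_reads", "orientation_stack", "control", "genic_fusion")

#: Table-style column names used in exported hit tables.
HIT_COLUMNS = [
    "Chr",
    "Strand orientation",
    "Insertion site (genomic position)",
    "Median_read_sample",
    "Nr Insertion sites",
    "Gene",
    "Gene ID",
    "Truncation (N-terminal AA)",
    "Protein length (AA)",
    "tier",
]


@dataclass
class FilterLedger:
    min_unique_reads: int = 3
    high_depth_threshold: int = 30
    control_presence_min: int = 1
    require_genic: bool = True
    require_fusion_viable: bool = True
    orientation_mode: str = "same"  # site strand vs host gene strand
    hard_depth_filter: bool = False
    strict_variant: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_unique_reads < 1:
            raise ValueError("min_unique_reads must be >= 1")
        if self.high_depth_threshold < self.min_unique_reads:
            raise ValueError(
                "high_depth_threshold must be >= min_unique_reads"
            )
        if self.orientation_mode not in ("same", "opposite"):
            raise ValueError("orientation_mode must be 'same' or 'opposite'")


@dataclass
class AnnotatedSite:
    """A SiteCall resolved against gene structure."""

    call: SiteCall
    context: gm.InsertionContext
    fusion: gm.FusionPrediction
    depth_tier: str = "long_tail"
    filter_trace: dict[str, bool] = field(default_factory=dict)

    @property
    def gene(self) -> Optional[gm.GeneModel]:
        return self.context.gene


def annotate_sites(
    calls: Iterable[SiteCall],
    annotation: gm.Annotation,
    ledger: FilterLedger,
) -> list[AnnotatedSite]:
    out = []
    for call in calls:
        ctx = gm.locate_insertion(
            annotation, call.chrom, call.junction_pos, call.strand
        )
        fusion = gm.predict_fusion(ctx, ledger.strict_variant)
        out.append(AnnotatedSite(call, ctx, fusion))
    return out


# --- individual filters (each returns a subset of its input) ---------------


def filter_min_reads(
    sites: list[AnnotatedSite], ledger: FilterLedger
) -> list[AnnotatedSite]:
    """Discard sites with fewer pooled unique-length reads than the minimum."""
    return [
        s for s in sites
        if s.call.unique_lengths_total >= ledger.min_unique_reads
    ]


def filter_orientation_stack(
    sites: list[AnnotatedSite], ledger: FilterLedger
) -> list[AnnotatedSite]:
    """Keep stacked sites co-oriented with their host gene.

    Intergenic sites pass unchanged (they are the genic filter's business).
    Under orientation_mode 'opposite' (for data produced with the other
    transposon-end chemistry) the required strand relation is inverted.
    """
    keep = []
    for s in sites:
        if not s.call.stack_ok:
            continue
        if s.gene is None:
            keep.append(s)
            continue
        same = s.gene.strand == s.call.strand
        wanted = same if ledger.orientation_mode == "same" else not same
        if wanted:
            keep.append(s)
    return keep


def subtract_control(
    sites: list[AnnotatedSite],
    control_calls: Iterable[SiteCall],
    ledger: FilterLedger,
) -> list[AnnotatedSite]:
    """Remove experimental sites whose master block is seen in the control arm."""
    present = {
        c.block_id
        for c in control_calls
        if c.unique_lengths_total >= ledger.control_presence_min
    }
    return [s for s in sites if s.call.block_id not in present]


def filter_genic_fusion(
    sites: list[AnnotatedSite], ledger: FilterLedger
) -> list[AnnotatedSite]:
    """Keep sites inside known genes whose splicing yields a viable fusion."""
    keep = []
    for s in sites:
        if ledger.require_genic and s.context.status == "intergenic":
            continue
        if ledger.require_fusion_viable and not s.fusion.viable:
            continue
        keep.append(s)
    return keep


def tier_by_depth(
    sites: list[AnnotatedSite], ledger: FilterLedger
) -> list[AnnotatedSite]:
    """Annotate the descriptive depth tier: high iff pooled count > threshold.

    By default this is stratification, not a discard rule; with
    hard_depth_filter the long tail is dropped as well.
    """
    for s in sites:
        s.depth_tier = (
            "high"
            if s.call.unique_lengths_total > ledger.high_depth_threshold
            else "long_tail"
        )
    if ledger.hard_depth_filter:
        return [s for s in sites if s.depth_tier == "high"]
    return sites


def apply_filters(
    experimental: list[AnnotatedSite],
    control_calls: Iterable[SiteCall],
    ledger: FilterLedger,
    control_available: bool = True,
) -> tuple[list[AnnotatedSite], pd.DataFrame]:
    """Run the full ledger in reporting order; returns (survivors, trace).

    The trace has one row per input site with a pass/fail column per filter
    (evaluated unconditionally, so conservation holds: every discarded site is
    attributed to its first failing filter).
    """
    control_blocks = {
        c.block_id
        for c in control_calls
        if c.unique_lengths_total >= ledger.control_presence_min
    }
    rows = []
    survivors = []
    for s in experimental:
        checks = {
            "min_reads": s.call.unique_lengths_total >= ledger.min_unique_reads,
            "orientation_stack": bool(
                filter_orientation_stack([s], ledger)
            ),
            "control": (not control_available)
            or s.call.block_id not in control_blocks,
            "genic_fusion": bool(filter_genic_fusion([s], ledger)),
        }
        s.filter_trace = checks
        failed = [f for f in FILTER_ORDER if not checks[f]]
        rows.append(
            {
                "block_id": s.call.block_id,
                "chrom": s.call.chrom,
                "junction_pos_1based": s.call.junction_pos + 1,
                **{f"pass_{f}": checks[f] for f in FILTER_ORDER},
                "first_failed": failed[0] if failed else "",
            }
        )
        if not failed:
            survivors.append(s)
    survivors = tier_by_depth(survivors, ledger)
    trace = pd.DataFrame(
        rows,
        columns=["block_id", "chrom", "junction_pos_1based"]
        + [f"pass_{f}" for f in FILTER_ORDER]
        + ["first_failed"],
    )
    return survivors, trace


# --- aggregation ------------------------------------------------------------


def aggregate_hits(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate surviving per-site records into the final hit table.

    Input columns (internal names): chrom, strand, position (1-based),
    median_read_sample, gene_id, gene_name, truncation_aa, protein_length_aa.
    Adds n_insertion_sites_in_gene and the confidence tier (high_confidence
    iff the gene has >= 2 independent sites), and orders the table by
    (tier desc, gene, position).
    """
    required = {"chrom", "strand", "position", "gene_id", "gene_name"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"hit records missing columns {sorted(missing)}")
    df = records.copy()
    if df.empty:
        df["n_insertion_sites_in_gene"] = pd.Series(dtype=int)
        df["tier"] = pd.Series(dtype=str)
        return df
    per_gene = df.groupby("gene_id")["position"].transform("count")
    df["n_insertion_sites_in_gene"] = per_gene.astype(int)
    df["tier"] = (per_gene >= 2).map(
        {True: "high_confidence", False: "single_site"}
    )
    df = df.sort_values(
        by=["tier", "gene_name", "position"],
        ascending=[True, True, True],
        kind="mergesort",  # stable; 'high_confidence' < 'single_site'
    ).reset_index(drop=True)
    return df


def sites_to_records(sites: list[AnnotatedSite]) -> pd.DataFrame:
    """Per-site records (1-based positions) from filtered annotated sites."""
    rows = []
    for s in sites:
        gene = s.gene
        t = s.context.transcript
        rows.append(
            {
                "chrom": s.call.chrom,
                "strand": s.call.strand,
                "position": s.call.junction_pos + 1,
                "median_read_sample": s.call.median_read_sample,
                "unique_lengths_total": s.call.unique_lengths_total,
                "gene_id": gene.gene_id if gene else "",
                "gene_name": gene.gene_name if gene else "",
                "truncation_aa": s.fusion.truncation_aa,
                "protein_length_aa": (
                    t.protein_length_aa if t is not None else ""
                ),
                "matching_variants": ",".join(
                    str(v) for v in sorted(s.fusion.matching_variants)
                ),
                "depth_tier": s.depth_tier,
                "block_id": s.call.block_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "strand", "position", "median_read_sample",
            "unique_lengths_total", "gene_id", "gene_name", "truncation_aa",
            "protein_length_aa", "matching_variants", "depth_tier", "block_id",
        ],
    )


def export_hit_table(df: pd.DataFrame) -> pd.DataFrame:
    """Rename an aggregated hit table to the published column layout."""
    renames = {
        "chrom": "Chr",
        "strand": "Strand orientation",
        "position": "Insertion site (genomic position)",
        "median_read_sample": "Median_read_sample",
        "n_insertion_sites_in_gene": "Nr Insertion sites",
        "gene_name": "Gene",
        "gene_id": "Gene ID",
        "truncation_aa": "Truncation (N-terminal AA)",
        "protein_length_aa": "Protein length (AA)",
    }
    out = df.rename(columns=renames)
    cols = [c for c in HIT_COLUMNS if c in out.columns] + [
        c for c in out.columns if c not in HIT_COLUMNS
    ]
    return out[cols]


def load_hit_records(path) -> pd.DataFrame:
    """Read a published-layout hit table TSV into internal per-site records."""
    df = pd.read_csv(path, sep="\t", comment="#")
    renames = {
        "Chr": "chrom",
        "Strand orientation": "strand",
        "Insertion site (genomic position)": "position",
        "Median_read_sample": "median_read_sample",
        "Nr Insertion sites": "n_sites_published",
        "Gene": "gene_name",
        "Gene ID": "gene_id",
        "Truncation (N-terminal AA)": "truncation_aa",
        "Protein length (AA)": "protein_length_aa",
    }
    df = df.rename(columns=renames)
    df["chrom"] = df["chrom"].astype(str)
    return df
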