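"""Master blocks, unique-length deduplication and site calls.

Linear amplification anchors one end of every fragment at the integration
junction, so distinct original molecules show up as distinct flank lengths
while PCR duplicates repeat a length exactly.  Counting distinct lengths per
(arm, replicate) is therefore molecule counting.  Sites are compared between
samples at the resolution of *master blocks*: maximal genomic intervals
covering any mutually overlapping alignments pooled across every sequenced
sample, so the same site gets the same identifier in every arm and replicate.
"""

from __future__ import annotations

import statistics
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

from .genome_models import GenomicInterval
from .readproc import FlankAlignment

DEFAULT_JUNCTION_TOLERANCE = 2
DEFAULT_MIN_STACK = 3
REPLICATES = ("A", "B", "C")


@dataclass
class MasterBlock:
    block_id: str
    interval: GenomicInterval
    members: list[FlankAlignment] = field(default_factory=list)


def build_master_blocks(
    alignments: Iterable[FlankAlignment],
) -> list[MasterBlock]:
    """Single-linkage merge of overlapping alignments across all samples.

    Strand is ignored for merging (reads of one site share the junction but a
    fixed strand; overlap is purely positional).  Blocks are maximal: the
    result is the transitive closure of pairwise interval overlap.  block_ids
    are assigned in (chrom, start) order and are deterministic for a given
    input set regardless of input order.
    """
    by_chrom: dict[str, list[FlankAlignment]] = defaultdict(list)
    for a in alignments:
        by_chrom[a.interval.chrom].append(a)
    blocks: list[MasterBlock] = []
    raw: list[tuple[str, int, int, list[FlankAlignment]]] = []
    for chrom in sorted(by_chrom):
        members = sorted(
            by_chrom[chrom], key=lambda a: (a.interval.start, a.interval.end)
        )
        cur_start, cur_end = members[0].interval.start, members[0].interval.end
        cur_members = [members[0]]
        for a in members[1:]:
            if a.interval.start < cur_end:  # half-open overlap
                cur_end = max(cur_end, a.interval.end)
                cur_members.append(a)
            else:
                raw.append((chrom, cur_start, cur_end, cur_members))
                cur_start, cur_end = a.interval.start, a.interval.end
                cur_members = [a]
        raw.append((chrom, cur_start, cur_end, cur_members))
    for i, (chrom, start, end, members) in enumerate(raw):
        blocks.append(
            MasterBlock(
                f"MB{i + 1:06d}",
                GenomicInterval(chrom, start, end, "+"),
                members,
            )
        )
    return blocks


def dedup_unique_lengths(
    members: Iterable[FlankAlignment],
) -> dict[tuple[str, str], set[int]]:
    """Distinct flank lengths per (arm, replicate) among block members."""
    lengths: dict[tuple[str, str], set[int]] = defaultdict(set)
    for a in members:
        lengths[(a.arm, a.replicate)].add(a.flank_length)
    return dict(lengths)


@dataclass
class SiteCall:
    """One candidate integration site: a master block seen from one arm."""

    block_id: str
    arm: str
    chrom: str
    junction_pos: int
    strand: str
    counts: dict[str, int]  # unique lengths per replicate
    unique_lengths_total: int  # distinct lengths pooled over replicates
    median_read_sample: float
    stack_ok: bool
    minority_strand_frac: float = 0.0


def _modal_junction(members: Sequence[FlankAlignment]) -> int:
    counts = Counter(a.junction_pos for a in members)
    top = max(counts.values())
    return min(p for p, c in counts.items() if c == top)


def _stack_ok(
    members: Sequence[FlankAlignment],
    junction: int,
    strand: str,
    tolerance: int,
    min_stack: int,
) -> bool:
    """Pyramid test: reads share the junction and coverage decays from it.

    Authentic nrLAM sites have all reads anchored at one junction with
    variable far ends, so per-base coverage is maximal at the junction and
    non-increasing with distance from it (a "stacked pyramidal arrangement").
    Requires >= min_stack distinct lengths within ``tolerance`` of the
    junction, and non-increasing coverage beyond the tolerance window.
    """
    sign = 1 if strand == "+" else -1
    offsets = []  # (start_offset, end_offset) along the away-from-junction axis
    near_lengths = set()
    for a in members:
        off = sign * (a.junction_pos - junction)
        if abs(off) <= tolerance:
            near_lengths.add(a.flank_length)
        offsets.append((off, off + a.flank_length))
    if len(near_lengths) < min_stack:
        return False
    lo = min(o for o, _ in offsets)
    hi = max(e for _, e in offsets)
    cov = np.zeros(hi - lo + 1, dtype=int)
    for o, e in offsets:
        cov[o - lo:e - lo] += 1
    start = max(tolerance - lo, 0)
    tail = cov[start:]
    return bool(np.all(np.diff(tail) <= 0))


def call_sites(
    blocks: Iterable[MasterBlock],
    junction_tolerance: int = DEFAULT_JUNCTION_TOLERANCE,
    min_stack: int = DEFAULT_MIN_STACK,
    replicates: Sequence[str] = REPLICATES,
) -> list[SiteCall]:
    """Per block and arm: modal junction, strand, molecule counts, QC flags.

    Counts are kept strictly per arm; experimental and control molecules are
    never pooled even when they share a block.  A block with conflicting
    strands takes the majority strand and reports the minority fraction.
    """
    calls: list[SiteCall] = []
    for block in blocks:
        by_arm: dict[str, list[FlankAlignment]] = defaultdict(list)
        for a in block.members:
            by_arm[a.arm].append(a)
        for arm in sorted(by_arm):
            members = by_arm[arm]
            strand_counts = Counter(a.strand for a in members)
            strand = max(sorted(strand_counts), key=strand_counts.__getitem__)
            minority = 1.0 - strand_counts[strand] / len(members)
            junction = _modal_junction(members)
            lengths = dedup_unique_lengths(members)
            counts = {
                rep: len(lengths.get((arm, rep), ())) for rep in replicates
            }
            pooled = len(
                set().union(*(lengths.get((arm, r), set())
                              for r in replicates))
            )
            calls.append(
                SiteCall(
                    block_id=block.block_id,
                    arm=arm,
                    chrom=block.interval.chrom,
                    junction_pos=junction,
                    strand=strand,
                    counts=counts,
                    unique_lengths_total=pooled,
                    median_read_sample=float(
                        statistics.median(counts.values())
                    ),
                    stack_ok=_stack_ok(
                        members, junction, strand,
                        junction_tolerance, min_stack,
                    ),
                    minority_strand_frac=minority,
                )
            )
    return calls


def replicate_concordance(
    calls: Iterable[SiteCall],
    arm: str = "experimental",
    replicates: Sequence[str] = REPLICATES,
) -> dict[str, Optional[float]]:
    """Pairwise Spearman rank correlation of per-site molecule counts.

    Vectors are per-replicate unique-length counts over all sites of one arm;
    ties get average ranks (scipy definition).  With fewer than 3 sites the
    correlations are undefined and reported as None.
    """
    site_counts = [c.counts for c in calls if c.arm == arm]
    result: dict[str, Optional[float]] = {}
    for i, r1 in enumerate(replicates):
        for r2 in replicates[i + 1:]:
            key = f"{r1}-{r2}"
            if len(site_counts) < 3:
                result[key] = None
                continue
            x = [c[r1] for c in site_counts]
            y = [c[r2] for c in site_counts]
            with warnings.catch_warnings():
                # constant input -> NaN, reported as undefined (None) below
                warnings.simplefilter("ignore", sp_stats.ConstantInputWarning)
                rho = sp_stats.spearmanr(x, y).statistic
            result[key] = None if np.isnan(rho) else float(rho)
    return result
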