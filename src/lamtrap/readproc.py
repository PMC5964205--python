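"""Junction-tag trimming and flank mapping.

nrLAM-PCR junction reads begin with the transposon-end tag; everything after
it is genomic flank whose first base is the integration junction.  Trimming is
a Hamming-prefix match (substitutions only).  The built-in mapper is an
exact-seed (first 20 nt) + full-length Hamming-extension aligner suited to
desk-scale references; genome-scale data is expected to come through
``import_alignments`` from an external aligner's BED/SAM output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pysam
from Bio import SeqIO

from .cassette import TOL2_TAG
from .genome_models import GenomicInterval, revcomp

SEED_LEN = 20
DEFAULT_MAX_TAG_MISMATCH = 2
DEFAULT_MIN_FLANK = 25
DEFAULT_MAX_MAP_MISMATCH = 2


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    flank_sequence: str
    arm: str = ""
    replicate: str = ""
    library_id: str = ""
    concatemer_truncated: bool = False

    @property
    def flank_length(self) -> int:
        return len(self.flank_sequence)


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # no_tag | too_short | empty | unmapped | multimapped


@dataclass(frozen=True)
class FlankAlignment:
    """A trimmed read's unique genomic placement.

    ``junction_pos`` is the coordinate of the tag-adjacent flank end:
    interval.start on +, interval.end - 1 on -.
    """

    read_id: str
    interval: GenomicInterval
    mismatches: int
    arm: str = ""
    replicate: str = ""

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def junction_pos(self) -> int:
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def flank_length(self) -> int:
        return len(self.interval)


def _hamming(a: str, b: str) -> int:
    return sum(x != y or x == "N" for x, y in zip(a, b))


def trim_tag(
    read_id: str,
    sequence: str,
    tag: str = TOL2_TAG,
    max_mismatch: int = DEFAULT_MAX_TAG_MISMATCH,
    min_flank: int = DEFAULT_MIN_FLANK,
    arm: str = "",
    replicate: str = "",
    library_id: str = "",
) -> TrimmedRead | Rejection:
    """Strip the junction tag off a read, or reject it.

    The prefix must match ``tag`` within ``max_mismatch`` substitutions
    (ambiguous bases count as mismatches).  A second exact tag occurrence in
    the flank marks a transposon concatemer: the flank is truncated before it
    and flagged.  Flanks shorter than ``min_flank`` are rejected.
    """
    if not tag:
        raise ValueError("tag must be non-empty")
    if not sequence:
        return Rejection(read_id, "empty")
    if len(sequence) < len(tag):
        return Rejection(read_id, "no_tag")
    if _hamming(sequence[: len(tag)], tag) > max_mismatch:
        return Rejection(read_id, "no_tag")
    flank = sequence[len(tag):]
    truncated = False
    second = flank.find(tag)
    if second != -1:
        flank = flank[:second]
        truncated = True
    if len(flank) < min_flank:
        return Rejection(read_id, "too_short")
    return TrimmedRead(read_id, flank, arm, replicate, library_id, truncated)


def trim_fastq(
    path: str | os.PathLike,
    arm: str = "",
    replicate: str = "",
    library_id: str = "",
    **kwargs,
) -> tuple[list[TrimmedRead], list[Rejection]]:
    trimmed, rejected = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        result = trim_tag(
            rec.id, str(rec.seq).upper(),
            arm=arm, replicate=replicate, library_id=library_id, **kwargs,
        )
        (trimmed if isinstance(result, TrimmedRead) else rejected).append(
            result
        )
    return trimmed, rejected


class FlankMapper:
    """Exact-seed + Hamming-extension mapper over a small reference.

    The first SEED_LEN bases of the flank (or of its reverse complement, for
    minus-strand placements) must match the genome exactly; candidate loci are
    then verified over the full flank length allowing up to ``max_mismatch``
    substitutions.  The unique best placement wins; ties across loci are
    rejected as multimapped.
    """

    def __init__(
        self,
        genome: Mapping[str, str],
        max_mismatch: int = DEFAULT_MAX_MAP_MISMATCH,
        seed_len: int = SEED_LEN,
    ):
        self.genome = dict(genome)
        self.max_mismatch = max_mismatch
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[i:i + seed_len], []).append(
                    (chrom, i)
                )

    def _candidates(self, flank: str):
        """(chrom, start, strand, mismatches) for verified placements."""
        L = len(flank)
        out = []
        fwd = self._index.get(flank[: self.seed_len], ())
        for chrom, i in fwd:
            ref = self.genome[chrom][i:i + L]
            if len(ref) == L:
                mm = _hamming(ref, flank)
                if mm <= self.max_mismatch:
                    out.append((chrom, i, "+", mm))
        rc = revcomp(flank)
        rev = self._index.get(rc[: self.seed_len], ())
        for chrom, i in rev:
            ref = self.genome[chrom][i:i + L]
            if len(ref) == L:
                mm = _hamming(ref, rc)
                if mm <= self.max_mismatch:
                    out.append((chrom, i, "-", mm))
        return out

    def map_flank(self, read: TrimmedRead) -> FlankAlignment | Rejection:
        flank = read.flank_sequence
        if len(flank) < self.seed_len:
            return Rejection(read.read_id, "unmapped")
        bad = set(flank) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{read.read_id}: non-ACGTN characters {sorted(bad)}"
            )
        cands = self._candidates(flank)
        if not cands:
            return Rejection(read.read_id, "unmapped")
        best_mm = min(c[3] for c in cands)
        best = [c for c in cands if c[3] == best_mm]
        if len(best) > 1:
            return Rejection(read.read_id, "multimapped")
        chrom, start, strand, mm = best[0]
        return FlankAlignment(
            read.read_id,
            GenomicInterval(chrom, start, start + len(flank), strand),
            mm,
            arm=read.arm,
            replicate=read.replicate,
        )

    def map_all(
        self, reads: Iterable[TrimmedRead]
    ) -> tuple[list[FlankAlignment], list[Rejection]]:
        aligned, rejected = [], []
        for read in reads:
            result = self.map_flank(read)
            (aligned if isinstance(result, FlankAlignment) else rejected
             ).append(result)
        return aligned, rejected


# ---------------------------------------------------------------------------
# BED / SAM interchange


def write_bed(path: str | os.PathLike, alignments: Iterable[FlankAlignment]):
    """BED6: name = read_id, score = mismatch count."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f"{a.interval.chrom}\t{a.interval.start}\t{a.interval.end}\t"
                f"{a.read_id}\t{a.mismatches}\t{a.strand}\n"
            )


def parse_sample_name(path: str | os.PathLike) -> tuple[str, str]:
    """(arm, replicate) from the `<arm>_<replicate>` filename convention."""
    stem = Path(path).stem
    if "_" not in stem:
        raise ValueError(
            f"{path}: cannot parse arm/replicate from filename"
        )
    arm, rep = stem.rsplit("_", 1)
    return arm, rep


def import_alignments(
    path: str | os.PathLike,
    arm: Optional[str] = None,
    replicate: Optional[str] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> list[FlankAlignment]:
    """Load externally produced alignments (BED6 or SAM).

    junction_pos is recomputed from the strand; SAM records must be primary
    and mapped (soft-clipped length counts toward the fragment length via the
    reference span, matching unique-length semantics on mapped coordinates).
    """
    if arm is None or replicate is None:
        arm, replicate = parse_sample_name(path)
    suffix = Path(path).suffix.lower()
    if suffix == ".sam":
        return _import_sam(path, arm, replicate, chrom_lengths)
    return _import_bed(path, arm, replicate, chrom_lengths)


def _check_bounds(chrom, end, chrom_lengths, where):
    if chrom_lengths is not None:
        if chrom not in chrom_lengths or end > chrom_lengths[chrom]:
            raise ValueError(
                f"{where}: coordinates {chrom}:{end} beyond reference"
            )


def _import_bed(path, arm, replicate, chrom_lengths) -> list[FlankAlignment]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED6 requires 6 fields "
                    f"(strand missing?)"
                )
            chrom, start, end, name, score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            _check_bounds(chrom, int(end), chrom_lengths,
                          f"{path}: line {lineno}")
            out.append(
                FlankAlignment(
                    name,
                    GenomicInterval(chrom, int(start), int(end), strand),
                    int(float(score)) if score != "." else 0,
                    arm=arm,
                    replicate=replicate,
                )
            )
    return out


def _import_sam(path, arm, replicate, chrom_lengths) -> list[FlankAlignment]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            strand = "-" if rec.is_reverse else "+"
            _check_bounds(rec.reference_name, rec.reference_end,
                          chrom_lengths, f"{path}: read {rec.query_name}")
            mm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                FlankAlignment(
                    rec.query_name,
                    GenomicInterval(
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        strand,
                    ),
                    int(mm),
                    arm=arm,
                    replicate=replicate,
                )
            )
    return out
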