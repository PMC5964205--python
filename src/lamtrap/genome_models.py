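"""Genome and gene-structure models, plus gene-trap fusion prediction.

The central question this module answers: given a transposon integration site,
will splice-acceptor capture produce an in-frame host-protein::reporter fusion,
with which frame variant, and how long is the retained N-terminal fragment?

Coordinates are 0-based half-open throughout (BED convention); GTF input is
converted on read and positions are re-expressed 1-based only in exported
reports.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

from .cassette import matching_variant

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval: 0-based start, half-open end."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Transcript:
    """Exon/CDS structure of one transcript.

    ``exons`` are in transcription order (ascending genomic coordinates on +,
    descending on -); ``cds`` is parallel to ``exons`` with the coding
    sub-interval of each exon, or None for UTR-only exons.  The CDS is taken to
    include the stop codon (a separate ``stop_codon`` GTF feature is merged in
    on read), so a complete CDS translates to total/3 - 1 residues.
    """

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[Optional[GenomicInterval], ...]

    def __post_init__(self) -> None:
        if len(self.exons) != len(self.cds):
            raise ValueError("cds must be parallel to exons")
        strand = self.exons[0].strand
        coords = [(e.start, e.end) for e in self.exons]
        ordered = coords if strand == "+" else coords[::-1]
        if ordered != sorted(ordered):
            raise ValueError(
                f"{self.transcript_id}: exons not in transcription order"
            )
        for (s1, e1), (s2, e2) in zip(sorted(coords), sorted(coords)[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{s1}-{e1} and {s2}-{e2}"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return GenomicInterval(
            self.exons[0].chrom, min(starts), max(ends), self.strand
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def total_cds_nt(self) -> int:
        return sum(len(c) for c in self.cds if c is not None)

    @property
    def is_coding(self) -> bool:
        return self.total_cds_nt > 0

    @property
    def is_complete(self) -> bool:
        """True when the CDS (with stop) is a non-empty multiple of 3."""
        return self.is_coding and self.total_cds_nt % 3 == 0

    @property
    def protein_length_aa(self) -> Optional[int]:
        """Residues of the full translation, stop codon excluded."""
        if not self.is_complete:
            return None
        return self.total_cds_nt // 3 - 1

    def upstream_cds_nt(self, intron_index: int) -> int:
        """Coding nucleotides in exons upstream of 1-based ``intron_index``."""
        if not 1 <= intron_index <= self.n_exons - 1:
            raise IndexError(
                f"intron index {intron_index} out of range for "
                f"{self.n_exons}-exon transcript {self.transcript_id}"
            )
        return sum(
            len(c) for c in self.cds[:intron_index] if c is not None
        )

    def intron_interval(self, intron_index: int) -> GenomicInterval:
        """Genomic interval of the 1-based ``intron_index``-th intron."""
        up = self.exons[intron_index - 1]
        down = self.exons[intron_index]
        if self.strand == "+":
            return GenomicInterval(up.chrom, up.end, down.start, "+")
        return GenomicInterval(up.chrom, down.end, up.start, "-")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    span: GenomicInterval
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.strand != self.span.strand:
                raise ValueError(
                    f"{self.gene_id}: transcript {t.transcript_id} strand "
                    f"disagrees with gene span"
                )

    @property
    def strand(self) -> str:
        return self.span.strand

    def canonical_transcript(
        self, override: Optional[str] = None
    ) -> Optional[Transcript]:
        """Fusion transcript: longest complete CDS, or an explicit override.

        Ties broken by transcript_id for determinism.  Returns None when the
        gene has no complete-CDS transcript (excluded from fusion prediction).
        """
        if override is not None:
            for t in self.transcripts:
                if t.transcript_id == override:
                    return t
            raise KeyError(
                f"{self.gene_id}: no transcript {override!r}"
            )
        complete = [t for t in self.transcripts if t.is_complete]
        if not complete:
            return None
        return max(complete, key=lambda t: (t.total_cds_nt, t.transcript_id))


class Annotation:
    """A set of gene models with fast point lookup by chromosome."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
            tree = self._trees.setdefault(g.span.chrom, IntervalTree())
            tree.addi(g.span.start, g.span.end, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        if chrom not in self._trees:
            raise KeyError(f"chromosome {chrom!r} absent from annotation")
        hits = self._trees[chrom].at(pos)
        return sorted(
            (self.genes[h.data] for h in hits),
            key=lambda g: (g.span.start, g.gene_id),
        )


# ---------------------------------------------------------------------------
# readers


def read_genome(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA into a name -> uppercase sequence mapping."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {record.id!r} has empty sequence")
        if record.id in genome:
            raise ValueError(f"duplicate FASTA record {record.id!r}")
        genome[record.id] = seq
    return genome


def _validate_gtf_lines(path: str | os.PathLike) -> int:
    """Pre-scan a GTF: every feature line must carry gene_id.

    Returns the number of feature lines, so an empty file can be detected
    before gffutils (which errors on truly empty input).
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            n += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 GTF fields, "
                    f"got {len(fields)}"
                )
            if "gene_id" not in fields[8]:
                raise ValueError(
                    f"{path}: line {lineno}: missing gene_id attribute"
                )
    return n


def read_annotation(path: str | os.PathLike) -> Annotation:
    """Read a GTF into gene models.

    gene/transcript feature lines are used when present; otherwise gffutils
    infers them from exon records.  CDS segments are merged with any
    stop_codon features so the stored CDS includes the stop; transcripts whose
    CDS is not a multiple of 3 are kept but flagged incomplete (and thereby
    excluded from fusion prediction).
    """
    if _validate_gtf_lines(path) == 0:
        return Annotation([])
    with open(path) as fh:
        has_gene_lines = any(
            not ln.startswith("#")
            and len(ln.split("\t")) >= 3
            and ln.split("\t")[2] == "gene"
            for ln in fh
        )
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=has_gene_lines,
        disable_infer_transcripts=has_gene_lines,
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        transcripts = []
        for tf in db.children(gf, featuretype="transcript", order_by="start"):
            exon_feats = list(
                db.children(tf, featuretype="exon", order_by="start")
            )
            if not exon_feats:
                continue
            cds_feats = list(db.children(tf, featuretype="CDS")) + list(
                db.children(tf, featuretype="stop_codon")
            )
            exons = []
            cds: list[Optional[GenomicInterval]] = []
            ordered = exon_feats if gf.strand == "+" else exon_feats[::-1]
            for ef in ordered:
                e = GenomicInterval(ef.seqid, ef.start - 1, ef.end, gf.strand)
                exons.append(e)
                pieces = [
                    (max(e.start, cf.start - 1), min(e.end, cf.end))
                    for cf in cds_feats
                    if cf.start - 1 < e.end and cf.end > e.start
                ]
                if pieces:
                    cds.append(
                        GenomicInterval(
                            e.chrom,
                            min(s for s, _ in pieces),
                            max(x for _, x in pieces),
                            gf.strand,
                        )
                    )
                else:
                    cds.append(None)
            transcripts.append(
                Transcript(tf.id, tuple(exons), tuple(cds))
            )
        if not transcripts:
            continue
        name = gf.attributes.get("gene_name", [gf.id])[0]
        span = GenomicInterval(gf.seqid, gf.start - 1, gf.end, gf.strand)
        genes.append(GeneModel(gf.id, name, span, tuple(transcripts)))
    return Annotation(genes)


def read_gene_spans_bed(path: str | os.PathLike) -> Annotation:
    """Fallback reader: gene spans only, from BED (>=6 columns, name=gene id).

    Produces transcript-less gene models usable for genic/intergenic calls but
    not for fusion prediction.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: need >= 6 BED columns"
                )
            chrom, start, end, name, _, strand = fields[:6]
            genes.append(
                GeneModel(
                    name, name,
                    GenomicInterval(chrom, int(start), int(end), strand),
                    (),
                )
            )
    return Annotation(genes)


# ---------------------------------------------------------------------------
# fusion prediction


def intron_phase(transcript: Transcript, intron_index: int) -> Optional[int]:
    """Phase of a 1-based intron: upstream coding nt mod 3.

    Undefined (None) when no coding nucleotide lies upstream, i.e. the intron
    precedes the CDS start.
    """
    up = transcript.upstream_cds_nt(intron_index)
    if up == 0:
        return None
    return up % 3


@dataclass(frozen=True)
class InsertionContext:
    """Where an integration site lands relative to gene structure."""

    site: GenomicInterval  # single-base junction interval
    orientation: str  # strand of the trap's SA cassette
    status: str  # intronic | exonic | intergenic | genic (span-only model)
    gene: Optional[GeneModel] = None
    transcript: Optional[Transcript] = None
    intron_index: Optional[int] = None
    upstream_cds_nt: Optional[int] = None

    @property
    def co_oriented(self) -> bool:
        return self.gene is not None and self.gene.strand == self.orientation


def locate_insertion(
    annotation: Annotation,
    chrom: str,
    pos: int,
    orientation: str,
    transcript_override: Optional[str] = None,
) -> InsertionContext:
    """Resolve a junction coordinate against gene structure.

    When several genes contain the site, a gene on the same strand as the
    cassette is preferred (an antisense-only overlap still yields the gene so
    that the orientation filter can report it as anti-oriented).  Within the
    chosen gene the fusion transcript (longest complete CDS, or the override)
    decides intron/exon status.
    """
    if orientation not in VALID_STRANDS:
        raise ValueError(f"invalid orientation {orientation!r}")
    site = GenomicInterval(chrom, pos, pos + 1, orientation)
    candidates = annotation.genes_at(chrom, pos)
    if not candidates:
        return InsertionContext(site, orientation, "intergenic")
    same = [g for g in candidates if g.strand == orientation]
    gene = (same or candidates)[0]
    if not gene.transcripts:
        # span-only model (BED fallback): genic, but no fusion prediction
        return InsertionContext(site, orientation, "genic", gene)
    t = gene.canonical_transcript(transcript_override)
    if t is None or not t.span.contains(pos):
        return InsertionContext(site, orientation, "intergenic")
    for exon in t.exons:
        if exon.contains(pos):
            return InsertionContext(site, orientation, "exonic", gene, t)
    for i in range(1, t.n_exons):
        if t.intron_interval(i).contains(pos):
            return InsertionContext(
                site,
                orientation,
                "intronic",
                gene,
                t,
                intron_index=i,
                upstream_cds_nt=t.upstream_cds_nt(i),
            )
    # inside the transcript span but neither exon nor intron cannot happen
    raise AssertionError("unreachable: position inside span but unplaced")


@dataclass(frozen=True)
class FusionPrediction:
    """Outcome of splice-acceptor capture at one insertion site."""

    viable: bool
    matching_variants: frozenset[int] = frozenset()
    truncation_aa: int = 0
    intron_index: Optional[int] = None
    upstream_cds_nt: Optional[int] = None


def predict_fusion(
    context: InsertionContext, variant: Optional[int] = None
) -> FusionPrediction:
    """Predict fusion viability, frame variant and N-terminal truncation.

    Viable requires an intronic, co-oriented site with at least one complete
    codon of coding sequence upstream.  Exactly one of the three C-padding
    variants complements the intron phase; in all-variant mode (variant=None,
    the screen pooled all three vectors) that variant is reported, in strict
    mode the supplied variant must itself match.  The residue encoded by the
    chimeric padded codon is not counted: truncation_aa = upstream_cds_nt // 3.
    """
    if context is None:
        raise ValueError("context is required")
    if variant is not None and variant not in (0, 1, 2):
        raise ValueError(f"variant must be 0, 1 or 2, got {variant!r}")
    if context.status != "intronic" or not context.co_oriented:
        return FusionPrediction(False, intron_index=context.intron_index,
                                upstream_cds_nt=context.upstream_cds_nt)
    up = context.upstream_cds_nt or 0
    truncation = up // 3
    # no complete codon upstream, or the native stop codon already upstream
    # (translation would terminate before ever reaching the reporter)
    if truncation < 1 or up >= context.transcript.total_cds_nt:
        return FusionPrediction(
            False, intron_index=context.intron_index, upstream_cds_nt=up
        )
    needed = matching_variant(up % 3)
    viable = variant is None or variant == needed
    plen = context.transcript.protein_length_aa
    if plen is not None and truncation > plen:
        raise AssertionError("truncation exceeds protein length")
    return FusionPrediction(
        viable=viable,
        matching_variants=frozenset({needed}),
        truncation_aa=truncation if viable else 0,
        intron_index=context.intron_index,
        upstream_cds_nt=up,
    )


def extract_cds(genome: Mapping[str, str], transcript: Transcript) -> str:
    """Spliced CDS nucleotides of a transcript, in reading orientation."""
    pieces = []
    for c in transcript.cds:
        if c is None:
            continue
        seq = genome[c.chrom][c.start:c.end]
        pieces.append(seq if transcript.strand == "+" else revcomp(seq))
    return "".join(pieces)


def upstream_cds_sequence(
    genome: Mapping[str, str], transcript: Transcript, intron_index: int
) -> str:
    """CDS nucleotides upstream of a 1-based intron, in reading orientation."""
    pieces = []
    for c in transcript.cds[:intron_index]:
        if c is None:
            continue
        seq = genome[c.chrom][c.start:c.end]
        pieces.append(seq if transcript.strand == "+" else revcomp(seq))
    return "".join(pieces)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
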