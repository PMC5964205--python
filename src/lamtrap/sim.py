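"""Synthetic nrLAM-PCR screen generator.

Emits a toy genome with embedded multi-exon genes, a ground-truth table of
transposon integration events, and per-arm / per-replicate FASTQ files with the
statistical structure the downstream pipeline assumes:

* every read is the transposon-end tag followed by a genomic flank that starts
  at the integration junction (linear amplification gives one fixed end and a
  variable-length free end);
* each original molecule at a site has a distinct flank length, and PCR
  duplicates repeat a molecule's exact length;
* each gDNA is amplified in three independent reactions (replicates A, B, C),
  each sampling a fraction of the molecules;
* the experimental arm carries true intronic co-oriented traps plus
  anti-oriented and intergenic decoys; a set of shared false-positive sites is
  seeded into both the experimental and the negative-control arm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import genome_models as gm
from .cassette import TOL2_TAG, matching_variant

ARMS = ("experimental", "control")
REPLICATES = ("A", "B", "C")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic screen.

    Counts and rates mirror the screen being emulated: ~tens of productive
    trap clones per library, triplicate nrLAM reactions, a long-tailed
    molecule-count distribution, and a negative-control arm sharing a set of
    false-positive sites with the experimental arm.
    """

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (100_000, 50_000)
    n_genes: int = 24
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (60, 180)
    intron_length: tuple[int, int] = (250, 700)
    utr_length: tuple[int, int] = (20, 80)
    n_true: int = 30
    n_anti: int = 5
    n_intergenic: int = 5
    n_control_shared: int = 10
    molecules_per_site: tuple[int, int] = (3, 60)
    flank_mean: int = 120
    flank_min: int = 25
    flank_max: int = 500
    pcr_duplication: float = 5.0
    base_error_rate: float = 0.005
    replicate_rate: float = 0.8
    three_prime_bias: float = 2.0
    min_event_separation: int = 1000
    trap_orientation: str = "same"  # or "opposite": flank strand vs gene

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_true", "n_anti", "n_intergenic",
                     "n_control_shared"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.flank_min < 20:
            raise ValueError("flank_min below mappable seed length")
        if self.trap_orientation not in ("same", "opposite"):
            raise ValueError("trap_orientation must be 'same' or 'opposite'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class InsertionEvent:
    """One simulated transposon integration (the ground truth)."""

    event_id: str
    chrom: str
    pos: int  # 0-based junction base
    orientation: str  # strand of the SA cassette
    variant: int  # C-padding variant 0/1/2
    host_gene: Optional[str]
    intron_index: Optional[int]
    arm: str  # experimental | control | both
    event_class: str  # true_trap | anti_oriented | intergenic | control_shared

    def in_arm(self, arm: str) -> bool:
        return self.arm == arm or self.arm == "both"


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# reference generation


def _random_genome(rng: np.random.Generator, lengths) -> dict[str, bytearray]:
    return {
        f"chr{i + 1}": bytearray(
            _BASES[rng.integers(0, 4, size=n)].tobytes()
        )
        for i, n in enumerate(lengths)
    }


def _sample_gene_structure(rng: np.random.Generator, cfg: SimConfig):
    """Exon/intron layout and coding sub-intervals, in gene-local + coords.

    Returns (span_length, exons, cds) where exons/cds are lists of (start, end)
    offsets from the gene start in transcription order; cds entries may be
    None.  Total coding length is forced to a multiple of 3 (stop included).
    """
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, n_ex)
    in_lens = rng.integers(
        cfg.intron_length[0], cfg.intron_length[1] + 1, n_ex - 1
    )
    utr5 = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
    utr3 = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
    utr5 = min(utr5, int(ex_lens[0]) - 30)
    utr3 = min(utr3, int(ex_lens[-1]) - 30)
    coding = [int(x) for x in ex_lens]
    coding[0] -= utr5
    coding[-1] -= utr3
    rem = sum(coding) % 3
    coding[-1] -= rem
    utr3 += rem
    exons, cds = [], []
    offset = 0
    for i, el in enumerate(ex_lens):
        el = int(el)
        exons.append((offset, offset + el))
        c_start = offset + (utr5 if i == 0 else 0)
        c_end = offset + el - (utr3 if i == n_ex - 1 else 0)
        cds.append((c_start, c_end))
        offset += el
        if i < n_ex - 1:
            offset += int(in_lens[i])
    return offset, exons, cds


def _random_cds(rng: np.random.Generator, n_nt: int) -> str:
    """ATG + stop-free random codons + a stop codon; length n_nt."""
    assert n_nt % 3 == 0 and n_nt >= 9
    n_mid = n_nt // 3 - 2
    mid = "".join(
        _CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_mid)
    )
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    return "ATG" + mid + stop


def generate_reference(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Build genome + gene models; returns (genome dict, manifest dict, gtf str).

    Genes are placed left to right with random intergenic gaps, alternating
    over chromosomes; placement failure after bounded retries raises
    GenerationError suggesting larger chromosomes.  The written CDS of every
    gene is a clean ORF (ATG ... stop, no internal stops) laid into the random
    genome sequence, reverse-complemented for minus-strand genes.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genome = _random_genome(rng, cfg.chromosome_lengths)
    chroms = list(genome)
    margin = cfg.flank_max + 200
    cursors = {c: margin for c in chroms}
    manifest_genes = []
    gtf_lines = []
    for gi in range(cfg.n_genes):
        span_len, exons, cds = _sample_gene_structure(rng, cfg)
        gap = int(rng.integers(500, 1500))
        placed = None
        for c in sorted(chroms, key=lambda c: cursors[c]):
            start = cursors[c] + gap
            if start + span_len + margin <= len(genome[c]):
                placed = (c, start)
                cursors[c] = start + span_len
                break
        if placed is None:
            raise GenerationError(
                f"could not place gene {gi + 1} of {cfg.n_genes}; "
                "use larger chromosomes"
            )
        chrom, gstart = placed
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"SIMG{gi + 1:04d}"
        tx_id = f"SIMT{gi + 1:04d}"
        gene_name = gene_id.lower()

        def to_genomic(a, b):
            if strand == "+":
                return gstart + a, gstart + b
            return gstart + span_len - b, gstart + span_len - a

        g_exons = [to_genomic(a, b) for a, b in exons]
        g_cds = [to_genomic(a, b) for a, b in cds]
        # write the coding sequence into the genome
        total_cds = sum(b - a for a, b in cds)
        coding_seq = _random_cds(rng, total_cds)
        consumed = 0
        for (a, b) in g_cds:
            piece = coding_seq[consumed:consumed + (b - a)]
            consumed += b - a
            if strand == "-":
                piece = gm.revcomp(piece)
            genome[chrom][a:b] = piece.encode()
        manifest_genes.append(
            {
                "gene_id": gene_id,
                "gene_name": gene_name,
                "transcript_id": tx_id,
                "chrom": chrom,
                "strand": strand,
                "span": [gstart, gstart + span_len],
                "exons": g_exons,  # transcription order
                "cds": g_cds,  # transcription order
                "protein_length_aa": total_cds // 3 - 1,
            }
        )
        gtf_lines.extend(
            _gtf_records(chrom, strand, gene_id, gene_name, tx_id,
                         gstart, gstart + span_len, g_exons, g_cds)
        )
    manifest = {
        "chromosomes": {c: len(genome[c]) for c in chroms},
        "genes": manifest_genes,
    }
    genome_str = {c: genome[c].decode() for c in chroms}
    return genome_str, manifest, "\n".join(gtf_lines) + ("\n" if gtf_lines else "")


def _gtf_records(chrom, strand, gene_id, gene_name, tx_id,
                 gstart, gend, g_exons, g_cds) -> list[str]:
    """GTF lines (1-based inclusive) for one single-transcript gene."""

    def line(feature, s, e, frame="."):
        attrs = (
            f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
            f'gene_name "{gene_name}";'
        )
        if feature == "gene":
            attrs = f'gene_id "{gene_id}"; gene_name "{gene_name}";'
        return "\t".join(
            [chrom, "lamtrap_sim", feature, str(s + 1), str(e), ".",
             strand, str(frame), attrs]
        )

    out = [line("gene", gstart, gend), line("transcript", gstart, gend)]
    cum = 0
    for (es, ee), (cs, ce) in zip(g_exons, g_cds):
        out.append(line("exon", es, ee))
        if ce > cs:
            frame = (3 - cum % 3) % 3
            out.append(line("CDS", cs, ce, frame))
            cum += ce - cs
    # emit in ascending coordinate order for a tidy file
    return [out[0], out[1]] + sorted(
        out[2:], key=lambda ln: int(ln.split("\t")[3])
    )


# ---------------------------------------------------------------------------
# insertion sampling


def sample_insertions(
    annotation: gm.Annotation,
    manifest: dict,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[InsertionEvent]:
    """Draw ground-truth integration events of the four classes.

    True traps (and control-shared sites, which must look like authentic traps
    so that only control subtraction can remove them) land in introns with at
    least one complete upstream codon, co-oriented, with the matching frame
    variant; anti-oriented decoys flip the cassette; intergenic decoys fall
    outside every gene span.  Intron choice is biased toward 3' introns with
    weight index**three_prime_bias.  All junctions are mutually separated by
    at least min_event_separation.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    chrom_len = manifest["chromosomes"]
    margin = cfg.flank_max + 50
    taken: list[tuple[str, int]] = []

    def far_enough(chrom: str, pos: int) -> bool:
        return all(
            c != chrom or abs(pos - p) >= cfg.min_event_separation
            for c, p in taken
        )

    # candidate introns with >=3 coding nt upstream (one full codon)
    candidates = []
    weights = []
    for g in annotation:
        t = g.canonical_transcript()
        if t is None:
            continue
        for i in range(1, t.n_exons):
            if t.upstream_cds_nt(i) >= 3:
                candidates.append((g, t, i))
                weights.append(float(i) ** cfg.three_prime_bias)
    weights_arr = np.asarray(weights)

    def draw_intronic(n: int, co_oriented: bool, klass: str, arm: str,
                      start_index: int) -> list[InsertionEvent]:
        if n == 0:
            return []
        if not candidates:
            raise GenerationError("no introns available for intronic events")
        events = []
        attempts = 0
        while len(events) < n:
            attempts += 1
            if attempts > 5000:
                raise GenerationError(
                    f"requested {n} {klass} events exceed available introns"
                )
            idx = int(rng.choice(len(candidates),
                                 p=weights_arr / weights_arr.sum()))
            g, t, i = candidates[idx]
            intron = t.intron_interval(i)
            if len(intron) < 20:
                continue
            pos = int(rng.integers(intron.start + 5, intron.end - 5))
            if pos < margin or pos > chrom_len[intron.chrom] - margin:
                continue
            if not far_enough(intron.chrom, pos):
                continue
            gene_strand = g.strand
            if co_oriented:
                orientation = gene_strand
                variant = matching_variant(t.upstream_cds_nt(i) % 3)
            else:
                orientation = "-" if gene_strand == "+" else "+"
                variant = int(rng.integers(0, 3))
            taken.append((intron.chrom, pos))
            events.append(
                InsertionEvent(
                    f"E{start_index + len(events):04d}",
                    intron.chrom, pos, orientation, variant,
                    g.gene_id, i, arm, klass,
                )
            )
        return events

    def draw_intergenic(n: int, start_index: int) -> list[InsertionEvent]:
        events = []
        attempts = 0
        chroms = list(chrom_len)
        lens = np.asarray([chrom_len[c] for c in chroms], dtype=float)
        while len(events) < n:
            attempts += 1
            if attempts > 5000:
                raise GenerationError("could not place intergenic decoys")
            chrom = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
            pos = int(rng.integers(margin, chrom_len[chrom] - margin))
            if annotation.chromosomes and chrom in annotation.chromosomes:
                near = annotation.genes_at(chrom, pos)
                if near:
                    continue
            if not far_enough(chrom, pos):
                continue
            taken.append((chrom, pos))
            events.append(
                InsertionEvent(
                    f"E{start_index + len(events):04d}",
                    chrom, pos, "+" if rng.random() < 0.5 else "-",
                    int(rng.integers(0, 3)), None, None,
                    "experimental", "intergenic",
                )
            )
        return events

    events: list[InsertionEvent] = []
    events += draw_intronic(cfg.n_true, True, "true_trap", "experimental", 1)
    events += draw_intronic(cfg.n_anti, False, "anti_oriented",
                            "experimental", len(events) + 1)
    events += draw_intergenic(cfg.n_intergenic, len(events) + 1)
    events += draw_intronic(cfg.n_control_shared, True, "control_shared",
                            "both", len(events) + 1)
    return events


# ---------------------------------------------------------------------------
# read simulation


def _flank_lengths(rng, cfg: SimConfig, n: int, max_room: int) -> list[int]:
    """n distinct flank lengths, geometric about flank_mean, min flank_min."""
    p = 1.0 / (cfg.flank_mean - cfg.flank_min + 1)
    cap = min(cfg.flank_max, max_room)
    lengths: set[int] = set()
    attempts = 0
    while len(lengths) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            break  # fewer distinct lengths than requested fit the room
        L = cfg.flank_min + int(rng.geometric(p)) - 1
        if L <= cap:
            lengths.add(L)
    return sorted(lengths)


def _read_strand_for(event: InsertionEvent, cfg: SimConfig) -> str:
    """Genomic strand of the flank read for an event.

    Under the 'same' convention the nrLAM primer exits the transposon end such
    that a co-oriented trap yields reads on the host-gene strand; 'opposite'
    flips every read strand.
    """
    if cfg.trap_orientation == "same":
        return event.orientation
    return "-" if event.orientation == "+" else "+"


def _extract_flank(genome, chrom, pos, length, strand) -> str:
    if strand == "+":
        return genome[chrom][pos:pos + length]
    return gm.revcomp(genome[chrom][pos - length + 1:pos + 1])


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return arr.tobytes().decode()


def simulate_reads(
    genome: dict[str, str],
    events: list[InsertionEvent],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Generate reads; returns (fastq dict[(arm, rep)] -> list[(id, seq)],
    read_truth rows).

    Per event and arm: a molecule count is drawn uniformly from
    molecules_per_site and that many distinct flank lengths are sampled; each
    replicate independently retains each molecule with replicate_rate; each
    retained molecule yields 1 + Poisson(pcr_duplication - 1) identical-length
    copies; substitution errors are applied to the assembled tag+flank read.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    # Independent streams so that changing the duplication factor or the
    # error rate does not perturb molecule sampling: unique-length counts are
    # then invariant under PCR duplication by construction.
    base = int(rng.integers(0, 2**31 - 4))
    rng_mol = np.random.default_rng(base)
    rng_dup = np.random.default_rng(base + 1)
    rng_err = np.random.default_rng(base + 2)
    rng_shuffle = np.random.default_rng(base + 3)
    fastq: dict[tuple[str, str], list[tuple[str, str]]] = {
        (arm, rep): [] for arm in ARMS for rep in REPLICATES
    }
    truth_rows = []
    dup_lambda = max(cfg.pcr_duplication - 1.0, 0.0)
    for event in events:
        strand = _read_strand_for(event, cfg)
        room = (
            len(genome[event.chrom]) - event.pos
            if strand == "+"
            else event.pos + 1
        )
        for arm in ARMS:
            if not event.in_arm(arm):
                continue
            n_mol = int(rng_mol.integers(cfg.molecules_per_site[0],
                                         cfg.molecules_per_site[1] + 1))
            lengths = _flank_lengths(rng_mol, cfg, n_mol, room)
            for rep in REPLICATES:
                kept = [L for L in lengths
                        if rng_mol.random() < cfg.replicate_rate]
                for mi, L in enumerate(kept):
                    flank = _extract_flank(
                        genome, event.chrom, event.pos, L, strand
                    )
                    n_copies = 1 + int(rng_dup.poisson(dup_lambda))
                    for ci in range(n_copies):
                        rid = f"{arm}_{rep}_{event.event_id}_L{L}_c{ci}"
                        seq = _apply_errors(
                            rng_err, TOL2_TAG + flank, cfg.base_error_rate
                        )
                        fastq[(arm, rep)].append((rid, seq))
                        truth_rows.append(
                            {
                                "read_id": rid,
                                "event_id": event.event_id,
                                "arm": arm,
                                "replicate": rep,
                                "flank_length": L,
                            }
                        )
    for key in fastq:
        rng_shuffle.shuffle(fastq[key])
    return fastq, truth_rows


# ---------------------------------------------------------------------------
# run directory


def write_fasta(path, genome: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate_run(cfg: SimConfig, outdir: str | os.PathLike) -> dict:
    """Full simulation into a run directory consumable by the pipeline.

    Layout: genome.fa, annotation.gtf, config.yaml, manifest.json,
    truth/events.tsv, truth/reads.tsv, reads/{arm}_{rep}.fastq.
    The manifest records the seed, config hash, the arm/replicate of every
    FASTQ and its read count.
    """
    out = Path(outdir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome, manifest, gtf = generate_reference(cfg, rng)
    write_fasta(out / "genome.fa", genome)
    (out / "annotation.gtf").write_text(gtf)
    annotation = gm.read_annotation(out / "annotation.gtf")
    events = sample_insertions(annotation, manifest, cfg, rng)
    fastq, truth_rows = simulate_reads(genome, events, cfg, rng)

    with open(out / "truth" / "events.tsv", "w") as fh:
        cols = ["event_id", "chrom", "pos", "orientation", "variant",
                "host_gene", "intron_index", "arm", "event_class"]
        fh.write("\t".join(cols) + "\n")
        for e in events:
            fh.write("\t".join(
                "" if getattr(e, c) is None else str(getattr(e, c))
                for c in cols
            ) + "\n")
    with open(out / "truth" / "reads.tsv", "w") as fh:
        cols = ["read_id", "event_id", "arm", "replicate", "flank_length"]
        fh.write("\t".join(cols) + "\n")
        for row in truth_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    files = {}
    for (arm, rep), reads in fastq.items():
        name = f"reads/{arm}_{rep}.fastq"
        with open(out / name, "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        files[name] = {"arm": arm, "replicate": rep, "n_reads": len(reads)}

    run_manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "genome": "genome.fa",
        "annotation": "annotation.gtf",
        "fastq": files,
        "n_events": len(events),
        "structure": manifest,
    }
    (out / "manifest.json").write_text(json.dumps(run_manifest, indent=1))
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    return run_manifest
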