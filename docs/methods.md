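# Methods

## Data model and coordinates

All interval arithmetic is 0-based half-open (BED convention). GTF input
(1-based inclusive) is converted on read; exported reports print 1-based
positions. A junction is a single base: the first genomic base of a read's
trimmed flank (`interval.start` on the plus strand, `interval.end − 1` on the
minus strand). The 8-bp target-site duplication of Tol2 integration is
ignored for coordinate purposes — the reported site is the junction base.

Transcript models store exons in transcription order with a parallel list of
per-exon coding sub-intervals. The stored CDS *includes* the stop codon
(separate `stop_codon` GTF features are merged in on read), so a complete CDS
has length divisible by 3 and translates to `total/3 − 1` residues; reported
protein lengths exclude the stop. Transcripts whose CDS is not a multiple of
3 are kept but flagged incomplete and excluded from fusion prediction. For
multi-transcript genes the fusion transcript is the one with the longest
complete CDS (ties broken by transcript id), overridable by explicit
transcript id.

## Fusion-frame prediction

A gene-trap insertion produces a host::reporter fusion protein iff

* the junction lies in an intron of the fusion transcript,
* the trap's SA cassette is co-oriented with transcription,
* at least one complete codon of coding sequence lies upstream, and
* the native stop codon does *not* lie upstream of the intron (otherwise
  translation terminates before the spliced-in reporter).

With φ = upstream coding nt mod 3 (the intron phase), the cassette variant
carrying `(3 − φ) mod 3` C bases before the reporter restores frame; the
15-nt SA-to-reporter spacer is a multiple of 3 and contributes no shift.
Exactly one of the three variants matches each phase-defined intron. The
default *all-variant* mode reports that variant (the screen pooled all three
vectors and the library→variant mapping is internal to the wet lab); strict
mode additionally requires a supplied variant to match.

The residue encoded by the chimeric split codon (φ native bases completed by
C padding) is not counted in the truncation: `truncation_aa =
upstream_cds_nt // 3`. This floor convention is verified in the tests by
explicitly concatenating upstream CDS + padding + spacer + reporter and
translating the construct: the fusion's first `truncation_aa` residues equal
the native protein's, for every simulated viable insertion.

Insertions in exons, in 5′-UTR introns, antisense to every overlapping gene,
or outside genes are non-viable. When genes overlap on opposite strands the
co-oriented gene wins; an antisense-only overlap still returns the gene so
the orientation filter can report the site as anti-oriented rather than
intergenic.

## Read model and trimming

Every junction read is the 23-nt transposon-end tag followed by the genomic
flank. Trimming is a Hamming prefix match, substitutions only, default ≤ 2
mismatches over the tag (ambiguous bases count as mismatches); flanks shorter
than 25 nt are rejected as unreliable to place. A second exact tag occurrence
inside the flank marks a transposon concatemer; the flank is truncated before
it and flagged. The tag is configurable — the published nrLAM adapter carries
two extra 5′ bases (GA) whose presence in reads depends on the sequencing
setup.

## Mapping

The built-in mapper is exact-seed (first 20 nt of the flank, or of its
reverse complement for minus-strand placements) plus full-length Hamming
verification, ≤ 2 mismatches, unique-best-placement; ties across loci are
rejected as multimapped. It is deliberately desk-scale: equivalent to an
exhaustive sliding-window scan whenever the strand-specific seed region is
error-free (verified against that oracle on 1000 random flanks), and a read
with an error inside its seed is simply dropped as unmapped — a sensitivity
loss of roughly `1 − (1−e)^20` per read at substitution rate *e* (~9% at the
default 0.005), which unique-length counting absorbs because each molecule is
sequenced several times. Genome-scale data should come from an external
aligner through `import_alignments` (BED6 or SAM; primary mapped records
only; the reference span serves as the fragment length, matching the
unique-length semantics on mapped coordinates).

## Master blocks, site calls and QC

Master blocks are the transitive closure of pairwise interval overlap over
the alignments of *all* samples jointly (single-linkage sweep; equality with
a union-find closure oracle is tested on 1000 random intervals). Block ids
are assigned in (chrom, start) order and are input-order invariant.

Per block and arm, the site call takes the modal junction (ties → smallest
coordinate), majority strand (minority fraction reported), and unique-length
counts per replicate plus pooled over replicates. Counts are never pooled
across arms. `median_read_sample` is the middle order statistic of the three
replicate counts.

The `stack_ok` pyramid test formalizes the expected junction-anchored read
arrangement: ≥ 3 distinct flank lengths must share the modal junction within
± 2 bp (`junction_tolerance`, absorbing alignment jitter), and per-base
coverage must be non-increasing with distance from the junction beyond that
tolerance window. Two junction clusters in one block (e.g. 500 bp apart)
fail this test.

Replicate concordance is the pairwise Spearman rank correlation (average
ranks for ties) of per-site molecule counts among reactions A, B and C;
undefined (reported as null) below 3 sites.

## Filter ledger

Reporting order: minimum pooled unique-length reads (default 3, boundary
inclusive) → orientation/stack → control subtraction → genic fusion
viability. The filters are independent predicates, so the survivor set is
order-independent; only the attribution of each discard to its first failing
filter depends on the order, and the trace conserves sites
(input = survivors + Σ per-filter discards). Control subtraction works at
master-block resolution with presence threshold 1 pooled unique length in
the control arm (conservative discard; configurable). The "> 30 unique
reads" depth tier is strict and, by default, descriptive stratification
rather than a discard rule — the narrative path that hard-filters the long
tail is available via `hard_depth_filter`. A missing control arm skips
subtraction with a prominent warning rather than failing.

Genes with ≥ 2 surviving sites in distinct master blocks are
high-confidence; no minimum junction separation beyond block identity is
imposed.

## The synthetic screen

The generator's defaults are the study conditions under which the pipeline
is validated: two chromosomes of 100 kb and 50 kb; 24 genes of 4–7 exons
(60–180 nt) separated by 250–700 nt introns, each with a clean ORF
(ATG…stop, no internal stops) written into the random genome sequence;
30 true traps, 5 anti-oriented decoys, 5 intergenic decoys and 10
control-shared sites (planted in both arms so that only control subtraction
can remove them); molecules per site uniform 3–60; flank lengths geometric
with mean 120 nt, minimum 25 nt, capped at 500 nt; PCR duplication
1 + Poisson(4) copies per molecule (mean 5×); substitution errors at
0.005/nt; each replicate independently retains 80% of molecules. True-trap
introns are drawn with weight `index²`, biasing insertions toward 3′ introns
as NMD-escape selection does in the real screen. Junctions are mutually
separated by ≥ 1 kb (> the flank cap), so distinct events can never share a
master block. Random draws are split into independent streams (molecules /
duplication / errors / shuffling), which makes unique-length counts exactly
invariant under the duplication factor and makes the error rate orthogonal
to molecule sampling.

What the simulator does **not** emulate, and hence what passing tests do not
show about real data: Ion Torrent homopolymer indels (substitution errors
only; quality strings are constant), chimeric/artifact reads, clonal
abundance differences between sites beyond the molecule-count distribution,
cross-mapping in repetitive genomes, and selection dynamics
(neomycin/FACS). Real-data scale should enter through `import_alignments`.

Within these conditions, the end-to-end checks are: recovery of 100% of
true traps that retain ≥ 3 molecules after subsampling with zero decoys of
any class in the final hit table (5 seeds), and median pairwise replicate
Spearman ρ > 0.9 across 10 seeds (observed ≈ 0.93–0.98; the discreteness of
small molecule counts keeps it below a perfect rank agreement).

## Numerical and degenerate-input choices

Strand ties in a block resolve to the majority, then lexicographically;
junction ties to the smallest coordinate. Empty inputs yield empty outputs
(empty FASTA → empty genome; empty GTF → empty annotation; empty manifest →
empty hit table) rather than errors. Sites for which zero molecules are
drawn are silently absent. Seeds fully determine all simulator and pipeline
outputs; reruns are byte-identical.

## Problem sizes

The shipped validation runs use the default synthetic conditions above
(~20–25 k reads per screen, 150 kb genome); oracle equivalences are checked
on 1000 random flanks / intervals. These sizes exercise every code path
while keeping the whole suite fast and deterministic.

## Known limitations

* The published screen's half-integer `Median_read_sample` values imply a
  median over an even number of samples; pipeline-computed medians are over
  the three reactions, so the two definitions coincide only up to that
  convention.
* Published truncation lengths are reported as printed; where a gene has
  several annotated isoforms the printed protein length fixes which isoform
  the truncation refers to, and no reconciliation across isoforms is
  attempted.
* The built-in mapper is not indel-aware and is not meant for
  reference-genome scale.
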