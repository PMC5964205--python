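"""Gene-structure models and fusion-frame prediction."""

import pytest

from lamtrap import genome_models as gm
from lamtrap.cassette import cassette_tail, matching_variant

from _oracles import translate


# ---------------------------------------------------------------------------
# read_genome


def test_read_genome_empty_file(tmp_path):
    p = tmp_path / "empty.fa"
    p.write_text("")
    assert gm.read_genome(p) == {}


def test_read_genome_uppercases_and_preserves_lengths(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">a\nacgTT\ngg\n>b\nTTTT\n")
    g = gm.read_genome(p)
    assert g == {"a": "ACGTTGG", "b": "TTTT"}


def test_read_genome_rejects_empty_record(tmp_path):
    p = tmp_path / "bad.fa"
    p.write_text(">ok\nACGT\n>broken\n>next\nACGT\n")
    with pytest.raises(ValueError, match="broken"):
        gm.read_genome(p)


def test_read_genome_matches_simulator_manifest(default_sim, default_genome,
                                                default_manifest):
    lengths = {c: len(s) for c, s in default_genome.items()}
    assert lengths == default_manifest["structure"]["chromosomes"]
    assert lengths == {"chr1": 100_000, "chr2": 50_000}


# ---------------------------------------------------------------------------
# read_annotation


def test_read_annotation_empty(tmp_path):
    p = tmp_path / "empty.gtf"
    p.write_text("# nothing here\n")
    assert len(gm.read_annotation(p)) == 0


def test_read_annotation_matches_simulator_structure(default_annotation,
                                                     default_manifest):
    truth = {g["gene_id"]: g for g in default_manifest["structure"]["genes"]}
    assert set(default_annotation.genes) == set(truth)
    for gene in default_annotation:
        t = gene.canonical_transcript()
        info = truth[gene.gene_id]
        assert t.n_exons == len(info["exons"])
        assert gene.strand == info["strand"]
        assert t.protein_length_aa == info["protein_length_aa"]
        assert [list((c.start, c.end)) if c else None for c in t.cds] == [
            list(c) for c in info["cds"]
        ]


def test_read_annotation_keeps_ensembl_style_ids(tmp_path):
    gtf = (
        'chr18\tx\tgene\t100\t500\t.\t+\t.\tgene_id "ENSG00000134030"; '
        'gene_name "CTIF";\n'
        'chr18\tx\ttranscript\t100\t500\t.\t+\t.\tgene_id "ENSG00000134030"; '
        'transcript_id "T1";\n'
        'chr18\tx\texon\t100\t500\t.\t+\t.\tgene_id "ENSG00000134030"; '
        'transcript_id "T1";\n'
    )
    p = tmp_path / "ensg.gtf"
    p.write_text(gtf)
    ann = gm.read_annotation(p)
    assert "ENSG00000134030" in ann.genes
    assert ann.genes["ENSG00000134030"].gene_name == "CTIF"


def test_read_annotation_missing_gene_id_reports_line(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text(
        'chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "G1"; transcript_id "T";\n'
        "chr1\tx\texon\t20\t30\t.\t+\t.\tsomething_else;\n"
    )
    with pytest.raises(ValueError, match="line 2"):
        gm.read_annotation(p)


def test_read_annotation_rejects_overlapping_exons(tmp_path):
    gtf = "".join(
        f'chr1\tx\t{f}\t{s}\t{e}\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        for f, s, e in [
            ("gene", 1, 100), ("transcript", 1, 100),
            ("exon", 1, 50), ("exon", 40, 100),
        ]
    )
    p = tmp_path / "overlap.gtf"
    p.write_text(gtf)
    with pytest.raises(ValueError, match="overlap"):
        gm.read_annotation(p)


def test_read_gene_spans_bed_fallback(tmp_path):
    p = tmp_path / "genes.bed"
    p.write_text("chr1\t100\t900\tGENEA\t0\t+\nchr2\t0\t50\tGENEB\t0\t-\n")
    ann = gm.read_gene_spans_bed(p)
    assert set(ann.genes) == {"GENEA", "GENEB"}
    ctx = gm.locate_insertion(ann, "chr1", 500, "+")
    assert ctx.status == "genic" and ctx.gene.gene_id == "GENEA"
    assert not gm.predict_fusion(ctx).viable


# ---------------------------------------------------------------------------
# intron phase


@pytest.mark.parametrize(
    "intron_index, expected",
    [(1, 1), (2, 0), (3, 1), (4, 2)],  # upstream CDS: 100, 147, 247, 323 nt
)
def test_intron_phase_modular_sum(toy_annotation, intron_index, expected):
    t = toy_annotation.genes["TOYG1"].transcripts[0]
    assert gm.intron_phase(t, intron_index) == expected


def test_intron_phase_multiple_of_three(toy_annotation):
    # single upstream coding exon of 300 nt -> phase 0
    e1 = gm.GenomicInterval("chr1", 0, 400, "+")
    e2 = gm.GenomicInterval("chr1", 1000, 1100, "+")
    t = gm.Transcript(
        "T", (e1, e2), (gm.GenomicInterval("chr1", 50, 350, "+"), None)
    )
    assert gm.intron_phase(t, 1) == 0


def test_intron_phase_undefined_in_utr_intron():
    # first exon entirely untranslated: the intron precedes the CDS start
    e1 = gm.GenomicInterval("chr1", 0, 100, "+")
    e2 = gm.GenomicInterval("chr1", 500, 700, "+")
    t = gm.Transcript(
        "T", (e1, e2), (None, gm.GenomicInterval("chr1", 550, 700, "+"))
    )
    assert gm.intron_phase(t, 1) is None


def test_intron_phase_out_of_range(toy_annotation):
    t = toy_annotation.genes["TOYG1"].transcripts[0]
    with pytest.raises(IndexError):
        gm.intron_phase(t, 5)
    with pytest.raises(IndexError):
        gm.intron_phase(t, 0)


# ---------------------------------------------------------------------------
# locate_insertion


def test_locate_intergenic(toy_annotation_complete):
    ctx = gm.locate_insertion(toy_annotation_complete, "chr1", 5000, "+")
    assert ctx.status == "intergenic" and ctx.gene is None


def test_locate_unknown_chromosome(toy_annotation_complete):
    with pytest.raises(KeyError):
        gm.locate_insertion(toy_annotation_complete, "chrUn", 10, "+")


def test_locate_exonic(toy_annotation_complete):
    ctx = gm.locate_insertion(toy_annotation_complete, "chr1", 120, "+")
    assert ctx.status == "exonic"


def test_locate_intron3_upstream_cds_hand_summed(toy_annotation_complete):
    # intron 3 spans (900, 1200) 0-based; upstream CDS = 100 + 47 + 100
    ctx = gm.locate_insertion(toy_annotation_complete, "chr1", 1000, "+")
    assert ctx.status == "intronic"
    assert ctx.intron_index == 3
    assert ctx.upstream_cds_nt == 247


def test_locate_prefers_co_oriented_gene_on_antisense_overlap(tmp_path):
    lines = []
    for gid, strand in (("GPLUS", "+"), ("GMINUS", "-")):
        for f, s, e in (("gene", 100, 1000), ("transcript", 100, 1000),
                        ("exon", 100, 1000), ("CDS", 200, 499)):
            lines.append(
                f"chr1\tx\t{f}\t{s}\t{e}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{gid}T";\n'
            )
    p = tmp_path / "two.gtf"
    p.write_text("".join(lines))
    ann = gm.read_annotation(p)
    assert gm.locate_insertion(ann, "chr1", 500, "+").gene.gene_id == "GPLUS"
    assert gm.locate_insertion(ann, "chr1", 500, "-").gene.gene_id == "GMINUS"


# ---------------------------------------------------------------------------
# predict_fusion


def test_predict_fusion_intergenic_not_viable(toy_annotation_complete):
    ctx = gm.locate_insertion(toy_annotation_complete, "chr1", 5000, "+")
    pred = gm.predict_fusion(ctx)
    assert pred == gm.FusionPrediction(False)


def test_predict_fusion_anti_oriented_not_viable(toy_annotation_complete):
    ctx = gm.locate_insertion(toy_annotation_complete, "chr1", 1000, "-")
    assert not gm.predict_fusion(ctx).viable


def test_predict_fusion_requires_context():
    with pytest.raises(ValueError):
        gm.predict_fusion(None)


@pytest.mark.parametrize("intron_index, phase", [(1, 1), (2, 0), (3, 1)])
def test_predict_fusion_single_matching_variant(
    toy_annotation_complete, intron_index, phase
):
    """Exactly one C-padding variant restores frame for each intron phase."""
    t = toy_annotation_complete.genes["TOYG1"].transcripts[0]
    intron = t.intron_interval(intron_index)
    ctx = gm.locate_insertion(
        toy_annotation_complete, "chr1", intron.start + 2, "+"
    )
    pred = gm.predict_fusion(ctx)
    assert pred.viable
    assert pred.matching_variants == {matching_variant(phase)}
    assert pred.truncation_aa == t.upstream_cds_nt(intron_index) // 3


def test_predict_fusion_not_viable_downstream_of_stop(toy_annotation_complete):
    """An intron after the last coding exon cannot yield a reporter fusion.

    The complete toy gene's CDS (stop included) ends in exon 4; intron 4 lies
    entirely downstream of the stop codon, so translation terminates before
    the spliced-in reporter.
    """
    t = toy_annotation_complete.genes["TOYG1"].transcripts[0]
    intron4 = t.intron_interval(4)
    ctx = gm.locate_insertion(
        toy_annotation_complete, "chr1", intron4.start + 2, "+"
    )
    assert ctx.upstream_cds_nt == t.total_cds_nt
    assert not gm.predict_fusion(ctx).viable


def test_predict_fusion_strict_mode(toy_annotation_complete):
    ctx = gm.locate_insertion(toy_annotation_complete, "chr1", 1000, "+")
    needed = next(iter(gm.predict_fusion(ctx).matching_variants))
    assert gm.predict_fusion(ctx, variant=needed).viable
    assert not gm.predict_fusion(ctx, variant=(needed + 1) % 3).viable


def test_predict_fusion_deterministic(toy_annotation_complete):
    ctx = gm.locate_insertion(toy_annotation_complete, "chr1", 1000, "+")
    assert gm.predict_fusion(ctx) == gm.predict_fusion(ctx)


def test_truncation_non_decreasing_in_intron_index(default_annotation):
    for gene in default_annotation:
        t = gene.canonical_transcript()
        truncs = [
            t.upstream_cds_nt(i) // 3 for i in range(1, t.n_exons)
        ]
        assert truncs == sorted(truncs)
        assert all(x <= t.protein_length_aa for x in truncs)


def test_fusion_translation_matches_native_prefix(default_sim, default_genome,
                                                  default_annotation):
    """Construct every intron's fusion mRNA explicitly and translate it.

    For the matching variant, the fusion protein's first truncation_aa
    residues must equal the native protein's; for the two other variants the
    reporter must be out of frame (or hit a stop) — the construct only works
    in one frame.
    """
    checked = 0
    for gene in default_annotation:
        t = gene.canonical_transcript()
        native = translate(gm.extract_cds(default_genome, t))
        for i in range(1, t.n_exons):
            up = gm.upstream_cds_sequence(default_genome, t, i)
            if len(up) < 3:
                continue
            intron = t.intron_interval(i)
            ctx = gm.locate_insertion(
                default_annotation, intron.chrom,
                intron.start + len(intron) // 2, gene.strand,
            )
            pred = gm.predict_fusion(ctx)
            assert pred.viable and pred.intron_index == i
            (variant,) = pred.matching_variants
            fusion = translate(up + cassette_tail(variant))
            n = pred.truncation_aa
            assert fusion[:n] == native[:n]
            assert "*" not in fusion[:-1]  # reads through to the reporter stop
            checked += 1
    assert checked >= 50
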