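"""Master blocks, unique-length dedup, site calls and concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamtrap import genome_models as gm
from lamtrap import site_calling as sc
from lamtrap.readproc import FlankAlignment

from _oracles import overlap_closure


def aln(chrom, start, end, strand="+", read_id="r", arm="experimental",
        replicate="A"):
    return FlankAlignment(
        read_id, gm.GenomicInterval(chrom, start, end, strand), 0,
        arm=arm, replicate=replicate,
    )


# ---------------------------------------------------------------------------
# master blocks


def test_two_disjoint_alignments_two_blocks():
    blocks = sc.build_master_blocks(
        [aln("chr1", 100, 160), aln("chr1", 500, 560)]
    )
    assert len(blocks) == 2
    assert [b.block_id for b in blocks] == ["MB000001", "MB000002"]


def test_abutting_half_open_intervals_do_not_merge():
    blocks = sc.build_master_blocks(
        [aln("chr1", 100, 160), aln("chr1", 160, 200)]
    )
    assert len(blocks) == 2


def test_bridge_across_samples_merges_into_one_block():
    """Reads in A and B that overlap only via a long read in C still form a
    single cross-sample block."""
    a = aln("chr1", 100, 140, replicate="A")
    b = aln("chr1", 260, 300, replicate="B")
    c = aln("chr1", 120, 280, replicate="C")
    blocks = sc.build_master_blocks([a, b])
    assert len(blocks) == 2
    blocks = sc.build_master_blocks([a, b, c])
    assert len(blocks) == 1
    assert (blocks[0].interval.start, blocks[0].interval.end) == (100, 300)
    assert len(blocks[0].members) == 3


def _assert_blocks_match_closure(alignments):
    blocks = sc.build_master_blocks(alignments)
    idx = {id(a): i for i, a in enumerate(alignments)}
    got = {frozenset(idx[id(m)] for m in b.members) for b in blocks}
    expected = set(
        overlap_closure(
            [(a.interval.chrom, a.interval.start, a.interval.end)
             for a in alignments]
        )
    )
    assert got == expected
    # partition: every alignment in exactly one block
    assert sum(len(b.members) for b in blocks) == len(alignments)
    # bounding interval = union of members
    for b in blocks:
        assert b.interval.start == min(m.interval.start for m in b.members)
        assert b.interval.end == max(m.interval.end for m in b.members)


def test_blocks_equal_overlap_closure_on_random_intervals():
    rng = np.random.default_rng(13)
    alignments = [
        aln(
            f"chr{rng.integers(1, 4)}",
            int(s := rng.integers(0, 5000)),
            int(s + rng.integers(20, 400)),
            replicate="ABC"[rng.integers(0, 3)],
        )
        for _ in range(1000)
    ]
    _assert_blocks_match_closure(alignments)


@given(
    st.lists(
        st.tuples(st.integers(0, 300), st.integers(5, 60)),
        min_size=1, max_size=40,
    )
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_blocks_closure_property(pairs):
    alignments = [aln("chr1", s, s + l) for s, l in pairs]
    _assert_blocks_match_closure(alignments)


def test_block_ids_invariant_to_input_order():
    rng = np.random.default_rng(3)
    alignments = [
        aln("chr1", int(s := rng.integers(0, 3000)), int(s + 50))
        for _ in range(200)
    ]
    blocks1 = sc.build_master_blocks(alignments)
    shuffled = list(alignments)
    rng.shuffle(shuffled)
    blocks2 = sc.build_master_blocks(shuffled)
    key = lambda bs: [
        (b.block_id, b.interval.start, b.interval.end,
         sorted(id(m) for m in b.members))
        for b in bs
    ]
    assert key(blocks1) == key(blocks2)


# ---------------------------------------------------------------------------
# unique-length dedup


def test_dedup_counts_distinct_lengths():
    members = [
        aln("chr1", 100, 100 + L, read_id=f"r{i}")
        for i, L in enumerate([40, 40, 55, 70, 70])
    ]
    lengths = sc.dedup_unique_lengths(members)
    assert len(lengths[("experimental", "A")]) == 3


def test_dedup_all_same_length_is_one():
    members = [aln("chr1", 100, 140, read_id=f"r{i}") for i in range(7)]
    assert len(sc.dedup_unique_lengths(members)[("experimental", "A")]) == 1


def test_dedup_idempotent_under_exact_duplication():
    members = [aln("chr1", 100, 100 + L) for L in (30, 45, 60)]
    before = sc.dedup_unique_lengths(members)
    after = sc.dedup_unique_lengths(members + members + members)
    assert before == after


def test_dedup_counts_invariant_to_pcr_duplication_factor(tmp_path):
    """Raising duplication 1 -> 10 at error rate 0 changes no pooled count."""
    from lamtrap import config_for_sim_run, run_pipeline, simulate_run
    from conftest import small_config

    counts = {}
    for dup in (1.0, 10.0):
        sim = tmp_path / f"sim{dup}"
        simulate_run(
            small_config(seed=21, base_error_rate=0.0, pcr_duplication=dup),
            sim,
        )
        run = tmp_path / f"run{dup}"
        run_pipeline(config_for_sim_run(sim, run))
        df = pd.read_csv(run / "site_calls.tsv", sep="\t")
        counts[dup] = df.set_index(
            ["chrom", "junction_pos_1based", "arm"]
        )[["A", "B", "C", "unique_lengths_total"]].sort_index()
    pd.testing.assert_frame_equal(counts[1.0], counts[10.0])


# ---------------------------------------------------------------------------
# call_sites


def _site_alignments(junction, lengths_by_rep, chrom="chr1", strand="+",
                     arm="experimental"):
    out = []
    for rep, lengths in lengths_by_rep.items():
        for i, L in enumerate(lengths):
            if strand == "+":
                iv = (junction, junction + L)
            else:
                iv = (junction - L + 1, junction + 1)
            out.append(
                aln(chrom, iv[0], iv[1], strand=strand,
                    read_id=f"{rep}{i}", arm=arm, replicate=rep)
            )
    return out


def test_call_sites_on_clean_simulated_screen(clean_sim):
    """Every called junction equals a planted event coordinate, stacked."""
    from lamtrap import FlankMapper, read_genome, trim_fastq

    genome = read_genome(clean_sim / "genome.fa")
    mapper = FlankMapper(genome)
    alignments = []
    for fastq in sorted((clean_sim / "reads").glob("*.fastq")):
        arm, rep = fastq.stem.rsplit("_", 1)
        trimmed, _ = trim_fastq(fastq, arm=arm, replicate=rep)
        aligned, _ = mapper.map_all(trimmed)
        alignments.extend(aligned)
    calls = sc.call_sites(sc.build_master_blocks(alignments))
    events = pd.read_csv(clean_sim / "truth" / "events.tsv", sep="\t")
    planted = {(r["chrom"], int(r["pos"])) for _, r in events.iterrows()}
    for call in calls:
        assert (call.chrom, call.junction_pos) in planted
        assert call.stack_ok


def test_two_distant_junctions_fail_the_stack_test():
    members = _site_alignments(1000, {"A": [600, 580, 560]}) + \
        _site_alignments(1500, {"A": [600, 580, 550]})
    (block,) = sc.build_master_blocks(members)
    (call,) = sc.call_sites([block])
    assert not call.stack_ok


def test_minority_strand_reported_majority_kept():
    members = _site_alignments(1000, {"A": [40, 50, 60], "B": [45, 55]})
    members += _site_alignments(1030, {"C": [35]}, strand="-")
    (block,) = sc.build_master_blocks(members)
    (call,) = sc.call_sites([block])
    assert call.strand == "+"
    assert call.minority_strand_frac == pytest.approx(1 / 6)


def test_median_read_sample_is_middle_order_statistic():
    lengths = {
        "A": list(range(30, 80)),        # 50 unique lengths
        "B": list(range(30, 78)),        # 48
        "C": list(range(30, 83)),        # 53
    }
    (block,) = sc.build_master_blocks(_site_alignments(500, lengths))
    (call,) = sc.call_sites([block])
    assert call.counts == {"A": 50, "B": 48, "C": 53}
    assert call.median_read_sample == 50


def test_counts_never_pool_across_arms():
    members = _site_alignments(800, {"A": [40, 50, 60]})
    members += _site_alignments(800, {"A": [40, 45]}, arm="control")
    (block,) = sc.build_master_blocks(members)
    calls = sc.call_sites([block])
    by_arm = {c.arm: c for c in calls}
    assert by_arm["experimental"].unique_lengths_total == 3
    assert by_arm["control"].unique_lengths_total == 2


# ---------------------------------------------------------------------------
# replicate concordance


def _calls_from_counts(count_rows):
    calls = []
    for i, (a, b, c) in enumerate(count_rows):
        calls.append(
            sc.SiteCall(
                block_id=f"MB{i}", arm="experimental", chrom="chr1",
                junction_pos=i * 1000, strand="+",
                counts={"A": a, "B": b, "C": c},
                unique_lengths_total=max(a, b, c),
                median_read_sample=float(sorted((a, b, c))[1]),
                stack_ok=True,
            )
        )
    return calls


def test_concordance_identical_vectors():
    calls = _calls_from_counts([(1, 1, 1), (5, 5, 5), (9, 9, 9), (2, 2, 2)])
    assert sc.replicate_concordance(calls) == {
        "A-B": 1.0, "A-C": 1.0, "B-C": 1.0,
    }


def test_concordance_is_rank_invariant():
    # monotone but non-linear: (1,2,3,4) vs (2,4,6,9)
    calls = _calls_from_counts([(1, 2, 1), (2, 4, 2), (3, 6, 3), (4, 9, 4)])
    assert sc.replicate_concordance(calls)["A-B"] == 1.0


def test_concordance_definitional_value():
    # vectors (3,1,2) and (2,3,1) over three sites: rho = -0.5
    calls = _calls_from_counts([(3, 2, 0), (1, 3, 0), (2, 1, 0)])
    assert sc.replicate_concordance(calls)["A-B"] == pytest.approx(-0.5)


def test_concordance_undefined_below_three_sites():
    calls = _calls_from_counts([(1, 2, 3), (4, 5, 6)])
    assert sc.replicate_concordance(calls) == {
        "A-B": None, "A-C": None, "B-C": None,
    }
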