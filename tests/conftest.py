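"""Shared fixtures: simulated screens at several scales.

The "small" screen keeps per-test cost low; the default-condition screen is
session-scoped and reused wherever the study conditions themselves matter.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pytest

from lamtrap import (
    SimConfig,
    config_for_sim_run,
    read_annotation,
    read_genome,
    run_pipeline,
    simulate_run,
)

SMALL = dict(
    chromosome_lengths=(60_000, 30_000),
    n_genes=12,
    n_true=8,
    n_anti=2,
    n_intergenic=2,
    n_control_shared=3,
    molecules_per_site=(3, 20),
)


def small_config(seed: int = 5, **overrides) -> SimConfig:
    kwargs = {**SMALL, **overrides}
    return SimConfig(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("small_sim")
    simulate_run(small_config(), out)
    return out


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory) -> Path:
    """Small screen without base errors or PCR duplication."""
    out = tmp_path_factory.mktemp("clean_sim")
    simulate_run(
        small_config(seed=7, base_error_rate=0.0, pcr_duplication=1.0), out
    )
    return out


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory) -> Path:
    """One screen at the default study conditions."""
    out = tmp_path_factory.mktemp("default_sim")
    simulate_run(SimConfig(seed=11), out)
    return out


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("default_run")
    cfg = config_for_sim_run(default_sim, out)
    result = run_pipeline(cfg)
    return out, result


@pytest.fixture(scope="session")
def default_genome(default_sim):
    return read_genome(default_sim / "genome.fa")


@pytest.fixture(scope="session")
def default_annotation(default_sim):
    return read_annotation(default_sim / "annotation.gtf")


@pytest.fixture(scope="session")
def default_manifest(default_sim):
    with open(default_sim / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def default_events(default_sim) -> pd.DataFrame:
    df = pd.read_csv(default_sim / "truth" / "events.tsv", sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df


TOY_GTF = """\
chr1\ttoy\tgene\t101\t2000\t.\t+\t.\tgene_id "TOYG1"; gene_name "toy1";
chr1\ttoy\ttranscript\t101\t2000\t.\t+\t.\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
chr1\ttoy\texon\t101\t250\t.\t+\t.\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
chr1\ttoy\tCDS\t151\t250\t.\t+\t0\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
chr1\ttoy\texon\t501\t547\t.\t+\t.\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
chr1\ttoy\tCDS\t501\t547\t.\t+\t2\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
chr1\ttoy\texon\t801\t900\t.\t+\t.\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
chr1\ttoy\tCDS\t801\t900\t.\t+\t0\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
chr1\ttoy\texon\t1201\t1300\t.\t+\t.\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
chr1\ttoy\tCDS\t1201\t1276\t.\t+\t2\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
chr1\ttoy\texon\t1601\t2000\t.\t+\t.\tgene_id "TOYG1"; transcript_id "TOYT1"; gene_name "toy1";
"""
# Toy gene: 5 exons on +, CDS lengths 100, 47, 100, 76 nt (total 323+1 -> pad
# below); upstream CDS at introns 1..4 = 100, 147, 247, 323.


@pytest.fixture()
def toy_annotation(tmp_path):
    """5-exon plus-strand toy gene; CDS per exon: 100, 47, 100, 76 nt.

    The CDS total (323) is deliberately NOT a multiple of 3, so this
    transcript is flagged incomplete — tests that need a complete CDS use
    `toy_annotation_complete`.
    """
    p = tmp_path / "toy.gtf"
    p.write_text(TOY_GTF)
    return read_annotation(p)


@pytest.fixture()
def toy_annotation_complete(tmp_path):
    """Same toy gene with the last CDS extended to 77 nt (total 324 = 108 codons)."""
    p = tmp_path / "toy_complete.gtf"
    p.write_text(TOY_GTF.replace("\tCDS\t1201\t1276\t", "\tCDS\t1201\t1277\t"))
    return read_annotation(p)
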