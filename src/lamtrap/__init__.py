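"""lamtrap: insertion-site deconvolution for gene-trap transposon screens.

The pipeline turns nrLAM-PCR junction reads into a filtered, frame-annotated
table of trapped genes: tag trimming, flank mapping, cross-sample master
blocks, unique-fragment-length PCR deduplication, the screen's filter ledger
(read count, orientation/stack, negative-control subtraction, genic fusion
viability) and per-gene aggregation with confidence tiers.  A synthetic-data
generator emulates the screen's read structure so every stage is verifiable
against ground truth.
"""

from importlib import resources

from .cassette import TOL2_TAG, cassette_tail, matching_variant
from .genome_models import (
    Annotation,
    FusionPrediction,
    GeneModel,
    GenomicInterval,
    InsertionContext,
    Transcript,
    intron_phase,
    locate_insertion,
    predict_fusion,
    read_annotation,
    read_genome,
    revcomp,
)
from .hit_filtering import (
    FilterLedger,
    aggregate_hits,
    apply_filters,
    annotate_sites,
    export_hit_table,
    load_hit_records,
    sites_to_records,
)
from .pipeline import (
    PipelineConfig,
    config_for_sim_run,
    evaluate_run,
    run_pipeline,
)
from .readproc import (
    FlankAlignment,
    FlankMapper,
    TrimmedRead,
    import_alignments,
    trim_fastq,
    trim_tag,
)
from .sim import InsertionEvent, SimConfig, simulate_run
from .site_calling import (
    MasterBlock,
    SiteCall,
    build_master_blocks,
    call_sites,
    dedup_unique_lengths,
    replicate_concordance,
)

__version__ = "0.1.0"


def screen_hit_table_path():
    """Path to the packaged PARylation-screen hit table (worked example)."""
    return resources.files("lamtrap.data") / "parylation_screen_hits.tsv"
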