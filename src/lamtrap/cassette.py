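"""Gene-trap cassette geometry.

The trap transposon carries a promoterless splice-acceptor (SA) cassette: after
integration into an intron of an actively transcribed gene (co-oriented with
transcription), splicing joins the host's upstream exons directly onto the
cassette.  The reporter open reading frame (an HA tag followed by the VC half of
split Venus) begins 15 nt downstream of the SA and carries no ATG of its own, so
translation runs in from the host CDS.  Three vector variants pad the junction
with 0, 1 or 2 C bases so that, between them, every intron phase can be captured
in frame.
"""

from __future__ import annotations

#: Transposon-end sequence that prefixes every nrLAM-PCR junction read.
TOL2_TAG = "TTTGAGTACTTTTTACACCTCTG"

#: Spacer between the splice acceptor and the reporter frame (15 nt, a multiple
#: of 3, free of ATG so the cassette cannot initiate translation on its own).
SA_SPACER = "GGATCCGGTGGATCT"

#: HA epitope tag, YPYDVPDYA.
HA_TAG_NT = "TACCCATACGATGTTCCAGATTACGCT"

#: Stand-in reporter ORF used when a fusion transcript is built explicitly
#: (tests translate through it to verify frame).  Stop-free, then TAA.
REPORTER_NT = "GTGAGCAAGGGCGAGGAGCTGTTCACCGGGGTGGTGCCCATCCTGGTCGAG" + "TAA"


def matching_variant(phase: int) -> int:
    """C-padding variant (0, 1 or 2) that restores frame for an intron phase.

    ``phase`` is the count of coding nucleotides upstream of the intron mod 3.
    The spacer length is a multiple of 3, so the reporter is in frame exactly
    when ``phase + padding`` completes the split codon: padding = (3 - phase) % 3.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"intron phase must be 0, 1 or 2, got {phase!r}")
    return (3 - phase) % 3


def cassette_tail(variant: int) -> str:
    """Nucleotides spliced after the upstream host CDS for a given variant."""
    if variant not in (0, 1, 2):
        raise ValueError(f"variant must be 0, 1 or 2, got {variant!r}")
    return "C" * variant + SA_SPACER + HA_TAG_NT + REPORTER_NT
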