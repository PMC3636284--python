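"""Shared category vocabulary for genic annotation."""

#: The eight genic annotation categories, in genomic order along the
#: transcription direction: distal/proximal upstream flanks, the four
#: transcript elements, then proximal/distal downstream flanks.
CATEGORIES = (
    "10k_up",
    "1k_up",
    "utr5",
    "exon",
    "intron",
    "utr3",
    "1k_down",
    "10k_down",
)

#: Transcript-internal element categories (the ones carried by gene models).
GENIC_ELEMENTS = ("utr5", "exon", "intron", "utr3")

#: Default resolution order when a position is covered by elements of more
#: than one gene: rarer, more specific elements win.
DEFAULT_PRECEDENCE = (
    "utr5",
    "utr3",
    "exon",
    "intron",
    "1k_up",
    "1k_down",
    "10k_up",
    "10k_down",
)

SCORE_COLUMNS = tuple(f"score_{c}" for c in CATEGORIES)
MEMBER_COLUMNS = tuple(f"member_{c}" for c in CATEGORIES)

#: Conventional genome-wide significance threshold (display cap only).
GENOME_WIDE_SIG = 5e-8
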