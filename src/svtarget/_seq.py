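"""Nucleotide alphabet helpers.

Convention: annotation/FASTA files on disk use DNA letters (ACGT); guide
sequences and everything inside the duplex aligner use RNA letters (ACGU).
Conversion is explicit at module boundaries via :func:`to_rna` / :func:`to_dna`.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Watson-Crick pairs (RNA letters).
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
#: G:U wobble pairs.
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def pair_type(guide_base: str, target_base: str) -> str | None:
    """Classify an opposed base pair: 'WC', 'wobble', or None (mismatch)."""
    duo = (guide_base, target_base)
    if duo in WC_PAIRS:
        return "WC"
    if duo in WOBBLE_PAIRS:
        return "wobble"
    return None


def anti_pair_bases(guide_base: str) -> str:
    """RNA bases that neither WC- nor wobble-pair with ``guide_base``."""
    return "".join(
        b for b in "ACGU"
        if (guide_base, b) not in WC_PAIRS and (guide_base, b) not in WOBBLE_PAIRS
    )
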