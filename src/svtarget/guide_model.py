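"""Guide RNA sequences and control constructions.

A guide is a short RNA (5'->3'); positions are 1-based from the 5' end in all
reports. Controls used to probe pairing requirements are built here: region
shuffles that preserve the base-composition multiset, and 5'/3' block swaps.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import ConfigurationError, CoordinateError, EmptyInputError, ParseError
from ._seq import RNA_ALPHABET, to_rna

#: Full-length vault RNA1-2 (89 nt) and the 3'-terminal 24-mer fragment guide
#: derived from it. The 24-mer is the default guide for scans; exact endpoints
#: of the endogenous fragment are configuration, not ground truth.
VTRNA1_2 = (
    "GGGCUGGCUUUAGCUCAGCGGUUACUUCGAGUACAUUGUAACCACCUCUCUGGGUGGUUCGAGACCCGCGGGUGCUUUCCAGCUCUUUU"
)
DEFAULT_FRAGMENT_LENGTH = 24

#: Default control regions (1-based closed): 5' shuffle over the seed 2-8,
#: 3' shuffle over 12-18, mirroring the transfected construct design.
DEFAULT_SHUFFLE_5P = (2, 8)
DEFAULT_SHUFFLE_3P = (12, 18)


@dataclass(frozen=True)
class GuideRNA:
    """A small guide RNA sequence.

    Attributes
    ----------
    id : str
        Record identifier.
    sequence : str
        RNA string, 5'->3', alphabet {A,C,G,U}.
    origin : tuple | None
        Optional ``(parent_id, (start, end))`` with a 0-based half-open
        interval on the parent sequence.
    """

    id: str
    sequence: str
    origin: tuple[str, tuple[int, int]] | None = field(default=None)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ParseError(
                f"guide {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def load_guides(fasta_path: str | Path) -> list[GuideRNA]:
    """Read guides from FASTA. T is transliterated to U; IDs are preserved.

    Raises
    ------
    EmptyInputError
        If the file contains no records.
    ParseError
        If a record contains characters outside {A,C,G,U,T} (case-insensitive).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {fasta_path}")
    guides = []
    for rec in records:
        seq = to_rna(str(rec.seq))
        guides.append(GuideRNA(id=rec.id, sequence=seq))
    return guides


def default_guide() -> GuideRNA:
    """The 3'-terminal 24-nt fragment of vault RNA1-2."""
    n = len(VTRNA1_2)
    return GuideRNA(
        id="svtRNA1-2",
        sequence=VTRNA1_2[-DEFAULT_FRAGMENT_LENGTH:],
        origin=("vtRNA1-2", (n - DEFAULT_FRAGMENT_LENGTH, n)),
    )


def extract_fragment_guide(parent: GuideRNA, interval: tuple[int, int],
                           guide_id: str | None = None) -> GuideRNA:
    """Slice a fragment guide out of a parent sequence.

    ``interval`` is 0-based half-open on the parent (e.g. the interval of a
    coverage-based fragment call).
    """
    start, end = interval
    if not (0 <= start < end <= len(parent)):
        raise CoordinateError(
            f"interval [{start}, {end}) outside parent {parent.id!r} "
            f"of length {len(parent)}"
        )
    return GuideRNA(
        id=guide_id or f"{parent.id}:{start}-{end}",
        sequence=parent.sequence[start:end],
        origin=(parent.id, (start, end)),
    )


def shuffle_region(guide: GuideRNA, region: tuple[int, int], seed: int,
                   suffix: str = "shuffled") -> GuideRNA:
    """Permute bases inside a 1-based closed region with a seeded PRNG.

    Bases outside the region are untouched, so the whole-guide base
    composition multiset is unchanged by construction.
    """
    lo, hi = region
    if hi < lo:
        raise ConfigurationError(f"region: [{lo}, {hi}] is empty")
    if not (1 <= lo <= hi <= len(guide)):
        raise ConfigurationError(
            f"region: [{lo}, {hi}] outside guide of length {len(guide)}"
        )
    rng = np.random.default_rng(seed)
    chars = list(guide.sequence)
    block = chars[lo - 1:hi]
    perm = rng.permutation(len(block))
    chars[lo - 1:hi] = [block[i] for i in perm]
    return GuideRNA(id=f"{guide.id}_{suffix}", sequence="".join(chars))


def swap_ends(guide: GuideRNA, block5: tuple[int, int], block3: tuple[int, int],
              suffix: str = "swapped") -> GuideRNA:
    """Exchange two equal-length, non-overlapping 1-based closed blocks.

    ``block5`` must precede ``block3``; everything outside the blocks is
    unchanged, so length and composition are preserved.
    """
    a_lo, a_hi = block5
    b_lo, b_hi = block3
    if (a_hi - a_lo) != (b_hi - b_lo):
        raise ConfigurationError("block5/block3: blocks must have equal length")
    if not (1 <= a_lo <= a_hi < b_lo <= b_hi <= len(guide)):
        raise ConfigurationError(
            "block5/block3: blocks must be in order, non-overlapping and "
            "within the guide"
        )
    chars = list(guide.sequence)
    a = chars[a_lo - 1:a_hi]
    b = chars[b_lo - 1:b_hi]
    chars[a_lo - 1:a_hi] = b
    chars[b_lo - 1:b_hi] = a
    return GuideRNA(id=f"{guide.id}_{suffix}", sequence="".join(chars))


def base_composition(guide: GuideRNA) -> dict[str, float]:
    """Per-base fractions over {A, C, G, U}; fractions sum to 1."""
    if len(guide) == 0:
        raise EmptyInputError("empty guide")
    counts = collections.Counter(guide.sequence)
    n = len(guide)
    return {b: counts.get(b, 0) / n for b in "ACGU"}


def make_controls(guide: GuideRNA, seed: int = 0,
                  region5: tuple[int, int] = DEFAULT_SHUFFLE_5P,
                  region3: tuple[int, int] = DEFAULT_SHUFFLE_3P) -> dict[str, GuideRNA]:
    """Standard control set: 5' shuffle, 3' shuffle, and a 5'/3' block swap."""
    return {
        "shuffle5": shuffle_region(guide, region5, seed, suffix="shuffled_5p"),
        "shuffle3": shuffle_region(guide, region3, seed + 1, suffix="shuffled_3p"),
        "swap": swap_ends(guide, region5, region3, suffix="swapped"),
    }
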