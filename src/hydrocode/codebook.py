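"""Standard genetic code, base complementation and complementary amino-acid pairs.

A sense codon read on one nucleic-acid strand has a complementary codon on the
other strand.  Depending on how the complementary strand is read, the antisense
codon is either the base-wise complement in the same order (parallel, 3'->5')
or the reverse complement (antiparallel, 5'->3').  Either way the *second*
codon position pairs Watson-Crick with the sense second position, so the Davis
polarity class of the antisense amino acid is forced by the sense class:
polar (2nd A) pairs with nonpolar (2nd U), and neutral (2nd C/G) pairs with
neutral.  This module enumerates those sense/antisense amino-acid pairs.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "STOP",
    "BASES",
    "CODONS",
    "STOP_CODONS",
    "AMINO_ACIDS",
    "DAVIS_SCORES",
    "Direction",
    "PolarityClass",
    "ComplementaryPair",
    "complement_base",
    "transcribe",
    "antisense_codon",
    "translate",
    "polarity_class",
    "enumerate_pairs",
    "pairs_to_frame",
]

#: Sentinel returned by :func:`translate` for the three stop codons.  It is a
#: punctuation character, never confusable with a one-letter amino-acid code.
STOP = "*"

BASES = ("A", "C", "G", "U")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

_TABLE = CodonTable.unambiguous_rna_by_id[1]  # the standard code
_FORWARD = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODONS = tuple("".join(b) for b in itertools.product(BASES, repeat=3))
AMINO_ACIDS = tuple(sorted(set(_FORWARD.values())))


class Direction(str, enum.Enum):
    """Reading direction of the complementary strand relative to the sense codon."""

    PARALLEL_3TO5 = "parallel_3to5"
    ANTIPARALLEL_5TO3 = "antiparallel_5to3"


class Dedup(str, enum.Enum):
    """Granularity of pair enumeration: every codon pair, or unique amino-acid pairs."""

    PER_CODON = "per_codon"
    PER_AA_PAIR = "per_aa_pair"


def complement_base(base: str) -> str:
    """Watson-Crick partner of an RNA base (A<->U, C<->G)."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"invalid RNA base {base!r}; expected one of A, C, G, U") from None


def transcribe(seq: str) -> str:
    """Normalize a nucleotide string to the RNA alphabet (T -> U, uppercase)."""
    return seq.upper().replace("T", "U")


def _check_codon(codon: str) -> str:
    codon = transcribe(codon)
    if len(codon) != 3 or any(b not in _COMPLEMENT for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return codon


def antisense_codon(codon: str, direction: Direction) -> str:
    """Complementary codon of ``codon`` under the given reading direction.

    Parallel (3'->5') reading keeps base order and complements each base;
    antiparallel (5'->3') reading is the reverse complement.
    """
    codon = _check_codon(codon)
    comp = "".join(_COMPLEMENT[b] for b in codon)
    if Direction(direction) is Direction.PARALLEL_3TO5:
        return comp
    return comp[::-1]


def translate(codon: str) -> str:
    """Standard-code translation; returns :data:`STOP` for the three stop codons."""
    codon = _check_codon(codon)
    if codon in STOP_CODONS:
        return STOP
    return _FORWARD[codon]


@dataclass(frozen=True)
class PolarityClass:
    """Davis polarity class of an amino acid, read off the 2nd base of its codons.

    2nd U -> nonpolar (+1), 2nd A -> polar (-1), 2nd C or G -> neutral (0).
    """

    label: str
    davis_score: int


_SCORE_BY_BASE = {"U": 1, "A": -1, "C": 0, "G": 0}
_LABEL_BY_SCORE = {1: "nonpolar", -1: "polar", 0: "neutral"}


def _build_polarity() -> dict[str, PolarityClass]:
    scores: dict[str, set[int]] = {}
    for codon, aa in _FORWARD.items():
        scores.setdefault(aa, set()).add(_SCORE_BY_BASE[codon[1]])
    out = {}
    for aa, ss in scores.items():
        if len(ss) != 1:  # cannot happen for the standard code; guards a bad table
            raise RuntimeError(f"codons of {aa} disagree on 2nd-base polarity class: {ss}")
        (s,) = ss
        out[aa] = PolarityClass(_LABEL_BY_SCORE[s], s)
    return out


_POLARITY = _build_polarity()

#: Davis 2nd-codon-base polarity score for each amino acid (+1/-1/0).
DAVIS_SCORES = {aa: pc.davis_score for aa, pc in _POLARITY.items()}


def polarity_class(aa: str) -> PolarityClass:
    """Polarity class (nonpolar/polar/neutral and Davis score) of an amino acid."""
    try:
        return _POLARITY[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


_GROUP_BY_BASE = {
    "A": "polar-nonpolar",
    "U": "polar-nonpolar",
    "C": "neutral-neutral",
    "G": "neutral-neutral",
}


@dataclass(frozen=True)
class ComplementaryPair:
    """A sense codon and its antisense partner, with the translated amino acids.

    ``group`` is determined solely by the 2nd base of the sense codon:
    A or U -> polar-nonpolar, C or G -> neutral-neutral.
    """

    sense_codon: str
    sense_aa: str
    antisense_codon: str
    antisense_aa: str
    direction: Direction
    group: str


def enumerate_pairs(
    direction: Direction,
    dedup: Dedup | str = Dedup.PER_AA_PAIR,
) -> list[ComplementaryPair]:
    """All complementary sense/antisense pairs under the standard code.

    Iterates the 64 sense codons; pairs in which either strand encodes a stop
    are excluded (no amino-acid value exists for a stop).  With
    ``dedup='per_aa_pair'`` duplicate (sense_aa, antisense_aa) combinations are
    collapsed, keeping the first codon encountered in codon order.
    """
    direction = Direction(direction)
    dedup = Dedup(dedup)
    pairs: list[ComplementaryPair] = []
    seen: set[tuple[str, str]] = set()
    for codon in CODONS:
        if codon in STOP_CODONS:
            continue
        anti = antisense_codon(codon, direction)
        if anti in STOP_CODONS:
            continue
        sense_aa = _FORWARD[codon]
        anti_aa = _FORWARD[anti]
        if dedup is Dedup.PER_AA_PAIR:
            key = (sense_aa, anti_aa)
            if key in seen:
                continue
            seen.add(key)
        pairs.append(
            ComplementaryPair(
                sense_codon=codon,
                sense_aa=sense_aa,
                antisense_codon=anti,
                antisense_aa=anti_aa,
                direction=direction,
                group=_GROUP_BY_BASE[codon[1]],
            )
        )
    return pairs


def pairs_to_frame(pairs: list[ComplementaryPair]) -> pd.DataFrame:
    """Pair table with the documented export columns."""
    return pd.DataFrame(
        {
            "sense_codon": [p.sense_codon for p in pairs],
            "sense_aa": [p.sense_aa for p in pairs],
            "antisense_codon": [p.antisense_codon for p in pairs],
            "antisense_aa": [p.antisense_aa for p in pairs],
            "direction": [p.direction.value for p in pairs],
            "group": [p.group for p in pairs],
        }
    )
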