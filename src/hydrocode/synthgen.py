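"""Synthetic binary-patterned alpha/beta protein designs and statistical fixtures.

De novo "binary code" proteins are specified only by the arrangement of polar
and nonpolar residues: a nonpolar period near 3.6 residues/cycle puts all
hydrophobics on one helix face (alpha bundles), strict alternation matches the
2-residue repeat of a beta strand.  The generator emulates that design logic —
segments of patterned residues joined by short turns — with the residue
identities drawn from the 2nd-codon-base alphabets, so every downstream stage
(series conversion, periodograms, fold calls) can be exercised with known
ground truth.  It emulates the patterning only; real designs add specific
core packing and termini the generator does not model.

Default geometry: alpha = 4 helical segments of 14 residues (period 3.6),
beta = 6 strands of 6 residues (alternation), 3-residue turns; overall lengths
(65 and 51 residues) are in the range of the classic designed sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NONPOLAR_ALPHABET",
    "POLAR_ALPHABET",
    "TURN_ALPHABET",
    "PatternSpec",
    "ALPHA_DEFAULT",
    "BETA_DEFAULT",
    "make_binary_pattern",
    "realize_sequence",
    "make_dataset",
    "make_correlated_pairs",
    "write_fasta",
]

#: Residue alphabets by 2nd-codon-base polarity class.
NONPOLAR_ALPHABET = "FLIMV"
POLAR_ALPHABET = "YHQNKDE"
TURN_ALPHABET = "GSP"


@dataclass(frozen=True)
class PatternSpec:
    """Geometry of a binary polar/nonpolar design."""

    class_label: str  # "alpha" or "beta"
    period: float  # residues per nonpolar cycle (alpha ~3.6, beta 2.0)
    segment_length: int
    n_segments: int
    turn_length: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in ("alpha", "beta"):
            raise ValueError("class_label must be 'alpha' or 'beta'")
        if self.period <= 1:
            raise ValueError("period must exceed 1 residue/cycle")
        if self.total_length < 16:
            raise ValueError("total length must be >= 16 residues")

    @property
    def total_length(self) -> int:
        return self.n_segments * self.segment_length + (self.n_segments - 1) * self.turn_length


ALPHA_DEFAULT = PatternSpec(class_label="alpha", period=3.6, segment_length=14, n_segments=4)
BETA_DEFAULT = PatternSpec(class_label="beta", period=2.0, segment_length=6, n_segments=6)


def make_binary_pattern(spec: PatternSpec) -> str:
    """Polar/nonpolar template string over {'N','P','T'} (T = turn positions).

    Within each segment, position i (0-based) is nonpolar when the fractional
    phase i/period falls in the first half cycle — for period 2 this is strict
    NP alternation, for period 3.6 the canonical one-helix-face pattern.  The
    template is deterministic (no randomness enters until realization).
    """
    segment = "".join(
        "N" if (i / spec.period) % 1.0 < 0.5 else "P" for i in range(spec.segment_length)
    )
    turn = "T" * spec.turn_length
    return turn.join([segment] * spec.n_segments)


def realize_sequence(template: str, seed: int) -> str:
    """Draw residues for a template: N from {FLIMV}, P from {YHQNKDE}, T from {GSP}."""
    rng = np.random.default_rng(seed)
    alphabet = {"N": NONPOLAR_ALPHABET, "P": POLAR_ALPHABET, "T": TURN_ALPHABET}
    out = []
    for ch in template:
        if ch not in alphabet:
            raise ValueError(f"unknown template symbol {ch!r}")
        letters = alphabet[ch]
        out.append(letters[rng.integers(len(letters))])
    return "".join(out)


def make_dataset(
    n_alpha: int,
    n_beta: int,
    seed: int = 0,
    alpha_spec: PatternSpec = ALPHA_DEFAULT,
    beta_spec: PatternSpec = BETA_DEFAULT,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Labeled synthetic designs: FASTA-ready records plus a truth table.

    Record ids encode the class and per-sequence seed; the truth table carries
    id, class, seed and period.  Sequence i of each class is realized with
    seed ``seed*100000 + index`` so datasets with different master seeds do
    not share sequences.
    """
    if n_alpha < 1 or n_beta < 1:
        raise ValueError("need at least one sequence per class")
    records = []
    rows = []
    counter = 0
    for spec, n in ((alpha_spec, n_alpha), (beta_spec, n_beta)):
        template = make_binary_pattern(spec)
        for i in range(n):
            sub_seed = seed * 100000 + counter
            counter += 1
            seq = realize_sequence(template, sub_seed)
            rid = f"{spec.class_label}_{i + 1:03d}_seed{sub_seed}"
            records.append((rid, seq))
            rows.append((rid, spec.class_label, sub_seed, spec.period))
    truth = pd.DataFrame(rows, columns=["id", "class", "seed", "period"])
    return records, truth


def make_correlated_pairs(n: int, rho: float, seed: int = 0) -> np.ndarray:
    """Bivariate-normal (x, y) draws with population correlation ``rho``.

    Fixture for testing correlation estimators: returns an (n, 2) array.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    if abs(rho) == 1.0:  # degenerate covariance: exactly colinear draws
        x = rng.standard_normal(n)
        return np.column_stack([x, rho * x])
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Plain single-line FASTA output."""
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
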