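"""Amino-acid property scales and conversion of sequences to numerical series.

Registered scales
-----------------
``logkwc_25``
    log10 equilibrium constant for transfer of the side chain from neutral
    aqueous solution to cyclohexane at 25 C (hydrophobicity; dimensionless).
``logkwc_100``
    Synthetic stand-in for the same quantity at 100 C, constructed from the
    25 C values by attenuating the hydrophilic end (see the packaged metadata);
    shipped because the measured 100 C table is not redistributable here.
``mean_buried_area``
    Mean area (A^2) buried on folding, per residue.
``davis``
    Integer polarity score from the 2nd codon base (+1 nonpolar, -1 polar,
    0 neutral); derived from the genetic code, not from a data file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .codebook import AMINO_ACIDS, DAVIS_SCORES

__all__ = [
    "Scale",
    "NumericSeries",
    "available_scales",
    "get_scale",
    "standardize",
    "sequence_to_series",
    "recover_scale_from_series",
    "read_fasta",
    "series_to_frame",
]


@dataclass(frozen=True)
class Scale:
    """A 20-entry map from one-letter amino-acid codes to a real property value."""

    name: str
    values: dict[str, float]
    temperature_C: float | None = None
    units: str | None = None
    synthetic: bool = False

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard amino acids "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} contains non-finite values")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def vector(self, order: Sequence[str] = AMINO_ACIDS) -> np.ndarray:
        return np.array([self.values[a] for a in order], dtype=float)


def _load_csv_scale(fname: str) -> dict[str, float]:
    with resources.files("hydrocode.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["aa"], df["value"].astype(float)))


def _load_meta() -> dict:
    with resources.files("hydrocode.data").joinpath("scales_meta.json").open() as fh:
        return json.load(fh)


def _build_registry() -> dict[str, Scale]:
    meta = _load_meta()
    reg = {}
    for name, fname in [
        ("logkwc_25", "logkwc_25.csv"),
        ("logkwc_100", "logkwc_100_synthetic.csv"),
        ("mean_buried_area", "mean_buried_area.csv"),
    ]:
        m = meta[name]
        reg[name] = Scale(
            name=name,
            values=_load_csv_scale(fname),
            temperature_C=m["temperature_C"],
            units=m["units"],
            synthetic=m["synthetic"],
        )
    reg["davis"] = Scale(
        name="davis",
        values={aa: float(s) for aa, s in DAVIS_SCORES.items()},
        units="score",
    )
    return reg


_REGISTRY = _build_registry()


def available_scales() -> list[str]:
    return sorted(_REGISTRY)


def get_scale(name: str) -> Scale:
    """Look up a registered scale by name (see module docstring for the list)."""
    key = name.lower()
    if key not in _REGISTRY:
        raise KeyError(f"unknown scale {name!r}; available: {', '.join(available_scales())}")
    return _REGISTRY[key]


def logkwc_scale(temperature: int | float) -> Scale:
    """The hydrophobicity scale for a temperature of 25 or 100 C."""
    t = int(temperature)
    if t not in (25, 100):
        raise ValueError("hydrophobicity scales are tabulated at 25 C and 100 C only")
    return get_scale(f"logkwc_{t}")


def standardize(values: Iterable[float], method: Literal["kr_mad", "zscore"] = "kr_mad") -> np.ndarray:
    """Center and rescale a variable.

    ``kr_mad`` subtracts the mean and divides by the mean absolute deviation
    (the Kaufman-Rousseeuw convention used by the classic clustering suites);
    ``zscore`` divides by the standard deviation instead.
    """
    v = np.asarray(list(values), dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values cannot be standardized")
    centered = v - v.mean()
    if method == "kr_mad":
        denom = np.abs(centered).mean()
    elif method == "zscore":
        denom = v.std()
    else:
        raise ValueError(f"unknown standardization method {method!r}")
    if denom <= 0:
        raise ValueError("degenerate variable: zero spread")
    return centered / denom


@dataclass
class NumericSeries:
    """A protein sequence rendered as a positional series of scale values."""

    protein_id: str
    residues: str
    values: np.ndarray
    class_label: str | None = None
    scale_name: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.residues) or len(self.residues) < 1:
            raise ValueError("series must have one value per residue and length >= 1")

    def __len__(self) -> int:
        return len(self.values)


def sequence_to_series(
    seq: str,
    scale: Scale,
    protein_id: str = "",
    class_label: str | None = None,
    on_unknown: Literal["raise", "skip"] = "raise",
) -> NumericSeries:
    """Assign the scale value to each residue, preserving positional order.

    Residues outside the 20-letter alphabet (X, B, Z, ...) either abort
    (default) or are dropped with a warning when ``on_unknown='skip'``.
    """
    seq = seq.upper()
    kept = []
    values = []
    for pos, aa in enumerate(seq, start=1):
        if aa not in scale.values:
            if on_unknown == "raise":
                raise ValueError(
                    f"residue {aa!r} at position {pos} of {protein_id or 'sequence'} "
                    f"is not covered by scale {scale.name!r}"
                )
            warnings.warn(f"skipping unknown residue {aa!r} at position {pos}", stacklevel=2)
            continue
        kept.append(aa)
        values.append(scale.values[aa])
    return NumericSeries(
        protein_id=protein_id,
        residues="".join(kept),
        values=np.array(values),
        class_label=class_label,
        scale_name=scale.name,
    )


def recover_scale_from_series(
    series: Iterable[NumericSeries],
    name: str = "recovered",
    **scale_kwargs,
) -> Scale:
    """Invert :func:`sequence_to_series`: read the per-residue value back off.

    Every amino acid must carry a single consistent value across all series;
    a conflict raises, and missing amino acids are reported in the error.
    """
    values: dict[str, float] = {}
    for s in series:
        for aa, v in zip(s.residues, s.values):
            if aa in values and not np.isclose(values[aa], v, rtol=0, atol=1e-9):
                raise ValueError(
                    f"inconsistent values for {aa!r}: {values[aa]} vs {v} (series {s.protein_id!r})"
                )
            values.setdefault(aa, float(v))
    missing = set(AMINO_ACIDS) - set(values)
    if missing:
        raise ValueError(f"series do not cover amino acids: {sorted(missing)}")
    return Scale(name=name, values=values, **scale_kwargs)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file, uppercased."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def series_to_frame(series: Iterable[NumericSeries]) -> pd.DataFrame:
    """Long-format table: protein_id, class, position, residue, value."""
    rows = []
    for s in series:
        for pos, (aa, v) in enumerate(zip(s.residues, s.values), start=1):
            rows.append((s.protein_id, s.class_label, pos, aa, v))
    return pd.DataFrame(rows, columns=["protein_id", "class", "position", "residue", "value"])
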