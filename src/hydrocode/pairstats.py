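"""Correlation statistics over complementary amino-acid pairs.

For each sense/antisense pair one member is designated the *ligand* (the one
whose own codon carries a purine, or a pyrimidine, at the 2nd position) and
the other the *receptor*.  Each pair becomes a point

    x = ligand hydrophobicity (free-energy orientation, see below)
    y = |ligand - receptor| absolute hydrophobicity difference

and a Pearson correlation is computed per pair group (polar-nonpolar /
neutral-neutral), reading direction, ligand rule and temperature.

Sign convention: the published scatter axes are transfer *free energies*,
which are proportional to -log10 Kw>c.  ``build_pair_points`` therefore
defaults to x = -value so that the strong purine-ligand correlations come out
positive; y is unaffected (absolute difference).  Set
``as_free_energy=False`` to correlate on the raw log K axis (mirrors r).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import clusterkit
from .codebook import ComplementaryPair, Dedup, Direction, PURINES, enumerate_pairs
from .scales import Scale, logkwc_scale

__all__ = [
    "LigandRule",
    "PairPoint",
    "CorrelationResult",
    "build_pair_points",
    "pearson",
    "table1",
    "pooled_pair_correlation",
]


class LigandRule(str, enum.Enum):
    """Which pair member acts as ligand: the one with a purine or a pyrimidine 2nd base."""

    SECOND_BASE_PURINE = "second_base_purine"
    SECOND_BASE_PYRIMIDINE = "second_base_pyrimidine"


@dataclass(frozen=True)
class PairPoint:
    ligand_aa: str
    receptor_aa: str
    x: float
    y: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int
    group: str | None = None
    direction: Direction | None = None
    ligand_rule: LigandRule | None = None
    temperature_C: float | None = None


def _assign_ligand(pair: ComplementaryPair, rule: LigandRule) -> tuple[str, str]:
    sense_is_purine = pair.sense_codon[1] in PURINES
    want_sense = sense_is_purine if rule is LigandRule.SECOND_BASE_PURINE else not sense_is_purine
    if want_sense:
        return pair.sense_aa, pair.antisense_aa
    return pair.antisense_aa, pair.sense_aa


def build_pair_points(
    pairs: list[ComplementaryPair],
    scale: Scale,
    ligand_rule: LigandRule | str = LigandRule.SECOND_BASE_PURINE,
    as_free_energy: bool = True,
) -> list[PairPoint]:
    """(x, y) points for a set of complementary pairs under one ligand rule.

    The 2nd bases of the two strands are Watson-Crick complements, so exactly
    one member matches the rule in every valid pair.
    """
    if not pairs:
        raise ValueError("no pairs given")
    rule = LigandRule(ligand_rule)
    sign = -1.0 if as_free_energy else 1.0
    points = []
    for pair in pairs:
        lig, rec = _assign_ligand(pair, rule)
        xv, yv = scale[lig], scale[rec]
        points.append(PairPoint(ligand_aa=lig, receptor_aa=rec, x=sign * xv, y=abs(xv - yv)))
    return points


def pearson(points: list[PairPoint], **context) -> CorrelationResult:
    """Product-moment correlation of the (x, y) points, with the t-based two-sided p."""
    if len(points) < 3:
        raise ValueError("need at least 3 points for a correlation")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: a variable has zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_two_sided=float(res.pvalue), n=len(points), **context)


_GROUPS = ("polar-nonpolar", "neutral-neutral")


def table1(
    directions: tuple[Direction, ...] = (Direction.PARALLEL_3TO5, Direction.ANTIPARALLEL_5TO3),
    temperatures: tuple[int, ...] = (25, 100),
    ligand_rules: tuple[LigandRule, ...] = (
        LigandRule.SECOND_BASE_PURINE,
        LigandRule.SECOND_BASE_PYRIMIDINE,
    ),
    dedup: Dedup | str = Dedup.PER_CODON,
) -> pd.DataFrame:
    """Correlation matrix over groups x directions (columns) and rules x temperatures (rows).

    Long-format output with one row per cell, carrying r, p and n.  The default
    per-codon point construction is the frozen mode (it reproduces the reference
    statistics most closely; per-amino-acid-pair collapse is available).
    """
    rows = []
    for direction in directions:
        direction = Direction(direction)
        pairs = enumerate_pairs(direction, dedup=dedup)
        by_group = {g: [p for p in pairs if p.group == g] for g in _GROUPS}
        for rule in ligand_rules:
            rule = LigandRule(rule)
            for temp in temperatures:
                scale = logkwc_scale(temp)
                for group in _GROUPS:
                    pts = build_pair_points(by_group[group], scale, rule)
                    res = pearson(
                        pts,
                        group=group,
                        direction=direction,
                        ligand_rule=rule,
                        temperature_C=float(temp),
                    )
                    rows.append(
                        {
                            "group": group,
                            "direction": direction.value,
                            "ligand_rule": rule.value,
                            "temperature_C": temp,
                            "r": res.r,
                            "p_two_sided": res.p_two_sided,
                            "n": res.n,
                        }
                    )
    return pd.DataFrame(rows)


def pooled_pair_correlation(
    direction: Direction,
    temperature: int = 25,
    statistic: str = "pooled_pearson",
    dedup: Dedup | str = Dedup.PER_AA_PAIR,
) -> CorrelationResult:
    """A single correlation over ALL complementary pairs (both groups pooled).

    Three candidate interpretations are implemented, because the pooled figure
    annotation does not state its statistic:

    - ``pooled_pearson`` (default): Pearson r of the (x, y) ligand points of
      both groups together, purine-ligand convention — the same statistic as
      the per-group table, pooled.
    - ``cophenetic_upgma``: cophenetic correlation of a UPGMA tree built on
      Euclidean distances between (ligand, receptor) value pairs.
    - ``ligand_receptor``: Pearson r between ligand and receptor values.
    """
    direction = Direction(direction)
    pairs = enumerate_pairs(direction, dedup=dedup)
    scale = logkwc_scale(temperature)
    context = dict(group="pooled", direction=direction, temperature_C=float(temperature))
    if statistic == "pooled_pearson":
        pts = build_pair_points(pairs, scale, LigandRule.SECOND_BASE_PURINE)
        return pearson(pts, ligand_rule=LigandRule.SECOND_BASE_PURINE, **context)
    lig_rec = np.array(
        [(scale[p.ligand_aa], scale[p.receptor_aa]) for p in build_pair_points(pairs, scale)]
    )
    if statistic == "ligand_receptor":
        if np.ptp(lig_rec[:, 0]) == 0 or np.ptp(lig_rec[:, 1]) == 0:
            raise ValueError("undefined correlation: a variable has zero variance")
        res = stats.pearsonr(lig_rec[:, 0], lig_rec[:, 1])
        return CorrelationResult(
            r=float(res.statistic), p_two_sided=float(res.pvalue), n=len(lig_rec), **context
        )
    if statistic == "cophenetic_upgma":
        diss = clusterkit.dissimilarity(lig_rec, metric="euclidean")
        dend = clusterkit.agnes(diss, method="upgma")
        r = clusterkit.cophenetic_correlation(dend, diss)
        return CorrelationResult(r=float(r), p_two_sided=float("nan"), n=len(lig_rec), **context)
    raise ValueError(f"unknown statistic {statistic!r}")
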