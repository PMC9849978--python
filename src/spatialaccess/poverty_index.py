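"""Composite block-level deprivation score and three-class labelling.

Raw economic, social, cultural and structural indicators are combined
into one deprivation score per census block: each indicator is
z-standardized over blocks, sign-flipped so that larger always means
more deprived, and averaged with user weights.  Blocks are then split
into terciles of the score — the most deprived third is the *lower*
class (slum analogue), then *middle* and *upper*.

The aggregation is deliberately minimal and fully configurable
(weights, directions, coding); no factor-analytic weighting is
attempted.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .geodata_io import CensusBlock

__all__ = [
    "Direction",
    "IndicatorSpec",
    "PovertyClass",
    "PovertyResult",
    "DEFAULT_DIRECTIONS",
    "default_specs",
    "composite_score",
    "class_to_value",
]


class Direction(str, enum.Enum):
    #: larger raw value = more deprived (e.g. unemployment rate)
    DEPRIVATION_UP = "deprivation_up"
    #: larger raw value = less deprived (e.g. literacy rate)
    DEPRIVATION_DOWN = "deprivation_down"


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    direction: Direction = Direction.DEPRIVATION_UP
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"indicator {self.name}: negative weight")


class PovertyClass(str, enum.Enum):
    LOWER = "lower"    # most deprived tercile
    MIDDLE = "middle"
    UPPER = "upper"    # least deprived tercile


#: Default direction table for common block indicators; override per spec.
DEFAULT_DIRECTIONS: dict[str, Direction] = {
    "unemployment_rate": Direction.DEPRIVATION_UP,
    "illiteracy_rate": Direction.DEPRIVATION_UP,
    "dependency_ratio": Direction.DEPRIVATION_UP,
    "household_size": Direction.DEPRIVATION_UP,
    "overcrowding": Direction.DEPRIVATION_UP,
    "population_density": Direction.DEPRIVATION_UP,
    "literacy_rate": Direction.DEPRIVATION_DOWN,
    "employment_rate": Direction.DEPRIVATION_DOWN,
    "economic_participation": Direction.DEPRIVATION_DOWN,
}


def default_specs(names) -> list[IndicatorSpec]:
    """Equal-weight specs using the default direction table (unknown names: up)."""
    return [IndicatorSpec(n, DEFAULT_DIRECTIONS.get(n, Direction.DEPRIVATION_UP), 1.0)
            for n in names]


@dataclass
class PovertyResult:
    """Per-block composite deprivation score (z-units) and tercile class."""

    block_ids: list[str]
    scores: np.ndarray
    classes: list[PovertyClass]
    degenerate: bool = False  # all scores tied; classes assigned by tie-break only

    def score_of(self, block_id: str) -> float:
        return float(self.scores[self.block_ids.index(block_id)])

    def class_of(self, block_id: str) -> PovertyClass:
        return self.classes[self.block_ids.index(block_id)]

    def class_counts(self) -> dict[PovertyClass, int]:
        out = {c: 0 for c in PovertyClass}
        for c in self.classes:
            out[c] += 1
        return out


def composite_score(blocks: list[CensusBlock],
                    specs: list[IndicatorSpec] | None = None) -> PovertyResult:
    """Weighted mean of direction-aligned z-scored indicators, with tercile classes.

    Zero-variance indicators are dropped with a warning (all of them
    zero-variance is an error).  Class cut-points are terciles of the
    score over blocks; ties and the tercile boundaries are made
    deterministic by ordering on (score desc, block_id asc), with class
    sizes differing by at most one.
    """
    if not blocks:
        raise ValueError("no blocks")
    if specs is None:
        names = sorted({k for b in blocks for k in b.indicators})
        specs = default_specs(names)
    if not specs:
        raise ValueError("at least one indicator spec required")
    if all(s.weight == 0 for s in specs):
        raise ValueError("indicator weights are all zero")

    block_ids = [b.block_id for b in blocks]
    cols = []
    weights = []
    for spec in specs:
        try:
            raw = np.array([b.indicators[spec.name] for b in blocks], dtype=float)
        except KeyError:
            raise ValueError(f"indicator {spec.name!r} missing from block attributes")
        sd = raw.std()
        if sd == 0:
            warnings.warn(f"indicator {spec.name} has zero variance; dropped")
            continue
        z = (raw - raw.mean()) / sd
        if Direction(spec.direction) is Direction.DEPRIVATION_DOWN:
            z = -z
        cols.append(z)
        weights.append(spec.weight)
    if not cols:
        raise ValueError("all indicators have zero variance")
    w = np.asarray(weights, dtype=float)
    scores = np.column_stack(cols) @ (w / w.sum())

    n = len(blocks)
    # most deprived first; block_id breaks ties deterministically
    order = sorted(range(n), key=lambda i: (-scores[i], block_ids[i]))
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n), 3)]
    classes: list[PovertyClass | None] = [None] * n
    pos = 0
    for cls, size in zip((PovertyClass.LOWER, PovertyClass.MIDDLE, PovertyClass.UPPER), sizes):
        for i in order[pos:pos + size]:
            classes[i] = cls
        pos += size
    degenerate = bool(np.allclose(scores, scores[0]))
    if degenerate:
        warnings.warn("composite scores are all tied; classes assigned by "
                      "block_id tie-break only")
    return PovertyResult(block_ids=block_ids, scores=scores,
                         classes=classes, degenerate=degenerate)


def class_to_value(result: PovertyResult, coding: str = "ordinal") -> np.ndarray:
    """Numeric coding of classes for autocorrelation testing.

    ``ordinal``: lower=3, middle=2, upper=1 (deprivation-increasing);
    ``lower_binary``: 1 for the lower (most deprived) class, else 0.
    """
    if coding == "ordinal":
        table = {PovertyClass.LOWER: 3.0, PovertyClass.MIDDLE: 2.0, PovertyClass.UPPER: 1.0}
    elif coding == "lower_binary":
        table = {PovertyClass.LOWER: 1.0, PovertyClass.MIDDLE: 0.0, PovertyClass.UPPER: 0.0}
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return np.array([table[c] for c in result.classes])
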