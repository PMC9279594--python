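"""Clonogenicity and lifespan metrics for serially passaged keratinocyte cultures.

A culture is expanded passage by passage; at each passage a known inoculum is
plated, a colony-forming efficiency (CFE) is measured, and the culture is
grown to a cell yield (UCY). The number of clonogenic cells I is the inoculum
multiplied by the CFE, and the population doublings accumulated within the
passage are log2(UCY / I). Cumulative population doublings are their sum over
passages; the lifespan ends at the first passage whose CFE reaches zero.

The module also covers two endpoint quantifications used alongside the
colony data: qPCR relative expression by the 2^-ddCt method, and the
regression of culture lifespan on initial stemness-marker expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stats import LinearFit, fit_linear

__all__ = [
    "PassageRecord",
    "LifespanSummary",
    "QpcrRecord",
    "clonogenic_count",
    "population_doublings",
    "cumulative_doublings",
    "abortion_crossing",
    "ddct_relative_expression",
    "marker_vs_passage_regression",
]


@dataclass(frozen=True)
class PassageRecord:
    """One passage of one culture: inoculum, CFE, yield, aborted-colony fraction."""

    culture_id: str
    passage: int
    inoculum: float
    cfe: float
    cell_yield: float
    aborted_fraction: float

    def __post_init__(self) -> None:
        if self.passage < 1:
            raise ValueError(f"passage index must be >= 1, got {self.passage}")
        if not 0.0 <= self.cfe <= 1.0:
            raise ValueError(f"cfe must be in [0, 1], got {self.cfe}")
        if not 0.0 <= self.aborted_fraction <= 1.0:
            raise ValueError(
                f"aborted_fraction must be in [0, 1], got {self.aborted_fraction}"
            )
        if self.inoculum < 0 or self.cell_yield < 0:
            raise ValueError("inoculum and cell_yield must be non-negative")

    @property
    def clonogenic(self) -> float:
        return clonogenic_count(self.inoculum, self.cfe)


@dataclass(frozen=True)
class LifespanSummary:
    culture_id: str
    n_passages: int
    per_passage_doublings: tuple[float, ...]
    cumulative_doublings: float
    passage_at_half_abortion: int | None
    days_in_culture: float | None = None


@dataclass(frozen=True)
class QpcrRecord:
    """Raw qPCR cycle thresholds for a target and its reference gene."""

    sample_id: str
    target_ct: float
    reference_ct: float
    calibrator: bool = False

    def __post_init__(self) -> None:
        for name, ct in (("target_ct", self.target_ct), ("reference_ct", self.reference_ct)):
            if ct is None or not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be finite and positive, got {ct}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def clonogenic_count(inoculum: float, cfe: float) -> float:
    """Clonogenic cells in an inoculum: plated cells times colony-forming efficiency."""
    if inoculum < 0:
        raise ValueError("inoculum must be non-negative")
    if not 0.0 <= cfe <= 1.0:
        raise ValueError(f"cfe must be in [0, 1], got {cfe}")
    return inoculum * cfe


def population_doublings(cell_yield: float, clonogenic: float) -> float:
    """Population doublings within one passage: log2(cell_yield / clonogenic).

    Equivalently 3.322·log10(UCY/I) with 3.322 = 1/log10(2); the exact
    base-2 logarithm is used. Doubling the yield at fixed clonogenic input
    adds exactly one doubling.
    """
    if cell_yield <= 0 or clonogenic <= 0:
        raise ValueError("cell_yield and clonogenic count must be positive")
    return math.log2(cell_yield / clonogenic)


def cumulative_doublings(
    records: Sequence[PassageRecord],
    level: float = 0.5,
    use_initial_clonogenic: bool = False,
) -> LifespanSummary:
    """Summarise a culture's lifespan from its ordered passage records.

    Per-passage doublings use that passage's own clonogenic count as the
    denominator (set ``use_initial_clonogenic=True`` to divide every yield by
    the first passage's count instead). The first passage with CFE = 0
    contributes zero doublings and terminates the lifespan; any later record
    claiming CFE > 0 is rejected as inconsistent.
    """
    if not records:
        raise ValueError("no passage records supplied")
    cultures = {r.culture_id for r in records}
    if len(cultures) > 1:
        raise ValueError(f"records mix cultures: {sorted(cultures)}")
    passages = [r.passage for r in records]
    if len(set(passages)) != len(passages) or passages != sorted(passages):
        raise ValueError("passages must be strictly increasing with no duplicates")

    exhausted = False
    doublings: list[float] = []
    initial_i = records[0].clonogenic
    for rec in records:
        if exhausted and rec.cfe > 0:
            raise ValueError(
                f"passage {rec.passage} has CFE > 0 after the culture was exhausted"
            )
        if rec.cfe == 0 or rec.clonogenic == 0:
            exhausted = True
            doublings.append(0.0)
            continue
        denom = initial_i if use_initial_clonogenic else rec.clonogenic
        doublings.append(population_doublings(rec.cell_yield, denom))
    n_passages = sum(1 for r in records if r.cfe > 0)
    return LifespanSummary(
        culture_id=records[0].culture_id,
        n_passages=n_passages,
        per_passage_doublings=tuple(doublings),
        cumulative_doublings=float(sum(doublings)),
        passage_at_half_abortion=abortion_crossing(records, level),
    )


def abortion_crossing(records: Sequence[PassageRecord], level: float = 0.5) -> int | None:
    """First passage whose aborted-colony fraction reaches ``level`` (>= rule).

    Returns ``None`` when the fraction never reaches the level.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level must be in (0, 1], got {level}")
    for rec in sorted(records, key=lambda r: r.passage):
        if rec.aborted_fraction >= level:
            return rec.passage
    return None


def ddct_relative_expression(sample: QpcrRecord, calibrator: QpcrRecord) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = target_ct - reference_ct within each record; ddCt is the sample's
    dCt minus the calibrator's; the fold change relative to the calibrator is
    2^(-ddCt). Assumes approximately equal amplification efficiencies for
    target and reference.
    """
    ddct = sample.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct)


def marker_vs_passage_regression(
    marker_levels: Sequence[float], max_passages: Sequence[float]
) -> LinearFit:
    """Regress culture lifespan (passages reached) on initial marker expression.

    Ordinary least squares with the marker level as the predictor; a positive
    slope means cultures starting with more marker-positive cells last
    longer. Requires at least 3 paired observations.
    """
    x = np.asarray(marker_levels, dtype=float)
    y = np.asarray(max_passages, dtype=float)
    if x.size != y.size:
        raise ValueError("marker_levels and max_passages must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 paired observations are required")
    return fit_linear(x, y)
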