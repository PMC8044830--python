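"""Set-overlap bookkeeping, stemness-matrix node counts, and the
prevalence–mortality correlation/attribution arithmetic.

Percentages are rounded half-up to 2 decimal places, matching the precision
of the published-style count tables this module reproduces; the rounding mode
matters for fixture equality and is therefore fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr

__all__ = [
    "round_half_up",
    "OverlapRow",
    "OverlapTable",
    "overlap_table",
    "StemnessMatrix",
    "stemness_nodes",
    "pearson_with_bonferroni",
    "MortalityRecord",
    "mortality_attribution",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OverlapRow:
    label: str
    total: int
    overlap: int
    percent: float

    def __post_init__(self) -> None:
        if not (0 <= self.overlap <= self.total):
            raise ValueError(
                f"{self.label!r}: overlap {self.overlap} outside [0, total={self.total}]"
            )


@dataclass
class OverlapTable:
    """Category rows of (total, overlapping, percent)."""

    rows: list[OverlapRow] = field(default_factory=list)

    def audit(self) -> list[str]:
        """Labels of rows whose percent does not recompute from its counts."""
        bad = []
        for row in self.rows:
            expected = round_half_up(100.0 * row.overlap / row.total, 2) if row.total else 0.0
            if abs(expected - row.percent) > 1e-9:
                bad.append(row.label)
        return bad


def overlap_table(
    category_sets: Mapping[str, Iterable[str]],
    reference: Iterable[str],
    all_label: str = "ALL",
) -> OverlapTable:
    """Per category: ``|set|``, ``|set ∩ reference|`` and the percent overlap,
    plus an ``ALL`` row over the union of the categories."""
    if not category_sets:
        raise ValueError("no category sets given")
    ref = set(reference)
    rows: list[OverlapRow] = []
    union: set[str] = set()
    for label, members in category_sets.items():
        mset = set(members)
        if not mset:
            raise ValueError(f"category {label!r} is empty")
        union |= mset
        overlap = len(mset & ref)
        rows.append(
            OverlapRow(label, len(mset), overlap, round_half_up(100.0 * overlap / len(mset)))
        )
    overlap = len(union & ref)
    rows.append(
        OverlapRow(all_label, len(union), overlap, round_half_up(100.0 * overlap / len(union)))
    )
    return OverlapTable(rows)


@dataclass
class StemnessMatrix:
    """Per-cancer-type counts of silenced and activated driver genes, crossed
    with the number of regulator families (default 3: the HERV-H lncRNA,
    LTR7Y/B and LTR5_Hs/SVA_D families) to define actionable
    gene × cancer-type × family nodes."""

    counts: dict[str, tuple[int, int]]  # cancer type -> (silenced, activated)
    family_count: int = 3

    def __post_init__(self) -> None:
        if self.family_count < 1:
            raise ValueError("family_count must be >= 1")
        for cancer, (sil, act) in self.counts.items():
            if sil < 0 or act < 0:
                raise ValueError(f"{cancer!r}: negative gene count")


def stemness_nodes(matrix: StemnessMatrix) -> tuple[int, int]:
    """(silenced node count, activated node count) =
    column sums × family count."""
    sil = sum(s for s, _ in matrix.counts.values())
    act = sum(a for _, a in matrix.counts.values())
    return sil * matrix.family_count, act * matrix.family_count


def pearson_with_bonferroni(
    x: Sequence[float], y: Sequence[float], m: int = 1
) -> tuple[float, float, float]:
    """Pearson r with two-sided p (t transform, n−2 df) and a Bonferroni
    adjustment for ``m`` tests: ``min(1, m·p)``."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 3:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 3")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in x or y")
    if m < 1:
        raise ValueError("m must be >= 1")
    r, p = pearsonr(xa, ya)
    return float(r), float(p), float(min(1.0, m * p))


@dataclass
class MortalityRecord:
    """Per-cancer-type prevalence of the malignancy subtype of interest and
    the annual case/death counts used for death attribution."""

    cancer_type: str
    prevalence_pct: float
    new_cases: float
    deaths: float
    attributed_cases: float | None = None
    attributed_deaths: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence_pct <= 100.0):
            raise ValueError(f"{self.cancer_type!r}: prevalence must be in [0, 100]")
        if self.new_cases < 0 or self.deaths < 0:
            raise ValueError(f"{self.cancer_type!r}: negative case or death count")


def mortality_attribution(
    records: Sequence[MortalityRecord],
) -> tuple[list[MortalityRecord], dict[str, float]]:
    """Attribute annual cases and deaths to the subtype per its prevalence.

    ``attributed_cases = prevalence/100 × new_cases``;
    ``attributed_deaths = min(attributed_cases, deaths)`` — attributed deaths
    are capped so they never exceed the type's total deaths.  The summary
    reports totals and the share of all deaths attributed.
    """
    completed: list[MortalityRecord] = []
    for rec in records:
        cases = rec.prevalence_pct / 100.0 * rec.new_cases
        deaths = min(cases, rec.deaths)
        completed.append(
            MortalityRecord(
                cancer_type=rec.cancer_type,
                prevalence_pct=rec.prevalence_pct,
                new_cases=rec.new_cases,
                deaths=rec.deaths,
                attributed_cases=cases,
                attributed_deaths=deaths,
            )
        )
    total_deaths = sum(r.deaths for r in completed)
    attributed = sum(r.attributed_deaths for r in completed)
    summary = {
        "total_new_cases": sum(r.new_cases for r in completed),
        "total_deaths": total_deaths,
        "attributed_cases": sum(r.attributed_cases for r in completed),
        "attributed_deaths": attributed,
        "attributed_death_share_pct": (
            100.0 * attributed / total_deaths if total_deaths > 0 else 0.0
        ),
    }
    return completed, summary
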