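"""Marker-threshold classification of multi-lineage markers expressing (MLME)
cells in single-cell expression matrices of human preimplantation embryos.

A cell is called MLME when, simultaneously,

* it expresses at least ``min_epi`` epiblast (EPI), ``min_te`` trophectoderm
  (TE) and ``min_pe`` primitive-endoderm (PE) lineage markers (defaults
  6 / 7 / 4);
* it expresses all three master pluripotency factors NANOG, POU5F1 (OCT4)
  and SOX2; and
* it is telomerase-positive (expresses TERT).

"Expresses" is a binary call per gene and cell: the value strictly exceeds
the median expression of that gene across the cell population.  Ties at the
median — including genes whose values are all equal — are called
not-expressed; telomerase positivity reuses the same rule, which is the only
expression rule the selection procedure defines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from .enrichment import adjust_pvalues
from .io_formats import ExpressionMatrix

__all__ = [
    "SYMBOL_ALIASES",
    "MarkerPanelSet",
    "MLMECriteria",
    "CellCall",
    "expression_calls",
    "classify_mlme",
    "derive_deg_sets",
]

# HGNC-style aliases; the pluripotency trio is printed both as OCT4/NANOG/SOX2
# and NANOG/POU5F1/SOX2 in the source material — OCT4 is POU5F1.
SYMBOL_ALIASES = {"OCT4": "POU5F1"}


def resolve_symbol(gene: str) -> str:
    return SYMBOL_ALIASES.get(gene, gene)


@dataclass
class MarkerPanelSet:
    """Lineage marker panels plus the pluripotency trio and telomerase gene."""

    epi_markers: list[str]
    te_markers: list[str]
    pe_markers: list[str]
    pluripotency_trio: tuple[str, str, str] = ("NANOG", "POU5F1", "SOX2")
    telomerase_gene: str = "TERT"

    def __post_init__(self) -> None:
        self.epi_markers = [resolve_symbol(g) for g in self.epi_markers]
        self.te_markers = [resolve_symbol(g) for g in self.te_markers]
        self.pe_markers = [resolve_symbol(g) for g in self.pe_markers]
        self.pluripotency_trio = tuple(resolve_symbol(g) for g in self.pluripotency_trio)
        self.telomerase_gene = resolve_symbol(self.telomerase_gene)
        if len(self.pluripotency_trio) != 3 or len(set(self.pluripotency_trio)) != 3:
            raise ValueError("pluripotency trio must be exactly three distinct genes")
        panels = {
            "EPI": self.epi_markers,
            "TE": self.te_markers,
            "PE": self.pe_markers,
        }
        for name, panel in panels.items():
            if not panel:
                raise ValueError(f"{name} marker panel is empty")
            if len(set(panel)) != len(panel):
                raise ValueError(f"{name} marker panel contains duplicates")
        special = set(self.pluripotency_trio) | {self.telomerase_gene}
        seen: set[str] = set(special)
        for name, panel in panels.items():
            overlap = set(panel) & seen
            if overlap:
                raise ValueError(
                    f"{name} panel overlaps other panels/trio/telomerase: {sorted(overlap)}"
                )
            seen |= set(panel)

    @property
    def panels(self) -> dict[str, list[str]]:
        return {"EPI": self.epi_markers, "TE": self.te_markers, "PE": self.pe_markers}

    def all_genes(self) -> list[str]:
        return (
            self.epi_markers
            + self.te_markers
            + self.pe_markers
            + list(self.pluripotency_trio)
            + [self.telomerase_gene]
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanelSet":
        """Load panels from a YAML mapping ``lineage -> gene list``.

        Recognised keys: ``EPI``, ``TE``, ``PE`` (required), ``trio`` and
        ``telomerase`` (optional, defaulting to NANOG/POU5F1/SOX2 and TERT).
        """
        data = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        if "trio" in data:
            kwargs["pluripotency_trio"] = tuple(data["trio"])
        if "telomerase" in data:
            kwargs["telomerase_gene"] = data["telomerase"]
        return cls(data["EPI"], data["TE"], data["PE"], **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "EPI": list(self.epi_markers),
            "TE": list(self.te_markers),
            "PE": list(self.pe_markers),
            "trio": list(self.pluripotency_trio),
            "telomerase": self.telomerase_gene,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass(frozen=True)
class MLMECriteria:
    """Per-lineage marker-count minimums and gating flags of the MLME call."""

    min_epi: int = 6
    min_te: int = 7
    min_pe: int = 4
    require_trio: bool = True
    require_telomerase: bool = True

    def __post_init__(self) -> None:
        for name, value in (("min_epi", self.min_epi), ("min_te", self.min_te), ("min_pe", self.min_pe)):
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")

    def validate_against(self, panels: MarkerPanelSet) -> None:
        limits = {
            "min_epi": len(panels.epi_markers),
            "min_te": len(panels.te_markers),
            "min_pe": len(panels.pe_markers),
        }
        for name, size in limits.items():
            if getattr(self, name) > size:
                raise ValueError(
                    f"{name}={getattr(self, name)} exceeds panel size {size}"
                )


@dataclass
class CellCall:
    """Per-cell marker counts, gate flags and the MLME decision."""

    cell_id: str
    epi_count: int
    te_count: int
    pe_count: int
    trio_ok: bool
    telomerase_ok: bool
    is_mlme: bool


def expression_calls(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Binary expression calls: value strictly exceeds the gene's population median.

    The median is over all cells of the gene (even counts use the standard
    midpoint).  A gene with all-equal values yields all-false calls — nothing
    exceeds its own median.
    """
    if matrix.n_cells < 2:
        raise ValueError("expression calls need at least 2 cells")
    medians = np.median(matrix.values, axis=1, keepdims=True)
    calls = matrix.values > medians
    return pd.DataFrame(calls, index=matrix.gene_ids, columns=matrix.cell_ids)


def classify_mlme(
    calls: pd.DataFrame,
    panels: MarkerPanelSet,
    criteria: MLMECriteria = MLMECriteria(),
) -> list[CellCall]:
    """Apply the marker-count / trio / telomerase conjunction to call MLME cells."""
    criteria.validate_against(panels)
    needed = set(panels.all_genes())
    missing = sorted(needed - set(calls.index))
    if missing:
        raise ValueError(f"panel genes absent from the matrix: {missing}")
    epi = calls.loc[panels.epi_markers].sum(axis=0)
    te = calls.loc[panels.te_markers].sum(axis=0)
    pe = calls.loc[panels.pe_markers].sum(axis=0)
    trio = calls.loc[list(panels.pluripotency_trio)].all(axis=0)
    tert = calls.loc[panels.telomerase_gene]
    out: list[CellCall] = []
    for cell in calls.columns:
        trio_ok = bool(trio[cell])
        tert_ok = bool(tert[cell])
        is_mlme = (
            epi[cell] >= criteria.min_epi
            and te[cell] >= criteria.min_te
            and pe[cell] >= criteria.min_pe
            and (trio_ok or not criteria.require_trio)
            and (tert_ok or not criteria.require_telomerase)
        )
        out.append(
            CellCall(
                cell_id=str(cell),
                epi_count=int(epi[cell]),
                te_count=int(te[cell]),
                pe_count=int(pe[cell]),
                trio_ok=trio_ok,
                telomerase_ok=tert_ok,
                is_mlme=bool(is_mlme),
            )
        )
    return out


def calls_to_frame(calls: Iterable[CellCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "epi_count": c.epi_count,
                "te_count": c.te_count,
                "pe_count": c.pe_count,
                "trio_ok": c.trio_ok,
                "telomerase_ok": c.telomerase_ok,
                "is_mlme": c.is_mlme,
            }
            for c in calls
        ]
    )


def derive_deg_sets(
    matrix: ExpressionMatrix,
    mlme_flags: Sequence[bool],
    alpha: float = 0.05,
    fdr_method: str = "bh",
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets of the MLME subpopulation.

    Per gene, a two-sided Wilcoxon rank-sum (Mann-Whitney) test compares MLME
    against non-MLME cells; p values are adjusted (BH by default) and genes
    with adjusted p < ``alpha`` are split by the sign of the difference of
    group medians, falling back to the difference of group means when the
    medians tie (sparse data: a marker expressed in under half of either
    group has median 0 in both).  The selection procedure in the source
    domain reports such sets without stating a derivation; this rank-based
    recipe is this package's documented choice.
    """
    flags = np.asarray(mlme_flags, dtype=bool)
    if flags.size != matrix.n_cells:
        raise ValueError("one flag per cell required")
    if flags.sum() < 2 or (~flags).sum() < 2:
        raise ValueError("both groups need at least 2 cells")
    group_a = matrix.values[:, flags]
    group_b = matrix.values[:, ~flags]
    # identical groups give a constant matrix row-wise; mannwhitneyu handles
    # ties, p=1 for all-tied rows
    stat = mannwhitneyu(group_a, group_b, axis=1, alternative="two-sided")
    pvals = np.asarray(stat.pvalue, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0  # all-tied rows have no evidence either way
    adjusted = adjust_pvalues(pvals, method=fdr_method)
    direction = np.median(group_a, axis=1) - np.median(group_b, axis=1)
    ties = direction == 0
    direction[ties] = np.mean(group_a[ties], axis=1) - np.mean(group_b[ties], axis=1)
    up = {
        g
        for g, q, d in zip(matrix.gene_ids, adjusted, direction)
        if q < alpha and d > 0
    }
    down = {
        g
        for g, q, d in zip(matrix.gene_ids, adjusted, direction)
        if q < alpha and d < 0
    }
    return up, down
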