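"""Seeded generators for every input the pipeline consumes.

Three planted-structure generators (expression matrices with an MLME
subpopulation, genome fixtures with a known fraction of genes near elements,
gene-set libraries with planted overlap enrichment) plus a writer for the
transcribed printed-count fixtures.  All randomness flows from the single
``seed`` of each call through one ``numpy.random.default_rng`` stream, so
identical configuration gives byte-identical outputs.

Expression model
----------------
The generator targets the statistical structure the median-exceedance
classifier assumes — sparse background expression with a clearly shifted
signal — and nothing more (no UMI counts, no library-size effects):

* background entries are "on" (leakily expressed) with probability
  ``background_on_fraction`` and are otherwise exactly 0; an on entry takes
  the value ``exp(eps)``, ``eps ~ Normal(0, noise_sd)``, and is then zeroed
  with probability ``dropout_rate``;
* signal entries (the markers a planted cell expresses, its pluripotency
  trio and TERT) take ``exp(marker_effect + eps)`` and are always present —
  the planted pattern is the construction, not a noisy tendency;
* a planted MLME cell expresses a uniformly drawn number of markers per
  lineage between that lineage's criterion threshold (6/7/4) and the panel
  size; lineage-only cells express a marker subset of one panel only.

With a sparse background (``background_on_fraction < 0.5`` after dropout) a
gene's population median is 0, so the strict median-exceedance call is
exactly "non-zero": planted cells are recovered perfectly in the noiseless
limit and near-perfectly at the default noise settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    ExpressionMatrix,
    GeneSetLibrary,
    GenomicInterval,
)
from . import tables

__all__ = [
    "DEFAULT_PANEL_SIZES",
    "DISCOVERY_PANEL_SIZES",
    "SimulationConfig",
    "TruthLabels",
    "generate_expression_matrix",
    "generate_genome_fixture",
    "generate_gene_set_library",
    "emit_count_fixtures",
]

# validation panels: top-100 markers per lineage (the PE panel prints 88);
# the 58-marker discovery preset splits the published total evenly-ish.
DEFAULT_PANEL_SIZES: dict[str, int] = {"EPI": 100, "TE": 100, "PE": 88}
DISCOVERY_PANEL_SIZES: dict[str, int] = {"EPI": 20, "TE": 20, "PE": 18}

_MIN_MARKERS = {"EPI": 6, "TE": 7, "PE": 4}
_TRIO = ("NANOG", "POU5F1", "SOX2")
_TERT = "TERT"


@dataclass
class SimulationConfig:
    """Conditions of one simulated embryo-cell cohort.

    ``n_mlme`` cells carry the full planted MLME pattern; ``n_lineage_only``
    maps lineage name to a count of cells expressing only that lineage's
    markers (no trio/TERT guarantee).  Effects and noise are on the log
    scale.
    """

    n_cells: int = 1000
    n_genes: int = 1000
    n_mlme: int = 135
    panel_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PANEL_SIZES))
    n_lineage_only: dict[str, int] = field(default_factory=dict)
    marker_effect: float = 3.0
    noise_sd: float = 1.0
    dropout_rate: float = 0.1
    background_on_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.n_genes < 1:
            raise ValueError("need n_cells >= 2 and n_genes >= 1")
        if self.n_mlme < 0 or self.n_mlme > self.n_cells:
            raise ValueError(f"n_mlme={self.n_mlme} outside [0, n_cells={self.n_cells}]")
        for lineage, minimum in _MIN_MARKERS.items():
            size = self.panel_sizes.get(lineage, 0)
            if size < minimum:
                raise ValueError(
                    f"{lineage} panel size {size} below criterion threshold {minimum}"
                )
        planted = self.n_mlme + sum(self.n_lineage_only.values())
        if planted > self.n_cells:
            raise ValueError("planted cells exceed n_cells")
        for name, value in (
            ("dropout_rate", self.dropout_rate),
            ("background_on_fraction", self.background_on_fraction),
        ):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.marker_effect <= 0 or self.noise_sd < 0:
            raise ValueError("marker_effect must be positive and noise_sd non-negative")
        n_special = sum(self.panel_sizes.values()) + len(_TRIO) + 1
        if self.n_genes < n_special:
            raise ValueError(
                f"n_genes={self.n_genes} cannot hold {n_special} marker/trio/TERT genes"
            )


@dataclass
class TruthLabels:
    """Ground truth of a generated dataset, for recovery scoring."""

    cell_roles: dict[str, str] = field(default_factory=dict)  # cell -> role
    gene_panels: dict[str, str] = field(default_factory=dict)  # gene -> panel/category
    planted_associations: dict[str, str] = field(default_factory=dict)  # gene -> element
    enriched_sets: list[str] = field(default_factory=list)

    def cells_with_role(self, role: str) -> set[str]:
        return {c for c, r in self.cell_roles.items() if r == role}


def _panel_gene_ids(panel_sizes: Mapping[str, int]) -> dict[str, list[str]]:
    return {
        lineage: [f"{lineage}_M{i + 1:03d}" for i in range(size)]
        for lineage, size in panel_sizes.items()
    }


def generate_expression_matrix(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TruthLabels]:
    """Simulate a genes × cells matrix with a planted MLME subpopulation."""
    rng = np.random.default_rng(config.seed)
    panels = _panel_gene_ids(config.panel_sizes)
    marker_genes = [g for genes in panels.values() for g in genes]
    special = marker_genes + list(_TRIO) + [_TERT]
    n_background_genes = config.n_genes - len(special)
    gene_ids = special + [f"BG_{i + 1:04d}" for i in range(n_background_genes)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    roles: list[tuple[str, str]] = []  # (cell_id, role)
    for i in range(config.n_mlme):
        roles.append((f"MLME_{i + 1:04d}", "MLME"))
    for lineage, count in sorted(config.n_lineage_only.items()):
        if lineage not in panels:
            raise ValueError(f"unknown lineage {lineage!r} in n_lineage_only")
        for i in range(count):
            roles.append((f"{lineage}only_{i + 1:04d}", f"{lineage}-only"))
    n_bg_cells = config.n_cells - len(roles)
    roles += [(f"CELL_{i + 1:04d}", "background") for i in range(n_bg_cells)]
    cell_ids = [c for c, _ in roles]

    shape = (config.n_genes, config.n_cells)
    on = rng.random(shape) < config.background_on_fraction
    noise = rng.normal(0.0, config.noise_sd, size=shape) if config.noise_sd > 0 else np.zeros(shape)
    values = np.where(on, np.exp(noise), 0.0)
    if config.dropout_rate > 0:
        values[rng.random(shape) < config.dropout_rate] = 0.0

    truth = TruthLabels()
    for gene in marker_genes:
        truth.gene_panels[gene] = gene.split("_")[0]
    for gene in _TRIO:
        truth.gene_panels[gene] = "trio"
    truth.gene_panels[_TERT] = "telomerase"

    def plant(cell_col: int, genes: Sequence[str]) -> None:
        idx = [gene_index[g] for g in genes]
        eps = rng.normal(0.0, config.noise_sd, size=len(idx)) if config.noise_sd > 0 else 0.0
        values[idx, cell_col] = np.exp(config.marker_effect + eps)

    for col, (cell_id, role) in enumerate(roles):
        truth.cell_roles[cell_id] = role
        if role == "MLME":
            expressed: list[str] = []
            for lineage, genes in panels.items():
                m = int(rng.integers(_MIN_MARKERS[lineage], len(genes) + 1))
                chosen = rng.choice(len(genes), size=m, replace=False)
                expressed += [genes[j] for j in chosen]
            plant(col, expressed + list(_TRIO) + [_TERT])
        elif role.endswith("-only"):
            lineage = role[: -len("-only")]
            genes = panels[lineage]
            m = int(rng.integers(_MIN_MARKERS[lineage], len(genes) + 1))
            chosen = rng.choice(len(genes), size=m, replace=False)
            plant(col, [genes[j] for j in chosen])

    matrix = ExpressionMatrix(gene_ids, cell_ids, values)
    return matrix, truth


# ---------------------------------------------------------------------------
# Genome fixtures with planted proximity structure
# ---------------------------------------------------------------------------


class PackingError(ValueError):
    """The requested intervals cannot be placed in the given genome length."""


def generate_genome_fixture(
    n_genes: int,
    n_elements: int,
    planted_fraction: float,
    genome_length: int,
    window: int = 10_000,
    seed: int = 0,
    gene_length: int = 1_000,
    element_length: int = 500,
    n_chromosomes: int = 1,
) -> tuple[list[GenomicInterval], list[GenomicInterval], TruthLabels]:
    """Place genes and elements so that exactly ``round(planted_fraction *
    n_genes)`` genes lie within ``window`` bp of some element and every other
    gene is farther than ``window`` from all elements.

    Intervals are laid left-to-right with randomized spacing on
    ``n_chromosomes`` synthetic chromosomes of ``genome_length`` bp each;
    associated genes sit downstream of their element at gaps in
    ``[0, window]``.  Raises :class:`PackingError` when the layout cannot
    fit.
    """
    if not (0.0 <= planted_fraction <= 1.0):
        raise ValueError("planted_fraction must be in [0, 1]")
    if n_elements < 1 and planted_fraction > 0:
        raise ValueError("cannot plant associations without elements")
    rng = np.random.default_rng(seed)
    n_near = round(planted_fraction * n_genes)
    n_far = n_genes - n_near

    # round-robin assignment of near genes to elements, far genes to slots
    near_per_element = [0] * max(n_elements, 1)
    for i in range(n_near):
        near_per_element[i % max(n_elements, 1)] += 1
    far_per_slot = [0] * (max(n_elements, 1) + 1)
    for i in range(n_far):
        far_per_slot[i % len(far_per_slot)] += 1

    chrom_of = lambda i: f"chr{(i % n_chromosomes) + 1}"
    cursors = {f"chr{c + 1}": 0 for c in range(n_chromosomes)}
    genes: list[GenomicInterval] = []
    elements: list[GenomicInterval] = []
    truth = TruthLabels()
    gene_no = 0

    def place_far(chrom: str, count: int) -> None:
        nonlocal gene_no
        for _ in range(count):
            gap = int(rng.integers(window + 1, window + 2 * gene_length + 2))
            start = cursors[chrom] + gap
            genes.append(
                GenomicInterval(chrom, start, start + gene_length, f"G{gene_no + 1:05d}")
            )
            gene_no += 1
            cursors[chrom] = start + gene_length

    for e in range(max(n_elements, 1)):
        chrom = chrom_of(e)
        if n_elements > 0:
            start = cursors[chrom] + int(rng.integers(window + 1, 2 * window + 2))
            elem = GenomicInterval(chrom, start, start + element_length, f"E{e + 1:04d}")
            elements.append(elem)
            cursors[chrom] = elem.end
            # near genes: each starts at an independent gap in [0, window]
            # downstream of the element (genes may overlap one another)
            for _ in range(near_per_element[e]):
                gap = int(rng.integers(0, window + 1))
                start = elem.end + gap
                gene = GenomicInterval(chrom, start, start + gene_length, f"G{gene_no + 1:05d}")
                genes.append(gene)
                truth.planted_associations[gene.id] = elem.id
                gene_no += 1
                cursors[chrom] = max(cursors[chrom], gene.end)
        place_far(chrom, far_per_slot[e])
    place_far(chrom_of(max(n_elements, 1)), far_per_slot[-1])

    if any(cursor > genome_length for cursor in cursors.values()):
        raise PackingError(
            f"layout needs {max(cursors.values())} bp but genome_length is {genome_length}"
        )
    return genes, elements, truth


# ---------------------------------------------------------------------------
# Gene-set libraries with planted enrichment
# ---------------------------------------------------------------------------


def generate_gene_set_library(
    universe: Sequence[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    target_set: Sequence[str],
    enriched_set_count: int,
    enrichment_odds: float,
    seed: int = 0,
) -> tuple[GeneSetLibrary, TruthLabels]:
    """Build a library whose first ``enriched_set_count`` sets oversample the
    target genes with the given odds multiplier; the rest sample uniformly.

    Sampling is without replacement with probability proportional to the
    per-gene weight (``enrichment_odds`` for target members, 1 otherwise).
    """
    universe = list(dict.fromkeys(universe))
    target = set(target_set)
    if not target <= set(universe):
        raise ValueError("target_set must be a subset of the universe")
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError(
            f"set sizes [{lo}, {hi}] must be within [1, |universe|={len(universe)}]"
        )
    if enriched_set_count > n_sets:
        raise ValueError("enriched_set_count exceeds n_sets")
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")
    rng = np.random.default_rng(seed)
    weights = np.array([enrichment_odds if g in target else 1.0 for g in universe])
    weights_enr = weights / weights.sum()
    library = GeneSetLibrary()
    truth = TruthLabels()
    n_digits = len(str(n_sets))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < enriched_set_count
        p = weights_enr if enriched else None
        members_idx = rng.choice(len(universe), size=size, replace=False, p=p)
        name = f"SET_{i + 1:0{n_digits}d}"
        kind = "planted" if enriched else "null"
        library.add(name, kind, [universe[j] for j in sorted(members_idx)])
        if enriched:
            truth.enriched_sets.append(name)
    return library, truth


# ---------------------------------------------------------------------------
# Printed-count fixtures
# ---------------------------------------------------------------------------


def emit_count_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the transcribed count tables as TSV fixtures.

    ``enrichment_params.tsv``
        header table_id, row_label, N, K, n, k, printed_percent, printed_p,
        printed_oe — one row per printed enrichment statistic.
    ``overlap_counts.tsv``
        header table_id, row_label, total, overlap, printed_percent.
    ``stemness_matrix.tsv``
        header cancer_type, silenced, activated, plus ``#`` comment lines
        carrying the family count and printed node totals.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    path = outdir / "enrichment_params.tsv"
    lines = ["table_id\trow_label\tN\tK\tn\tk\tprinted_percent\tprinted_p\tprinted_oe"]
    for row in tables.ENRICHMENT_ROWS:
        lines.append(
            f"{row.table_id}\t{row.row_label}\t{row.N}\t{row.K}\t{row.n}\t{row.k}"
            f"\t{row.printed_percent}\t{row.printed_p}\t{row.printed_oe}"
        )
    path.write_text("\n".join(lines) + "\n")
    paths["enrichment_params"] = path

    path = outdir / "overlap_counts.tsv"
    lines = ["table_id\trow_label\ttotal\toverlap\tprinted_percent"]
    for row in tables.COUNT_ROWS:
        lines.append(
            f"{row.table_id}\t{row.row_label}\t{row.total}\t{row.overlap}\t{row.printed_percent}"
        )
    path.write_text("\n".join(lines) + "\n")
    paths["overlap_counts"] = path

    path = outdir / "stemness_matrix.tsv"
    sil_total, act_total = tables.STEMNESS_PRINTED_TOTALS
    lines = [
        f"# family_count={tables.STEMNESS_FAMILY_COUNT}",
        f"# printed_silenced_nodes={sil_total}",
        f"# printed_activated_nodes={act_total}",
        "cancer_type\tsilenced\tactivated",
    ]
    for cancer, (sil, act) in tables.STEMNESS_COUNTS.items():
        lines.append(f"{cancer}\t{sil}\t{act}")
    path.write_text("\n".join(lines) + "\n")
    paths["stemness_matrix"] = path
    return paths
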