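"""Genome-wide proximity placement analysis (GPPA).

Genes are associated to regulatory elements (e.g. functionally active hESC
enhancers) when they lie within a fixed genomic window — by default ±10 kb —
of the element.  Distance is the gap between the nearest interval boundaries,
zero for overlapping intervals, and the ``<= window`` comparison is
inclusive; chromosomes are isolated and strand is ignored.  The genes
associated with an element family form its "regulatory network", and gene
expression signatures are tested for enrichment within such networks by the
hypergeometric overlap test against a genome-wide gene count (default
63,677 — the annotation-wide background this analysis conventionally uses;
the background dominates these p values, so it is an explicit parameter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import binom

from .enrichment import EnrichmentResult, OverlapParams, hypergeom_overlap_test
from .io_formats import GenomicInterval, to_tss_intervals

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_GENOME_GENE_COUNT",
    "ProximityMap",
    "NetworkGeneSet",
    "associate_genes",
    "network_genes",
    "signature_network_enrichment",
    "placement_enrichment",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000
DEFAULT_GENOME_GENE_COUNT = 63_677

Anchor = Literal["gene-body", "tss"]


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Boundary gap in bp between two intervals; 0 if overlapping, None if on
    different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


@dataclass
class ProximityMap:
    """Element → associated genes (with boundary gaps), plus the parameters
    that produced the association."""

    associations: dict[str, dict[str, int]]
    window: int
    anchor: Anchor = "gene-body"

    def gene_ids(self) -> set[str]:
        out: set[str] = set()
        for genes in self.associations.values():
            out.update(genes)
        return out

    def n_pairs(self) -> int:
        return sum(len(g) for g in self.associations.values())

    def rows(self) -> list[tuple[str, str, int]]:
        """Flat (element_id, gene_id, gap_bp) rows, deterministically ordered."""
        return sorted(
            (e, g, gap)
            for e, genes in self.associations.items()
            for g, gap in genes.items()
        )


@dataclass
class NetworkGeneSet:
    """The de-duplicated union of genes associated with an element family."""

    name: str
    genes: set[str]
    window: int | None = None
    anchor: Anchor | None = None
    element_count: int | None = None

    def __len__(self) -> int:
        return len(self.genes)


def associate_genes(
    elements: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    window: int = DEFAULT_WINDOW,
    anchor: Anchor = "gene-body",
) -> ProximityMap:
    """Associate every gene within ``window`` bp of each element.

    ``anchor="gene-body"`` measures the gap to the whole gene interval;
    ``anchor="tss"`` collapses genes to strand-aware single-bp transcription
    start sites first.  The relation is symmetric in the two interval sets
    and empty inputs give an empty map.
    """
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    anchored = list(genes) if anchor == "gene-body" else to_tss_intervals(genes)
    trees: dict[str, IntervalTree] = {}
    by_key: dict[tuple[str, int, int], list[GenomicInterval]] = {}
    for g in anchored:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        by_key.setdefault((g.chrom, g.start, g.end), []).append(g)
    associations: dict[str, dict[str, int]] = {e.id: {} for e in elements}
    for elem in elements:
        tree = trees.get(elem.chrom)
        if tree is None:
            continue
        # envelope query, then exact gap filter (inclusive <= window)
        lo = max(0, elem.start - window - 1)
        hi = elem.end + window + 1
        for hit in tree.overlap(lo, hi):
            for gene in by_key[(elem.chrom, hit.begin, hit.end)]:
                gap = interval_gap(elem, gene)
                if gap is not None and gap <= window:
                    prev = associations[elem.id].get(gene.id)
                    if prev is None or gap < prev:
                        associations[elem.id][gene.id] = gap
    return ProximityMap(associations=associations, window=window, anchor=anchor)


def network_genes(
    *maps: ProximityMap, name: str = "network"
) -> NetworkGeneSet:
    """Union of associated genes across elements, and across maps when several
    maps (element families) are combined into one network."""
    if not maps:
        raise ValueError("at least one proximity map required")
    genes: set[str] = set()
    n_elements = 0
    for m in maps:
        genes |= m.gene_ids()
        n_elements += len(m.associations)
    first = maps[0]
    return NetworkGeneSet(
        name=name,
        genes=genes,
        window=first.window,
        anchor=first.anchor,
        element_count=n_elements,
    )


def signature_network_enrichment(
    signature: Iterable[str],
    network: NetworkGeneSet,
    genome_gene_count: int = DEFAULT_GENOME_GENE_COUNT,
) -> EnrichmentResult:
    """Hypergeometric enrichment of a gene expression signature within an
    element-family regulatory network.

    ``N = genome_gene_count``, ``K = |network|``, ``n = |signature|``,
    ``k = |signature ∩ network|``.
    """
    signature_set = set(signature)
    if genome_gene_count < len(network.genes) or genome_gene_count < len(signature_set):
        raise ValueError(
            "genome_gene_count smaller than the network or signature it backgrounds"
        )
    logger.info(
        "signature-network enrichment: background=%d network=%s (K=%d) signature n=%d",
        genome_gene_count,
        network.name,
        len(network.genes),
        len(signature_set),
    )
    params = OverlapParams(
        N=genome_gene_count,
        K=len(network.genes),
        n=len(signature_set),
        k=len(signature_set & network.genes),
    )
    return hypergeom_overlap_test(params, set_name=network.name)


# ---------------------------------------------------------------------------
# Placement (co-localization) enrichment of two interval sets
# ---------------------------------------------------------------------------


def _merged_coverage(intervals: list[tuple[int, int]], genome_length: int) -> int:
    """Total bp covered by the union of [start, end) intervals clipped to the
    genome."""
    clipped = sorted(
        (max(0, s), min(genome_length, e)) for s, e in intervals if e > 0 and s < genome_length
    )
    covered = 0
    cur_s, cur_e = None, None
    for s, e in clipped:
        if e <= s:
            continue
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def _count_hits(
    a_starts: np.ndarray, a_ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> int:
    """Number of A intervals overlapping at least one B interval (sorted sweep)."""
    order = np.argsort(b_starts)
    bs, be = b_starts[order], b_ends[order]
    # prefix max of ends lets a binary search decide overlap with any earlier B
    be_cummax = np.maximum.accumulate(be)
    idx = np.searchsorted(bs, a_ends, side="left")  # B's starting before a_end
    hits = 0
    for i, j in enumerate(idx):
        if j > 0 and be_cummax[j - 1] > a_starts[i]:
            hits += 1
    return hits


def placement_enrichment(
    feature_a: Sequence[GenomicInterval],
    feature_b: Sequence[GenomicInterval],
    genome_length: int,
    mode: Literal["analytic", "permutation"] = "analytic",
    window: int = 0,
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> tuple[int, float, float | None, float]:
    """Placement enrichment of feature A within ±``window`` of feature B,
    taking the bp size of the B regions into account.

    Returns ``(observed, expected, fold, p)`` where ``observed`` counts A
    elements within the window of some B element.

    analytic
        ``expected = |A| * (bp covered by B ± window, merged and clipped) /
        genome_length`` with a binomial upper-tail p — each A element is
        treated as a uniformly placed point.
    permutation
        B is re-placed uniformly (lengths preserved) ``n_shuffles`` times on
        the same chromosome namespace collapsed to one sequence; the
        empirical p is ``(1 + #{shuffles >= observed}) / (1 + n_shuffles)``.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    for iv in list(feature_a) + list(feature_b):
        if iv.end > genome_length:
            raise ValueError(f"interval {iv.id!r} extends past genome_length")
    if not feature_a or not feature_b:
        return 0, 0.0, None, 1.0
    # the ±window expansion is applied once, on the B side, for both the
    # observed count and the analytic coverage
    a_starts = np.array([iv.start for iv in feature_a])
    a_ends = np.array([iv.end for iv in feature_a])
    b_starts = np.array([max(0, iv.start - window) for iv in feature_b])
    b_lengths = np.array(
        [min(genome_length, iv.end + window) - max(0, iv.start - window) for iv in feature_b]
    )
    observed = _count_hits(a_starts, a_ends, b_starts, b_starts + b_lengths)

    frac = (
        _merged_coverage(
            [(iv.start - window, iv.end + window) for iv in feature_b], genome_length
        )
        / genome_length
    )
    expected = len(feature_a) * frac
    fold = observed / expected if expected > 0 else None

    if mode == "analytic":
        p = float(binom.sf(observed - 1, len(feature_a), frac)) if frac > 0 else 1.0
    elif mode == "permutation":
        if n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1 in permutation mode")
        rng = np.random.default_rng(seed)
        at_least = 0
        max_starts = genome_length - b_lengths
        if np.any(max_starts < 0):
            raise ValueError("a B interval is longer than the genome")
        for _ in range(n_shuffles):
            starts = rng.integers(0, max_starts + 1)
            count = _count_hits(a_starts, a_ends, starts, starts + b_lengths)
            if count >= observed:
                at_least += 1
        p = (1 + at_least) / (1 + n_shuffles)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return int(observed), float(expected), fold, float(p)
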