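"""Pipeline orchestration: simulate → classify → enrich, with provenance
headers and deterministic outputs under a fixed seed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import gene_set_enrichment
from .io_formats import write_gene_list
from .mlme import (
    MarkerPanelSet,
    MLMECriteria,
    calls_to_frame,
    classify_mlme,
    derive_deg_sets,
    expression_calls,
)
from .synthetic import SimulationConfig, generate_expression_matrix, generate_gene_set_library

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "provenance_header"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "enrich")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its input context."""


def provenance_header(stage: str, seed: int, params: dict) -> str:
    lines = [f"# scarskit {__version__}", f"# stage={stage}", f"# seed={seed}"]
    lines += [f"# {key}={value}" for key, value in sorted(params.items())]
    return "\n".join(lines) + "\n"


@dataclass
class PipelineConfig:
    """Stage selection, simulation conditions, classifier criteria and
    enrichment settings of one pipeline run."""

    outdir: Path
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    criteria: MLMECriteria = field(default_factory=MLMECriteria)
    alpha: float = 0.05
    adjust: str = "bh"
    n_library_sets: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        sim = SimulationConfig(**data.pop("simulation", {}))
        crit = MLMECriteria(**data.pop("criteria", {}))
        return cls(simulation=sim, criteria=crit, **data)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the selected stages, writing each stage's outputs under ``outdir``.

    Returns the mapping of output name to path.  Stage failures re-raise as
    :class:`PipelineError` naming the stage.
    """
    outputs: dict[str, Path] = {}
    config.outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "simulate":
                matrix, truth = generate_expression_matrix(sim)
                state["matrix"], state["truth"] = matrix, truth
                path = config.outdir / "expression.tsv"
                with open(path, "w") as handle:
                    handle.write(
                        provenance_header(
                            stage, sim.seed,
                            {"n_cells": sim.n_cells, "n_genes": sim.n_genes,
                             "n_mlme": sim.n_mlme, "marker_effect": sim.marker_effect,
                             "noise_sd": sim.noise_sd, "dropout_rate": sim.dropout_rate,
                             "background_on_fraction": sim.background_on_fraction},
                        )
                    )
                    matrix.to_frame().to_csv(
                        handle, sep="\t", index_label="gene_id", float_format="%.17g"
                    )
                outputs["expression"] = path

                panels = _panels_from_truth(truth)
                panels_path = config.outdir / "panels.yaml"
                panels.to_yaml(panels_path)
                outputs["panels"] = panels_path

                truth_path = config.outdir / "truth.tsv"
                with open(truth_path, "w") as handle:
                    handle.write(provenance_header(stage, sim.seed, {}))
                    handle.write("cell_id\trole\n")
                    for cell, role in truth.cell_roles.items():
                        handle.write(f"{cell}\t{role}\n")
                outputs["truth"] = truth_path
                state["panels"] = panels
            elif stage == "classify":
                matrix, panels = state["matrix"], state["panels"]
                calls = expression_calls(matrix)
                cell_calls = classify_mlme(calls, panels, config.criteria)
                state["cell_calls"] = cell_calls
                path = config.outdir / "calls.tsv"
                with open(path, "w") as handle:
                    handle.write(
                        provenance_header(
                            stage, config.seed,
                            {"min_epi": config.criteria.min_epi,
                             "min_te": config.criteria.min_te,
                             "min_pe": config.criteria.min_pe},
                        )
                    )
                    calls_to_frame(cell_calls).to_csv(handle, sep="\t", index=False)
                outputs["calls"] = path
            elif stage == "enrich":
                matrix, cell_calls = state["matrix"], state["cell_calls"]
                flags = [c.is_mlme for c in cell_calls]
                up, down = derive_deg_sets(matrix, flags, alpha=config.alpha,
                                           fdr_method=config.adjust)
                up_path = config.outdir / "deg_up.txt"
                write_gene_list(sorted(up), up_path)
                down_path = config.outdir / "deg_down.txt"
                write_gene_list(sorted(down), down_path)
                outputs["deg_up"], outputs["deg_down"] = up_path, down_path

                truth = state["truth"]
                markers = sorted(g for g, p in truth.gene_panels.items())
                library, _ = generate_gene_set_library(
                    universe=matrix.gene_ids,
                    n_sets=config.n_library_sets,
                    set_size_range=(20, 60),
                    target_set=markers,
                    enriched_set_count=max(1, config.n_library_sets // 10),
                    enrichment_odds=10.0,
                    seed=config.seed,
                )
                results = gene_set_enrichment(
                    sorted(up) if up else markers, library, matrix.gene_ids,
                    adjust=config.adjust,
                )
                path = config.outdir / "enrichment.tsv"
                with open(path, "w") as handle:
                    handle.write(
                        provenance_header(stage, config.seed, {"adjust": config.adjust})
                    )
                    handle.write(
                        "set\tN\tK\tn\tk\texpected\toe_ratio\tp\tp_adjusted\tcombined_score\n"
                    )
                    for r in results:
                        oe = f"{r.oe_ratio:.6g}" if r.oe_ratio is not None else "NA"
                        c = f"{r.combined:.6g}" if r.combined is not None else "NA"
                        handle.write(
                            f"{r.set_name}\t{r.params.N}\t{r.params.K}\t{r.params.n}"
                            f"\t{r.params.k}\t{r.expected:.6g}\t{oe}\t{r.p:.6g}"
                            f"\t{r.p_adjusted:.6g}\t{c}\n"
                        )
                outputs["enrichment"] = path
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s complete", stage)
    return outputs


def _panels_from_truth(truth) -> MarkerPanelSet:
    by_panel: dict[str, list[str]] = {}
    for gene, panel in truth.gene_panels.items():
        by_panel.setdefault(panel, []).append(gene)
    return MarkerPanelSet(
        sorted(by_panel.get("EPI", [])),
        sorted(by_panel.get("TE", [])),
        sorted(by_panel.get("PE", [])),
    )
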