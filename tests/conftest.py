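import numpy as np
import pytest

from scarskit.mlme import MarkerPanelSet, classify_mlme, expression_calls
from scarskit.synthetic import SimulationConfig, generate_expression_matrix


def panels_from_truth(truth) -> MarkerPanelSet:
    by_panel: dict[str, list[str]] = {}
    for gene, panel in truth.gene_panels.items():
        by_panel.setdefault(panel, []).append(gene)
    return MarkerPanelSet(
        sorted(by_panel["EPI"]), sorted(by_panel["TE"]), sorted(by_panel["PE"])
    )


def mlme_recovery(config: SimulationConfig) -> tuple[float, float]:
    """(sensitivity, precision) of MLME recovery on one generated cohort."""
    matrix, truth = generate_expression_matrix(config)
    calls = classify_mlme(expression_calls(matrix), panels_from_truth(truth))
    predicted = {c.cell_id for c in calls if c.is_mlme}
    planted = truth.cells_with_role("MLME")
    tp = len(predicted & planted)
    sensitivity = tp / len(planted) if planted else 1.0
    precision = tp / len(predicted) if predicted else 1.0
    return sensitivity, precision


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at generator defaults, shared across read-only tests."""
    config = SimulationConfig(seed=11)
    matrix, truth = generate_expression_matrix(config)
    return config, matrix, truth
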