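"""MLME classifier: median-exceedance calls, criterion conjunction,
invariances, planted-cohort recovery and DEG derivation."""

import numpy as np
import pytest

from scarskit.io_formats import ExpressionMatrix
from scarskit.mlme import (
    MarkerPanelSet,
    MLMECriteria,
    classify_mlme,
    derive_deg_sets,
    expression_calls,
)
from scarskit.synthetic import SimulationConfig, generate_expression_matrix

from conftest import mlme_recovery, panels_from_truth


def tiny_panels() -> MarkerPanelSet:
    return MarkerPanelSet(
        epi_markers=[f"E{i}" for i in range(8)],
        te_markers=[f"T{i}" for i in range(9)],
        pe_markers=[f"P{i}" for i in range(6)],
    )


def matrix_for_cells(panels: MarkerPanelSet, expressed_by_cell: list[set[str]]):
    """Two-level matrix: listed genes get value 2, others 0; a final all-zero
    reference cell keeps every gene's median at 0 for the expressing cells."""
    genes = panels.all_genes()
    n_cells = len(expressed_by_cell)
    values = np.zeros((len(genes), n_cells + n_cells))  # pad with zero cells
    for j, expressed in enumerate(expressed_by_cell):
        for i, g in enumerate(genes):
            if g in expressed:
                values[i, j] = 2.0
    cells = [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, cells, values)


class TestExpressionCalls:
    def test_strict_exceedance_of_median(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"], [[1.0, 2.0, 3.0]])
        calls = expression_calls(m)
        assert list(calls.loc["g"]) == [False, False, True]

    def test_all_equal_values_are_never_expressed(self):
        m = ExpressionMatrix(["g"], list("abcd"), [[5.0] * 4])
        assert not expression_calls(m).loc["g"].any()

    def test_even_count_midpoint_median(self):
        m = ExpressionMatrix(["g"], list("abcd"), [[1.0, 2.0, 3.0, 4.0]])
        # median 2.5: only the 3 and 4 exceed it
        assert list(expression_calls(m).loc["g"]) == [False, False, True, True]

    def test_single_cell_rejected(self):
        m = ExpressionMatrix(["g"], ["a"], [[1.0]])
        with pytest.raises(ValueError):
            expression_calls(m)

    def test_noiseless_planted_calls_match_truth(self):
        config = SimulationConfig(
            n_cells=200, n_genes=400, n_mlme=30, noise_sd=0.0, dropout_rate=0.0,
            marker_effect=5.0, background_on_fraction=0.0, seed=3,
        )
        matrix, truth = generate_expression_matrix(config)
        calls = expression_calls(matrix)
        planted = truth.cells_with_role("MLME")
        # calls are exactly the planted signal entries: true only in MLME cells
        assert set(calls.columns[calls.loc["TERT"]]) == planted
        assert not calls.loc[:, ~calls.columns.isin(planted)].any().any()


class TestClassify:
    def test_boundary_cell_at_exact_thresholds_is_mlme(self):
        panels = tiny_panels()
        expressed = (
            set(panels.epi_markers[:6]) | set(panels.te_markers[:7])
            | set(panels.pe_markers[:4]) | set(panels.pluripotency_trio)
            | {panels.telomerase_gene}
        )
        calls = classify_mlme(expression_calls(matrix_for_cells(panels, [expressed])), panels)
        assert calls[0].is_mlme

    def test_one_marker_short_fails(self):
        panels = tiny_panels()
        expressed = (
            set(panels.epi_markers[:6]) | set(panels.te_markers[:6])  # TE below 7
            | set(panels.pe_markers[:4]) | set(panels.pluripotency_trio)
            | {panels.telomerase_gene}
        )
        calls = classify_mlme(expression_calls(matrix_for_cells(panels, [expressed])), panels)
        assert calls[0].te_count == 6 and not calls[0].is_mlme

    def test_missing_trio_gene_fails_gate(self):
        panels = tiny_panels()
        expressed = (
            set(panels.epi_markers[:6]) | set(panels.te_markers[:7])
            | set(panels.pe_markers[:4]) | {"NANOG", "SOX2", panels.telomerase_gene}
        )
        calls = classify_mlme(expression_calls(matrix_for_cells(panels, [expressed])), panels)
        assert not calls[0].trio_ok and not calls[0].is_mlme

    def test_monotone_in_added_markers(self):
        """Expressing one more marker never flips an MLME call to false."""
        panels = tiny_panels()
        base = (
            set(panels.epi_markers[:6]) | set(panels.te_markers[:7])
            | set(panels.pe_markers[:4]) | set(panels.pluripotency_trio)
            | {panels.telomerase_gene}
        )
        assert classify_mlme(
            expression_calls(matrix_for_cells(panels, [base])), panels
        )[0].is_mlme
        for extra in set(panels.all_genes()) - base:
            calls = classify_mlme(
                expression_calls(matrix_for_cells(panels, [base | {extra}])), panels
            )
            assert calls[0].is_mlme

    def test_permutation_invariance(self, default_cohort):
        _, matrix, truth = default_cohort
        panels = panels_from_truth(truth)
        rng = np.random.default_rng(0)
        gene_perm = rng.permutation(matrix.n_genes)
        cell_perm = rng.permutation(matrix.n_cells)
        shuffled = ExpressionMatrix(
            [matrix.gene_ids[i] for i in gene_perm],
            [matrix.cell_ids[j] for j in cell_perm],
            matrix.values[np.ix_(gene_perm, cell_perm)],
        )
        orig = {c.cell_id: c.is_mlme for c in classify_mlme(expression_calls(matrix), panels)}
        perm = {c.cell_id: c.is_mlme for c in classify_mlme(expression_calls(shuffled), panels)}
        assert orig == perm

    def test_missing_panel_gene_listed(self, default_cohort):
        _, matrix, truth = default_cohort
        panels = panels_from_truth(truth)
        calls = expression_calls(matrix).drop(index=panels.epi_markers[0])
        with pytest.raises(ValueError, match=panels.epi_markers[0]):
            classify_mlme(calls, panels)

    def test_criteria_exceeding_panel_size_rejected(self):
        panels = tiny_panels()
        with pytest.raises(ValueError):
            classify_mlme(
                expression_calls(matrix_for_cells(panels, [set()])),
                panels,
                MLMECriteria(min_epi=9),
            )


class TestRecovery:
    def test_noiseless_recovery_is_exact(self):
        config = SimulationConfig(
            noise_sd=0.0, dropout_rate=0.0, marker_effect=5.0,
            background_on_fraction=0.0, seed=1,
        )
        sensitivity, precision = mlme_recovery(config)
        assert sensitivity == 1.0 and precision == 1.0

    def test_default_conditions_recovery(self):
        """Mean sensitivity and precision >= 0.95 over 10 seeded cohorts at
        the generator's default noise, dropout and effect size."""
        scores = [mlme_recovery(SimulationConfig(seed=s)) for s in range(1, 11)]
        sens = np.mean([s for s, _ in scores])
        prec = np.mean([p for _, p in scores])
        assert sens >= 0.95 and prec >= 0.95


class TestPanels:
    def test_oct4_alias_resolves_to_pou5f1(self):
        panels = MarkerPanelSet(["E1"], ["T1"], ["P1"],
                                pluripotency_trio=("OCT4", "NANOG", "SOX2"))
        assert set(panels.pluripotency_trio) == {"POU5F1", "NANOG", "SOX2"}

    def test_panel_overlap_rejected(self):
        with pytest.raises(ValueError):
            MarkerPanelSet(["shared"], ["shared"], ["P1"])

    def test_trio_must_have_three_members(self):
        with pytest.raises(ValueError):
            MarkerPanelSet(["E1"], ["T1"], ["P1"],
                           pluripotency_trio=("NANOG", "NANOG", "SOX2"))


class TestDegSets:
    @pytest.mark.parametrize("seed", [2, 3])
    def test_planted_markers_all_up(self, seed):
        config = SimulationConfig(
            n_cells=1000, n_genes=600, n_mlme=135, marker_effect=5.0,
            noise_sd=0.5, seed=seed,
        )
        matrix, truth = generate_expression_matrix(config)
        flags = [truth.cell_roles[c] == "MLME" for c in matrix.cell_ids]
        up, down = derive_deg_sets(matrix, flags)
        planted_genes = set(truth.gene_panels)
        assert planted_genes <= up
        assert not planted_genes & down

    def test_permuted_labels_control_type_one_error(self):
        """With labels shuffled, nominal rank-sum p < alpha at roughly the
        alpha rate, and the BH-adjusted sets stay (near-)empty."""
        from scipy.stats import mannwhitneyu

        config = SimulationConfig(n_cells=400, n_genes=800, n_mlme=60, seed=5)
        matrix, _ = generate_expression_matrix(config)
        rng = np.random.default_rng(5)
        flags = np.zeros(matrix.n_cells, dtype=bool)
        flags[rng.choice(matrix.n_cells, 60, replace=False)] = True
        p = mannwhitneyu(
            matrix.values[:, flags], matrix.values[:, ~flags], axis=1
        ).pvalue
        p[~np.isfinite(p)] = 1.0
        nominal_rate = float(np.mean(p < 0.05))
        assert nominal_rate < 0.09  # at or below alpha, allowing sampling noise
        up, down = derive_deg_sets(matrix, flags)
        assert len(up) + len(down) <= 5

    def test_identical_groups_yield_empty_sets(self):
        rng = np.random.default_rng(1)
        block = rng.random((50, 20))
        matrix = ExpressionMatrix(
            [f"g{i}" for i in range(50)],
            [f"c{j}" for j in range(40)],
            np.hstack([block, block]),
        )
        flags = [True] * 20 + [False] * 20
        up, down = derive_deg_sets(matrix, flags)
        assert up == set() and down == set()

    def test_tiny_group_rejected(self, default_cohort):
        _, matrix, _ = default_cohort
        flags = [True] + [False] * (matrix.n_cells - 1)
        with pytest.raises(ValueError):
            derive_deg_sets(matrix, flags)
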