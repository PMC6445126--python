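import numpy as np
import pandas as pd
import pytest

from sfcomod.io import ExpressionMatrix, ValidationError
from sfcomod.isoforms import (
    IsoformTable,
    detect_switch_genes,
    isoform_fraction_histogram,
    isoform_length_compare,
    isoform_module_clusters,
)
from sfcomod.modules import ClusterAssignment


def _iso_table(rows: dict[str, list[float]], gene_map=None, lengths=None) -> IsoformTable:
    df = pd.DataFrame(rows, dtype=float).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    gene_map = gene_map or {i: i.rsplit(".", 1)[0] for i in rows}
    lengths = lengths or {i: 1000 for i in rows}
    return IsoformTable(ExpressionMatrix(df), gene_map, lengths)


class TestDetectSwitchGenes:
    def test_perfect_switch_selected(self):
        iso = _iso_table({"g.1": [1, 2, 3, 4], "g.2": [4, 3, 2, 1]})
        res = detect_switch_genes(iso, pc_threshold=-0.01)
        assert res.genes == ["g"]
        assert res.best_pair["g"][2] == pytest.approx(-1.0)

    def test_parallel_isoforms_not_selected(self):
        iso = _iso_table({"g.1": [1, 2, 3, 4], "g.2": [3, 4, 5, 6]})
        res = detect_switch_genes(iso)
        assert res.genes == []

    def test_low_expression_isoforms_dropped(self):
        iso = _iso_table({"g.1": [1, 2, 3, 4], "g.2": [0.1, 0.075, 0.05, 0.025]})
        res = detect_switch_genes(iso, min_expression=1.0)
        assert res.genes == []  # only one expressed isoform remains

    def test_most_negative_pair_rule_with_three_isoforms(self):
        iso = _iso_table(
            {"g.1": [1, 2, 3, 4], "g.2": [1.1, 2, 3.1, 4], "g.3": [4, 3, 2, 1]}
        )
        res = detect_switch_genes(iso, pc_threshold=-0.5)
        assert res.genes == ["g"]
        a, b, pc = res.best_pair["g"]
        assert {a, b} <= {"g.1", "g.2", "g.3"}
        assert pc == pytest.approx(-1.0, abs=1e-6)

    def test_invariant_to_row_and_sample_order(self, small_cohort):
        iso = IsoformTable(
            small_cohort.isoforms,
            small_cohort.isoform_gene_map,
            small_cohort.isoform_lengths,
        )
        base = detect_switch_genes(iso)
        shuffled_rows = small_cohort.isoforms.data.iloc[::-1]
        shuffled = IsoformTable(
            ExpressionMatrix(shuffled_rows[shuffled_rows.columns[::-1]]),
            small_cohort.isoform_gene_map,
            small_cohort.isoform_lengths,
        )
        assert detect_switch_genes(shuffled).genes == base.genes

    def test_positive_threshold_rejected(self):
        iso = _iso_table({"g.1": [1, 2, 3], "g.2": [3, 2, 1]})
        with pytest.raises(ValidationError, match="negative"):
            detect_switch_genes(iso, pc_threshold=0.1)


class TestIsoformModuleClusters:
    def test_switch_pair_lands_in_different_clusters(self, small_cohort):
        iso = IsoformTable(
            small_cohort.isoforms,
            small_cohort.isoform_gene_map,
            small_cohort.isoform_lengths,
        )
        switch = detect_switch_genes(iso)
        modules = {
            "Enhancer": small_cohort.truth.module_genes("enhancer"),
            "Suppressor": small_cohort.truth.module_genes("suppressor"),
        }
        assignment, in_both, frac = isoform_module_clusters(
            iso, switch, small_cohort.expression, modules
        )
        assert assignment.k == 2
        detected_true = set(switch.genes) & set(small_cohort.truth.switch_genes)
        assert len(set(in_both) & detected_true) / len(detected_true) >= 0.8

    def test_duplicated_isoform_rows_same_cluster(self, small_cohort):
        iso_data = small_cohort.isoforms.data
        g = small_cohort.truth.switch_genes[0]
        dup = iso_data.loc[[f"{g}.1"]].rename(index={f"{g}.1": "dup.1"})
        combined = ExpressionMatrix(pd.concat([iso_data, dup]))
        gene_map = dict(small_cohort.isoform_gene_map, **{"dup.1": "dup"})
        lengths = dict(small_cohort.isoform_lengths, **{"dup.1": 1000})
        iso = IsoformTable(combined, gene_map, lengths)
        switch = detect_switch_genes(iso)
        switch.selected_isoforms = sorted(set(switch.selected_isoforms) | {f"{g}.1", "dup.1"})
        modules = {
            "Enhancer": small_cohort.truth.module_genes("enhancer"),
            "Suppressor": small_cohort.truth.module_genes("suppressor"),
        }
        assignment, _, _ = isoform_module_clusters(
            iso, switch, small_cohort.expression, modules
        )
        assert assignment.labels[f"{g}.1"] == assignment.labels["dup.1"]

    def test_too_few_isoforms_rejected(self, small_cohort):
        iso = IsoformTable(
            small_cohort.isoforms,
            small_cohort.isoform_gene_map,
            small_cohort.isoform_lengths,
        )
        from sfcomod.isoforms import SwitchGeneSet

        empty = SwitchGeneSet(genes=[], best_pair={}, selected_isoforms=[])
        with pytest.raises(ValidationError, match=">= 2"):
            isoform_module_clusters(iso, empty, small_cohort.expression, {"m": ["SF0001"]})


class TestIsoformLengthCompare:
    def _assignment(self, labels: dict[str, int]) -> ClusterAssignment:
        return ClusterAssignment(labels, k=2)

    def test_similar_lengths_high_p(self):
        iso = _iso_table(
            {f"g{i}.1": [1, 2, 3] for i in range(6)},
            lengths={"g0.1": 100, "g1.1": 110, "g2.1": 120, "g3.1": 100, "g4.1": 110, "g5.1": 121},
        )
        assignment = self._assignment(
            {"g0.1": 1, "g1.1": 1, "g2.1": 1, "g3.1": 2, "g4.1": 2, "g5.1": 2}
        )
        res = isoform_length_compare(assignment, iso)
        assert res["p_value"] > 0.9

    def test_degenerate_zero_variance_rejected(self):
        iso = _iso_table(
            {f"g{i}.1": [1, 2, 3] for i in range(4)},
            lengths={"g0.1": 100, "g1.1": 100, "g2.1": 200, "g3.1": 200},
        )
        assignment = self._assignment({"g0.1": 1, "g1.1": 1, "g2.1": 2, "g3.1": 2})
        with pytest.raises(ValidationError, match="zero pooled variance"):
            isoform_length_compare(assignment, iso)

    def test_tiny_cluster_rejected(self):
        iso = _iso_table({f"g{i}.1": [1, 2, 3] for i in range(3)})
        assignment = self._assignment({"g0.1": 1, "g1.1": 1, "g2.1": 2})
        with pytest.raises(ValidationError, match="fewer than 2"):
            isoform_length_compare(assignment, iso)


def test_fraction_histogram_bimodal_for_switch_genes(small_cohort):
    iso = IsoformTable(
        small_cohort.isoforms, small_cohort.isoform_gene_map, small_cohort.isoform_lengths
    )
    hist = isoform_fraction_histogram(iso, small_cohort.truth.switch_genes, bins=10)
    counts = hist.drop(columns="gene_id").to_numpy(dtype=float)
    tails = counts[:, [0, -1]].sum()
    middle = counts[:, 4:6].sum()
    assert tails > middle  # mutually exclusive usage: mass at the extremes
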