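import numpy as np
import pandas as pd
import pytest

from sfcomod.io import ValidationError
from sfcomod.synthetic import (
    SyntheticConfig,
    creb_like_pwm,
    generate_cohort,
    generate_promoters,
    generate_validation_cohort,
)


def _small_cfg(**overrides):
    base = dict(
        n_samples=100,
        panel_size=40,
        n_suppressor=12,
        n_enhancer=8,
        n_background=50,
        n_null_background=20,
        n_matched_pairs=20,
        n_switch_genes=5,
        n_nonswitch_genes=5,
        seed=1,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        c1 = generate_cohort(_small_cfg())
        c2 = generate_cohort(_small_cfg())
        pd.testing.assert_frame_equal(c1.expression.data, c2.expression.data)
        pd.testing.assert_frame_equal(c1.survival.data, c2.survival.data)
        pd.testing.assert_frame_equal(c1.isoforms.data, c2.isoforms.data)
        assert c1.truth.de_genes == c2.truth.de_genes

    def test_seed_changes_values_not_structure(self):
        c1 = generate_cohort(_small_cfg(seed=1))
        c2 = generate_cohort(_small_cfg(seed=2))
        assert c1.expression.gene_ids == c2.expression.gene_ids
        assert not np.allclose(c1.expression.data.to_numpy(), c2.expression.data.to_numpy())


class TestCorrelationStructure:
    def test_independence_limit_beta_zero(self):
        cfg = _small_cfg(n_samples=500, beta=0.0, panel_loading_sd=0.0, seed=5)
        cohort = generate_cohort(cfg)
        sub = cohort.expression.data.loc[cohort.truth.panel_genes]
        C = np.corrcoef(sub.to_numpy())
        off = ~np.eye(C.shape[0], dtype=bool)
        assert np.abs(C[off]).mean() < 0.05

    def test_closed_form_module_correlation(self):
        # beta=1, sigma=1 -> expected within-module r = 1/2, cross-module -1/2
        cfg = _small_cfg(n_samples=2000, n_suppressor=15, n_enhancer=10, seed=7)
        cohort = generate_cohort(cfg)
        supp = cohort.truth.module_genes("suppressor")
        enh = cohort.truth.module_genes("enhancer")
        data = cohort.expression.data
        C = np.corrcoef(data.loc[supp + enh].to_numpy())
        ns = len(supp)
        within = np.concatenate(
            [C[:ns, :ns][~np.eye(ns, dtype=bool)], C[ns:, ns:][~np.eye(len(enh), dtype=bool)]]
        )
        cross = C[:ns, ns:].ravel()
        assert within.mean() == pytest.approx(0.5, abs=0.05)
        assert cross.mean() == pytest.approx(-0.5, abs=0.05)


class TestValidationCohort:
    def test_drop_zero_keeps_gene_set(self):
        cohort = generate_cohort(_small_cfg())
        val = generate_validation_cohort(cohort.truth, n_drop=0)
        assert val.expression.gene_ids == cohort.expression.gene_ids

    def test_default_drop_leaves_235_of_244(self):
        cfg = SyntheticConfig(
            n_samples=50, n_matched_pairs=10, n_background=10, n_null_background=0,
            n_switch_genes=2, n_nonswitch_genes=2, seed=3,
        )
        cohort = generate_cohort(cfg)
        val = generate_validation_cohort(cohort.truth, n_drop=9)
        panel_left = [g for g in val.expression.gene_ids if g.startswith("SF")]
        assert len(panel_left) == 235
        assert set(val.truth.module_genes("enhancer")) <= set(
            cohort.truth.module_genes("enhancer")
        )

    def test_seed_change_same_genes_new_values(self):
        cohort = generate_cohort(_small_cfg())
        v1 = generate_validation_cohort(cohort.truth, n_drop=0, seed=10)
        v2 = generate_validation_cohort(cohort.truth, n_drop=0, seed=11)
        assert v1.expression.gene_ids == v2.expression.gene_ids
        assert not np.allclose(v1.expression.data.to_numpy(), v2.expression.data.to_numpy())

    def test_excessive_drop_rejected(self):
        cohort = generate_cohort(_small_cfg())
        with pytest.raises(ValidationError, match="n_drop"):
            generate_validation_cohort(cohort.truth, n_drop=8)


class TestIsoformStructure:
    def test_switch_pairs_anticorrelated_nonswitch_centered(self):
        cohort = generate_cohort(_small_cfg(n_samples=400, seed=9))
        iso = cohort.isoforms.data
        switch_r = [
            np.corrcoef(iso.loc[f"{g}.1"], iso.loc[f"{g}.2"])[0, 1]
            for g in cohort.truth.switch_genes
        ]
        nonswitch_r = [
            np.corrcoef(iso.loc[f"{g}.1"], iso.loc[f"{g}.2"])[0, 1]
            for g in cohort.truth.nonswitch_genes
        ]
        assert np.mean(switch_r) < -0.3
        assert abs(np.mean(nonswitch_r)) < 0.2


class TestPairedDesignStructure:
    def test_pair_differences_carry_planted_offset(self):
        cfg = _small_cfg(de_offset=1.0, de_fraction=0.2, seed=11)
        cohort = generate_cohort(cfg)
        tumor = cohort.expression.data[cohort.pair_design["tumor_sample"]]
        normal = cohort.normal_expression.data[cohort.pair_design["normal_sample"]]
        diffs = tumor.to_numpy() - normal.to_numpy()
        genes = cohort.expression.gene_ids
        de_idx = [i for i, g in enumerate(genes) if g in set(cohort.truth.de_genes)]
        null_idx = [i for i, g in enumerate(genes) if g not in set(cohort.truth.de_genes)]
        assert diffs[de_idx].mean() == pytest.approx(1.0, abs=0.15)
        assert diffs[null_idx].mean() == pytest.approx(0.0, abs=0.1)


class TestPromoters:
    def test_zero_rates_plant_nothing(self):
        cfg = _small_cfg(motif_plant_rate_fg=0.0, motif_plant_rate_bg=0.0)
        prom, plants = generate_promoters(cfg, creb_like_pwm(), ["f1", "f2"], ["b1", "b2"])
        assert all(pos is None for pos in plants.values())

    def test_rate_one_plants_consensus_at_recorded_position(self):
        cfg = _small_cfg(motif_plant_rate_fg=1.0)
        motif = creb_like_pwm()
        prom, plants = generate_promoters(cfg, motif, ["f1", "f2", "f3"], ["b1"] * 0 + ["b1"])
        consensus = motif.consensus()
        for gene in ("f1", "f2", "f3"):
            pos = plants[gene]
            assert pos is not None
            window = prom.window_slice(gene, pos, pos + motif.width - 1)
            assert window == consensus

    def test_window_exceeding_promoter_rejected(self):
        cfg = _small_cfg(promoter_length=100)
        with pytest.raises(ValidationError, match="window"):
            generate_promoters(cfg, creb_like_pwm(), ["f"], ["b"], window=(-50, 450))


class TestConfigValidation:
    def test_module_overflow_rejected(self):
        with pytest.raises(ValidationError, match="panel_size"):
            SyntheticConfig(panel_size=50, n_suppressor=40, n_enhancer=20)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValidationError, match="probabilities"):
            SyntheticConfig(motif_plant_rate_fg=1.5)
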