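"""Planted-truth recovery experiments on synthetic cohorts.

Each function runs one stage of the analysis on freshly generated synthetic
cohorts and scores the result against the generator's ground truth:
consensus-module recovery (Adjusted Rand Index and role labels), paired-DE
calibration and power, survival effect detection and null calibration,
isoform-switch detection, ranking/enrichment recovery, and promoter-motif
enrichment.  These are the quantities the package's acceptance checks and
reproduction script compute.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .correlation import pearson_cross, pearson_matrix
from .enrichment import gsea_preranked, ora_hypergeometric, rank_genes
from .io import ExpressionMatrix
from .isoforms import IsoformTable, detect_switch_genes, isoform_module_clusters
from .modules import (
    cluster_correlation_rows,
    consensus_overlap,
    label_modules,
    stability_select_k,
)
from .motifs import motif_z_enrichment
from .paired import PairedDesign, paired_log2fc
from .survival import logrank_km, median_split, module_score
from .synthetic import (
    SyntheticConfig,
    creb_like_pwm,
    decoy_pwm,
    generate_cohort,
    generate_promoters,
    generate_validation_cohort,
    planted_gene_sets,
)

# panel-only configuration used for the module-recovery design: two cohorts
# of 300 tumors, the 244-gene panel with 61 + 24 planted module genes
MODULE_RECOVERY_CONFIG = dict(
    n_samples=300,
    n_background=0,
    n_null_background=0,
    n_matched_pairs=10,
    n_switch_genes=5,
    n_nonswitch_genes=5,
)


def recover_modules_once(seed: int, k_min: int = 2, k_max: int = 6, n_remove: int = 30) -> dict:
    """Two-cohort discovery -> consensus -> labels for one seed.

    Returns the chosen k, the ARI between recovered role labels (Enhancer /
    Suppressor / none) and the planted module labels over panel genes, and
    whether the Enhancer label landed on the planted enhancer module.
    """
    cfg = SyntheticConfig(**MODULE_RECOVERY_CONFIG, seed=seed)
    a = generate_cohort(cfg)
    b = generate_validation_cohort(a.truth, cfg, n_drop=0)
    report, assigns = stability_select_k(
        a.expression, a.truth.panel_genes, k_min, k_max, n_remove=n_remove, seed=seed
    )
    C_b = pearson_matrix(b.expression, b.truth.panel_genes)
    assign_b = cluster_correlation_rows(C_b, report.chosen_k)
    consensus = consensus_overlap(assigns[report.chosen_k], assign_b)
    consensus = label_modules(consensus, a.expression, a.survival)
    role_of: dict[str, str] = {}
    for name, genes in consensus.modules.items():
        if name in consensus.roles:
            for g in genes:
                role_of[g] = consensus.roles[name]
    truth_labels = [a.truth.module[g] for g in a.truth.panel_genes]
    recovered = [role_of.get(g, "none") for g in a.truth.panel_genes]
    ari = float(adjusted_rand_score(truth_labels, recovered))
    enh_recovered = {g for g, r in role_of.items() if r == "Enhancer"}
    labels_correct = enh_recovered == set(a.truth.module_genes("enhancer"))
    # does the chosen cut isolate both planted modules in the discovery cohort?
    clusters = assigns[report.chosen_k].clusters()
    supp, enh = set(a.truth.module_genes("suppressor")), set(a.truth.module_genes("enhancer"))
    isolated = any(c == supp for c in clusters) and any(c == enh for c in clusters)
    return {
        "chosen_k": report.chosen_k,
        "ari": ari,
        "labels_correct": bool(labels_correct),
        "modules_isolated": bool(isolated),
        "n_suppressor_recovered": len({g for g, r in role_of.items() if r == "Suppressor"}),
        "n_enhancer_recovered": len(enh_recovered),
    }


def module_recovery_experiment(seeds: Sequence[int], **kwargs) -> dict:
    runs = [recover_modules_once(s, **kwargs) for s in seeds]
    return {
        "runs": runs,
        "mean_ari": float(np.mean([r["ari"] for r in runs])),
        "n_pass": int(sum(r["ari"] >= 0.9 and r["labels_correct"] for r in runs)),
        "n_isolated": int(sum(r["modules_isolated"] for r in runs)),
        "n_seeds": len(runs),
    }


# ---------------------------------------------------------------------------
# Paired differential expression
# ---------------------------------------------------------------------------

def _paired_cohort(seed: int, de_offset: float, n_genes: int = 1000, n_pairs: int = 114):
    cfg = SyntheticConfig(
        n_samples=n_pairs,
        panel_size=n_genes,
        n_suppressor=61,
        n_enhancer=24,
        n_background=0,
        n_null_background=0,
        n_matched_pairs=n_pairs,
        de_offset=de_offset,
        de_fraction=0.1,
        n_switch_genes=3,
        n_nonswitch_genes=3,
        seed=seed,
    )
    cohort = generate_cohort(cfg)
    X = ExpressionMatrix(
        pd.concat([cohort.expression.data, cohort.normal_expression.data], axis=1)
    )
    design = PairedDesign(
        cohort.pair_design.rename(
            columns={"normal_sample": "sample_condition1", "tumor_sample": "sample_condition2"}
        ),
        condition_names=("normal", "tumor"),
    )
    return cohort, X, design


def paired_de_null_calibration(seed: int, n_genes: int = 1000, n_pairs: int = 114) -> dict:
    """Null design (no planted shift): raw-p and BH-q exceedance fractions."""
    cohort, X, design = _paired_cohort(seed, de_offset=0.0, n_genes=n_genes, n_pairs=n_pairs)
    de = paired_log2fc(X, design, cohort.truth.panel_genes)
    return {
        "frac_p_below_05": float((de["p_value"] < 0.05).mean()),
        "frac_q_below_05": float((de["q_value"] < 0.05).mean()),
        "n_genes": len(de),
    }


def paired_de_power(seeds: Sequence[int], n_genes: int = 1000, n_pairs: int = 114) -> dict:
    """Signal design (offset 1 on 10% of genes): sensitivity and FDP at q < 0.05."""
    sens, fdp = [], []
    for seed in seeds:
        cohort, X, design = _paired_cohort(seed, de_offset=1.0, n_genes=n_genes, n_pairs=n_pairs)
        de = paired_log2fc(X, design, cohort.truth.panel_genes).set_index("gene_id")
        de_truth = set(cohort.truth.de_genes)
        called = set(de.index[de["q_value"] < 0.05])
        sens.append(len(called & de_truth) / len(de_truth))
        fdp.append(len(called - de_truth) / len(called) if called else 0.0)
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "n_seeds": len(list(seeds)),
    }


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def survival_effect_experiment(seeds: Sequence[int], n_samples: int = 400) -> dict:
    """Median split on the planted enhancer module score at gamma = 0.5."""
    hits = 0
    hrs, ps = [], []
    for seed in seeds:
        cfg = SyntheticConfig(
            n_samples=n_samples,
            panel_size=85,
            n_suppressor=61,
            n_enhancer=24,
            n_background=0,
            n_null_background=0,
            n_matched_pairs=5,
            n_switch_genes=3,
            n_nonswitch_genes=3,
            gamma=0.5,
            seed=seed,
        )
        cohort = generate_cohort(cfg)
        score = module_score(cohort.expression, cohort.truth.module_genes("enhancer"))
        km = logrank_km(cohort.survival, median_split(score))
        hrs.append(km.hazard_ratio)
        ps.append(km.p_value)
        hits += km.hazard_ratio > 1 and km.p_value < 0.01
    return {
        "n_detected": int(hits),
        "n_seeds": len(list(seeds)),
        "median_hr": float(np.median(hrs)),
        "median_p": float(np.median(ps)),
    }


def logrank_null_pvalues(n_seeds: int = 200, n_samples: int = 60, base_seed: int = 0) -> np.ndarray:
    """Log-rank p-values under gamma = 0 (scaled-down cohorts); should be uniform."""
    ps = []
    for seed in range(base_seed, base_seed + n_seeds):
        cfg = SyntheticConfig(
            n_samples=n_samples,
            panel_size=20,
            n_suppressor=8,
            n_enhancer=6,
            n_background=0,
            n_null_background=0,
            n_matched_pairs=3,
            n_switch_genes=2,
            n_nonswitch_genes=2,
            gamma=0.0,
            seed=seed,
        )
        cohort = generate_cohort(cfg)
        score = module_score(cohort.expression, cohort.truth.module_genes("enhancer"))
        km = logrank_km(cohort.survival, median_split(score))
        ps.append(km.p_value)
    return np.asarray(ps)


# ---------------------------------------------------------------------------
# Isoform switching
# ---------------------------------------------------------------------------

def isoform_switch_experiment(seeds: Sequence[int], n_samples: int = 300) -> dict:
    """Switch detection sensitivity/FPR and the both-cluster fraction."""
    sens, fpr, both = [], [], []
    for seed in seeds:
        cfg = SyntheticConfig(
            n_samples=n_samples,
            panel_size=85,
            n_suppressor=61,
            n_enhancer=24,
            n_background=0,
            n_null_background=0,
            n_matched_pairs=5,
            seed=seed,
        )
        cohort = generate_cohort(cfg)
        iso = IsoformTable(cohort.isoforms, cohort.isoform_gene_map, cohort.isoform_lengths)
        switch = detect_switch_genes(iso, pc_threshold=-0.3)
        truth_sw = set(cohort.truth.switch_genes)
        truth_ns = set(cohort.truth.nonswitch_genes)
        detected = set(switch.genes)
        sens.append(len(detected & truth_sw) / len(truth_sw))
        fpr.append(len(detected & truth_ns) / len(truth_ns))
        modules = {
            "Enhancer": cohort.truth.module_genes("enhancer"),
            "Suppressor": cohort.truth.module_genes("suppressor"),
        }
        _, in_both, frac = isoform_module_clusters(iso, switch, cohort.expression, modules)
        detected_sw = detected & truth_sw
        frac_detected = (
            len(set(in_both) & detected_sw) / len(detected_sw) if detected_sw else 0.0
        )
        both.append(frac_detected)
    return {
        "sensitivity": float(np.mean(sens)),
        "false_positive_rate": float(np.mean(fpr)),
        "both_cluster_fraction": float(np.mean(both)),
        "n_seeds": len(list(seeds)),
    }


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def enrichment_experiment(
    seeds: Sequence[int], n_perm: int = 1000, n_background: int = 1500
) -> dict:
    """GSEA detection of the planted positive set; ORA of the top 500."""
    gsea_hits = 0
    ora_ps, gsea_ps, nes_values = [], [], []
    for seed in seeds:
        cfg = SyntheticConfig(
            n_samples=300,
            n_background=n_background,
            n_null_background=200,
            n_matched_pairs=3,
            n_switch_genes=3,
            n_nonswitch_genes=3,
            seed=seed,
        )
        cohort = generate_cohort(cfg)
        panel = cohort.truth.panel_genes
        enh = cohort.truth.module_genes("enhancer")
        non_panel = [g for g in cohort.expression.gene_ids if g not in set(panel)]
        cross = pearson_cross(cohort.expression, enh, non_panel)
        ranked = rank_genes(cross, enh, exclude=panel)
        sets = planted_gene_sets(cohort.truth, n_random_sets=3)
        gsea = gsea_preranked(ranked, sets, n_perm=n_perm, seed=seed).set_index("set_name")
        p = float(gsea.loc["PLANTED_POSITIVE", "p_value"])
        nes_values.append(float(gsea.loc["PLANTED_POSITIVE", "nes"]))
        gsea_ps.append(p)
        gsea_hits += p < 0.05 and gsea.loc["PLANTED_POSITIVE", "es"] > 0
        ora = ora_hypergeometric(ranked.genes[:500], ranked.genes, sets).set_index("set_name")
        ora_ps.append(float(ora.loc["PLANTED_POSITIVE", "p_value"]))
    return {
        "gsea_detected": int(gsea_hits),
        "n_seeds": len(list(seeds)),
        "median_gsea_p": float(np.median(gsea_ps)),
        "median_nes": float(np.median(nes_values)),
        "median_ora_p": float(np.median(ora_ps)),
    }


# ---------------------------------------------------------------------------
# Motif enrichment
# ---------------------------------------------------------------------------

def motif_experiment(seeds: Sequence[int], n_fg: int = 50, n_bg: int = 500) -> dict:
    """Planted vs decoy motif z under the -50..+450 window."""
    hits = 0
    planted_z, decoy_z = [], []
    fg = [f"FG{i:03d}" for i in range(n_fg)]
    bg = [f"BG{i:03d}" for i in range(n_bg)]
    for seed in seeds:
        cfg = SyntheticConfig(seed=seed)
        promoters, _ = generate_promoters(cfg, creb_like_pwm(), fg, bg)
        r_planted = motif_z_enrichment(fg, promoters, creb_like_pwm())
        r_decoy = motif_z_enrichment(fg, promoters, decoy_pwm())
        planted_z.append(r_planted.z)
        decoy_z.append(r_decoy.z)
        hits += r_planted.z > 3 and abs(r_decoy.z) < 2
    return {
        "n_detected": int(hits),
        "n_seeds": len(list(seeds)),
        "median_planted_z": float(np.median(planted_z)),
        "median_decoy_abs_z": float(np.median(np.abs(decoy_z))),
    }
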