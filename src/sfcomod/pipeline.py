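"""End-to-end orchestration from a single YAML config.

Stages run in dependency order (correlate → discover → paired-DE →
clinical/survival → isoform → enrichment → motif) and communicate through
on-disk TSV/JSON artifacts so every stage is independently re-runnable.  A
manifest records parameters, seeds and per-file SHA-256 checksums; re-running
with an identical config reproduces identical checksums.

The config either names a ``synthetic`` section (the cohorts are generated
in-process with planted truth) or per-cohort input paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as sfio
from .correlation import pearson_cross, pearson_matrix
from .enrichment import gsea_preranked, ora_hypergeometric, rank_genes
from .isoforms import (
    IsoformTable,
    detect_switch_genes,
    isoform_length_compare,
    isoform_module_clusters,
)
from .modules import consensus_overlap, label_modules, stability_select_k
from .motifs import motif_enrichment_table
from .paired import PairedDesign, fold_change_summary, paired_log2fc
from .survival import compare_groups, logrank_km, median_normalize, median_split, module_score
from .synthetic import (
    SyntheticConfig,
    creb_like_pwm,
    decoy_pwm,
    generate_cohort,
    generate_promoters,
    generate_validation_cohort,
    planted_gene_sets,
)

log = logging.getLogger("sfcomod")

DEFAULT_PARAMS: dict[str, Any] = {
    "k_min": 2,
    "k_max": 6,
    "n_remove": 20,
    "min_size": 5,
    "pc_threshold": -0.3,
    "min_expression": 1.0,
    "top_n": 500,
    "n_perm": 300,
    "weight_p": 1.0,
    "gsea_min_size": 15,
    "gsea_max_size": 500,
    "window": (-50, 450),
}

STAGES = ("paired_de", "clinical", "survival", "isoform", "enrichment", "motif")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_config(config: dict) -> tuple[list[str], list[str]]:
    """Schema and consistency checks; returns (errors, warnings)."""
    errors: list[str] = []
    warnings: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"], []
    if "seed" in config and not isinstance(config["seed"], int):
        errors.append("seed must be an integer")
    has_synth = "synthetic" in config
    has_paths = "inputs" in config
    if not has_synth and not has_paths:
        errors.append("config must provide a 'synthetic' section or an 'inputs' section")
    if has_synth and not isinstance(config["synthetic"], dict):
        errors.append("'synthetic' must be a mapping of SyntheticConfig fields")
    if has_synth and isinstance(config["synthetic"], dict):
        valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
        unknown = set(config["synthetic"]) - valid
        if unknown:
            errors.append(f"unknown synthetic config keys: {sorted(unknown)}")
    params = config.get("params", {})
    if not isinstance(params, dict):
        errors.append("'params' must be a mapping")
        params = {}
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        warnings.append(f"unknown params ignored: {sorted(unknown)}")
    k_min = params.get("k_min", DEFAULT_PARAMS["k_min"])
    k_max = params.get("k_max", DEFAULT_PARAMS["k_max"])
    if k_min > k_max:
        errors.append(f"k_min ({k_min}) > k_max ({k_max})")
    if k_min < 2:
        errors.append("k_min must be >= 2")
    stages = config.get("stages", {})
    unknown = set(stages) - set(STAGES)
    if unknown:
        warnings.append(f"unknown stage flags ignored: {sorted(unknown)}")
    if has_paths:
        inputs = config["inputs"]
        if not isinstance(inputs, dict) or "expression" not in inputs:
            errors.append("'inputs' must be a mapping with at least an 'expression' path")
        else:
            for key, path in inputs.items():
                if isinstance(path, str) and not Path(path).exists():
                    errors.append(f"input path for {key!r} does not exist: {path}")
    return errors, warnings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    sfio.write_result_table(df, str(path))


def run_full_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every enabled stage; returns the manifest dict (also written to disk).

    Any stage failure aborts with the stage name and cause; outputs written
    before the failure are retained next to a ``FAILED_<stage>`` marker.
    """
    errors, warnings = validate_config(config)
    for w in warnings:
        log.warning("config: %s", w)
    if errors:
        raise sfio.ValidationError("invalid config: " + "; ".join(errors))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    stages = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGES}
    manifest: dict[str, Any] = {
        "seed": seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()},
        "stages": stages,
        "outputs": {},
        "results": {},
    }
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        _write(df, path)
        written.append(path)

    current_stage = "setup"
    try:
        # ------------------------------------------------------------------
        current_stage = "simulate"
        synthetic_mode = "synthetic" in config
        if synthetic_mode:
            scfg = SyntheticConfig(**{**config["synthetic"], "seed": seed})
            cohort = generate_cohort(scfg)
            val_cfg = config.get("validation", {})
            validation = generate_validation_cohort(
                cohort.truth, scfg, n_drop=int(val_cfg.get("n_drop", 9))
            )
            X = cohort.expression
            panel = cohort.truth.panel_genes
            survival_table = cohort.survival
            clinical = cohort.clinical
            iso_table = IsoformTable(cohort.isoforms, cohort.isoform_gene_map, cohort.isoform_lengths)
            design = PairedDesign(
                cohort.pair_design.rename(
                    columns={"normal_sample": "sample_condition1", "tumor_sample": "sample_condition2"}
                ),
                condition_names=("normal", "tumor"),
            )
            paired_X = sfio.ExpressionMatrix(
                pd.concat([cohort.expression.data, cohort.normal_expression.data], axis=1)
            )
            gene_sets = planted_gene_sets(cohort.truth)
            sfio.write_expression_table(X, str(outdir / "expression.tsv"))
            written.append(outdir / "expression.tsv")
            (outdir / "truth.json").write_text(cohort.truth.to_json())
            written.append(outdir / "truth.json")
            X_val, panel_val = validation.expression, validation.truth.panel_genes
        else:
            inputs = config["inputs"]
            X = sfio.read_expression_table(inputs["expression"])
            panel = (
                Path(inputs["panel"]).read_text().split() if "panel" in inputs else X.gene_ids
            )
            X_val = panel_val = None
            if "expression_validation" in inputs:
                X_val = sfio.read_expression_table(inputs["expression_validation"])
                panel_val = [g for g in panel if g in set(X_val.gene_ids)]
            survival_table = (
                sfio.read_survival_table(inputs["survival"]) if "survival" in inputs else None
            )
            clinical = sfio.read_clinical_table(inputs["clinical"]) if "clinical" in inputs else None
            iso_table = None
            if "isoforms" in inputs and "isoform_map" in inputs:
                iso_expr = sfio.read_expression_table(inputs["isoforms"])
                mapping = pd.read_csv(inputs["isoform_map"], sep="\t", index_col=0)
                iso_table = IsoformTable(
                    iso_expr,
                    mapping["gene_id"].to_dict(),
                    mapping["length"].astype(int).to_dict(),
                )
            design = None
            if "pairs" in inputs:
                design = PairedDesign(pd.read_csv(inputs["pairs"], sep="\t"))
            paired_X = X
            gene_sets = sfio.read_gmt(inputs["gmt"]) if "gmt" in inputs else None

        # ------------------------------------------------------------------
        current_stage = "correlate"
        panel_present = [g for g in panel if g in set(X.gene_ids)]
        C = pearson_matrix(X, panel_present)
        emit("pc_panel.tsv", C.data.reset_index(names="gene_id"))

        # ------------------------------------------------------------------
        current_stage = "discover"
        report, assignments = stability_select_k(
            X,
            panel_present,
            k_min=params["k_min"],
            k_max=params["k_max"],
            n_remove=min(params["n_remove"], X.shape[1] - 3),
            min_size=params["min_size"],
            seed=seed,
        )
        emit(
            "stability.tsv",
            pd.DataFrame(
                {
                    "k": list(report.apn),
                    "apn": list(report.apn.values()),
                    "ad": list(report.ad.values()),
                    "chosen": [k == report.chosen_k for k in report.apn],
                }
            ),
        )
        assignment_a = assignments[report.chosen_k]
        emit(
            "clusters_discovery.tsv",
            pd.DataFrame(
                {"gene_id": list(assignment_a.labels), "cluster": list(assignment_a.labels.values())}
            ),
        )
        modules = None
        if X_val is not None:
            C_val = pearson_matrix(X_val, [g for g in panel_val if g in set(X_val.gene_ids)])
            from .modules import cluster_correlation_rows

            assignment_b = cluster_correlation_rows(C_val, report.chosen_k)
            modules = consensus_overlap(assignment_a, assignment_b, min_size=params["min_size"])
            if survival_table is not None and len(modules.modules) >= 2:
                modules = label_modules(modules, X, survival_table)
            payload = {
                "chosen_k": report.chosen_k,
                "modules": {n: sorted(g) for n, g in modules.modules.items()},
                "provenance": {n: list(p) for n, p in modules.provenance.items()},
                "roles": modules.roles,
                "label_stats": modules.label_stats,
            }
            (outdir / "modules.json").write_text(json.dumps(payload, indent=1, default=float))
            written.append(outdir / "modules.json")
        else:
            log.warning("no validation cohort: consensus stage skipped")

        def module_gene_sets() -> dict[str, list[str]]:
            if modules is not None and modules.roles:
                return {
                    role: sorted(modules.role_genes(role)) for role in ("Enhancer", "Suppressor")
                }
            if modules is not None and len(modules.modules) >= 2:
                by_size = sorted(modules.modules, key=lambda n: -len(modules.modules[n]))[:2]
                return {name: sorted(modules.modules[name]) for name in by_size}
            # fall back to the discovery clustering's two largest clusters
            clusters = sorted(assignment_a.clusters(), key=len, reverse=True)[:2]
            return {f"cluster_{i+1}": sorted(c) for i, c in enumerate(clusters)}

        # ------------------------------------------------------------------
        current_stage = "paired_de"
        if stages["paired_de"] and design is not None:
            de = paired_log2fc(paired_X, design, panel_present)
            emit("paired_de.tsv", de)
            manifest["results"]["paired_de_summary"] = fold_change_summary(de)

        # ------------------------------------------------------------------
        current_stage = "clinical"
        if stages["clinical"] and clinical is not None:
            norm = median_normalize(X)
            rows = []
            for name, genes in module_gene_sets().items():
                score = module_score(norm, [g for g in genes if g in set(norm.gene_ids)])
                for covariate in ("grade", "mitotic_score", "er_status", "subtype"):
                    if covariate not in clinical.data.columns:
                        continue
                    labels = clinical.data[covariate].dropna()
                    shared = [s for s in labels.index if s in score.index]
                    try:
                        res = compare_groups(score.loc[shared], labels.loc[shared])
                    except sfio.ValidationError:
                        continue
                    rows.append(
                        (name, covariate, res["test"], res["statistic"], res["p_value"])
                    )
            emit(
                "clinical_tests.tsv",
                pd.DataFrame(rows, columns=["module", "covariate", "test", "statistic", "p_value"]),
            )

        # ------------------------------------------------------------------
        current_stage = "survival"
        if stages["survival"] and survival_table is not None:
            km_rows = []
            curve_rows = []
            for name, genes in module_gene_sets().items():
                score = module_score(X, [g for g in genes if g in set(X.gene_ids)])
                groups = median_split(score)
                km = logrank_km(survival_table, groups)
                km_rows.append((name, km.chi_square, km.p_value, km.hazard_ratio))
                for grp, curve in km.curves.items():
                    for _, r in curve.iterrows():
                        curve_rows.append((name, grp, r["time"], r["survival"], r["at_risk"]))
                manifest["results"].setdefault("survival", {})[name] = {
                    "hazard_ratio": km.hazard_ratio,
                    "p_value": km.p_value,
                }
            emit("logrank.tsv", pd.DataFrame(km_rows, columns=["module", "chi_square", "p_value", "hazard_ratio"]))
            emit(
                "km_curves.tsv",
                pd.DataFrame(curve_rows, columns=["module", "group", "time", "survival", "at_risk"]),
            )

        # ------------------------------------------------------------------
        current_stage = "isoform"
        if stages["isoform"] and iso_table is not None:
            switch = detect_switch_genes(
                iso_table, pc_threshold=params["pc_threshold"], min_expression=params["min_expression"]
            )
            emit(
                "switch_genes.tsv",
                pd.DataFrame(
                    [
                        (g, *switch.best_pair[g])
                        for g in switch.genes
                    ],
                    columns=["gene_id", "isoform_a", "isoform_b", "min_pair_pc"],
                ),
            )
            if len(switch.selected_isoforms) >= 2:
                assignment, in_both, frac = isoform_module_clusters(
                    iso_table, switch, X, module_gene_sets()
                )
                emit(
                    "isoform_clusters.tsv",
                    pd.DataFrame(
                        {
                            "isoform_id": list(assignment.labels),
                            "cluster": list(assignment.labels.values()),
                        }
                    ),
                )
                manifest["results"]["isoform"] = {
                    "n_switch_genes": len(switch.genes),
                    "n_in_both_clusters": len(in_both),
                    "fraction_in_both": frac,
                }
                try:
                    manifest["results"]["isoform"]["length_test"] = isoform_length_compare(
                        assignment, iso_table
                    )
                except sfio.ValidationError as exc:
                    log.warning("isoform length comparison skipped: %s", exc)

        # ------------------------------------------------------------------
        current_stage = "enrichment"
        if stages["enrichment"] and gene_sets is not None:
            non_panel = [g for g in X.gene_ids if g not in set(panel_present)]
            for name, genes in module_gene_sets().items():
                genes = [g for g in genes if g in set(X.gene_ids)]
                cross = pearson_cross(X, genes, non_panel)
                ranked = rank_genes(cross, genes, exclude=panel_present)
                emit(
                    f"ranking_{name}.tsv",
                    pd.DataFrame({"gene_id": ranked.genes, "score": ranked.scores}),
                )
                top = ranked.genes[: params["top_n"]]
                ora = ora_hypergeometric(top, ranked.genes, gene_sets, min_size=params["min_size"])
                emit(f"ora_{name}.tsv", ora)
                gsea = gsea_preranked(
                    ranked,
                    gene_sets,
                    weight_p=params["weight_p"],
                    n_perm=params["n_perm"],
                    seed=seed,
                    min_size=params["gsea_min_size"],
                    max_size=params["gsea_max_size"],
                )
                emit(f"gsea_{name}.tsv", gsea)

        # ------------------------------------------------------------------
        current_stage = "motif"
        if stages["motif"]:
            window = tuple(params["window"])
            if synthetic_mode:
                motif = creb_like_pwm()
                pwms = [motif, decoy_pwm()]
                fg_truth = cohort.truth.module_genes("suppressor")
                bg = [g for g in cohort.truth.panel_genes if g not in set(fg_truth)]
                promoters, plants = generate_promoters(scfg, motif, fg_truth, bg, window=window)
                sfio.write_promoters_fasta(promoters, str(outdir / "promoters.fasta"))
                written.append(outdir / "promoters.fasta")
            elif "promoters" in config.get("inputs", {}) and "jaspar" in config.get("inputs", {}):
                promoters = sfio.read_promoters_fasta(
                    config["inputs"]["promoters"], window[0], window[1]
                )
                pwms = sfio.read_jaspar(config["inputs"]["jaspar"])
            else:
                promoters = None
                pwms = []
            if promoters is not None:
                sets = module_gene_sets()
                preferred = "Suppressor" if "Suppressor" in sets else sorted(sets)[0]
                fg = [g for g in sets[preferred] if g in promoters.records]
                if len(fg) >= 2:
                    table = motif_enrichment_table(fg, promoters, pwms, window=window)
                    emit("motif_enrichment.tsv", table)
                    manifest["results"]["motif"] = {
                        r["motif_id"]: r["z"] for _, r in table.iterrows()
                    }
    except Exception as exc:  # noqa: BLE001 - stage attribution is the contract
        (outdir / f"FAILED_{current_stage}").write_text(str(exc))
        raise StageError(current_stage, exc) from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=float))
    log.info("pipeline complete: %d artifacts in %s", len(written), outdir)
    return manifest


def run_multi_cohort(
    base_config: dict, n_cohorts: int, outdir: str | Path
) -> pd.DataFrame:
    """Pan-cancer-style replication: the discovery loop over several cohorts.

    Each cohort reuses the first cohort's planted truth (same modules, new
    samples and cohort-specific weak loadings) and reports the recovered
    within/cross-module mean correlations and module overlap with truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(base_config.get("seed", 0))
    scfg = SyntheticConfig(**{**base_config.get("synthetic", {}), "seed": seed})
    discovery = generate_cohort(scfg)
    truth = discovery.truth
    supp = truth.module_genes("suppressor")
    enh = truth.module_genes("enhancer")
    rows = []
    for c in range(n_cohorts):
        cohort = (
            discovery
            if c == 0
            else generate_validation_cohort(truth, scfg, n_drop=0, seed=seed + 5000 + c)
        )
        X = cohort.expression
        C = pearson_matrix(X, [g for g in truth.panel_genes if g in set(X.gene_ids)])
        supp_block = C.data.loc[supp, supp].to_numpy()
        enh_block = C.data.loc[enh, enh].to_numpy()
        cross_block = C.data.loc[supp, enh].to_numpy()
        off = ~np.eye(len(supp), dtype=bool)
        rows.append(
            (
                f"cohort_{c+1}",
                float(supp_block[off].mean()),
                float(enh_block[~np.eye(len(enh), dtype=bool)].mean()),
                float(cross_block.mean()),
            )
        )
    df = pd.DataFrame(
        rows, columns=["cohort", "mean_pc_suppressor", "mean_pc_enhancer", "mean_pc_cross"]
    )
    _write(df, outdir / "multi_cohort_summary.tsv")
    return df
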