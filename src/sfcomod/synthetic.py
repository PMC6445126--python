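"""Synthetic tumor-cohort generator with planted ground truth.

A single latent activity :math:`a_s \\sim N(0, 1)` per tumor drives two
anti-correlated splicing-factor modules: enhancer genes load with
:math:`+\\beta`, suppressor genes with :math:`-\\beta`, so the expected
within-module pairwise Pearson correlation is
:math:`\\beta^2 / (\\beta^2 + \\sigma^2)` and the cross-module expectation
is its negative.  Non-module panel genes carry weak, partly cohort-specific
loadings; genome background genes carry graded loadings spanning the range
given by the config; null background genes carry none.  Clinical covariates,
survival hazard, isoform usage fractions and promoter motif plants are all
tied to the same latent activity, and every planted entity is recorded in a
truth object so downstream stages can be scored against it.

All randomness flows from one integer seed through deterministic
sub-streams per component.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PromoterSet,
    PWM,
    SurvivalTable,
    ValidationError,
)

log = logging.getLogger("sfcomod")


@dataclass
class SyntheticConfig:
    """Parameters of the generative model; defaults mirror the study design.

    Panel and module sizes (244 splicing factors, 61-gene suppressor and
    24-gene enhancer modules) follow the panel and consensus module sizes;
    cohort sizes, effect sizes and rates are the generator's stated study
    conditions.
    """

    n_samples: int = 300
    panel_size: int = 244
    n_suppressor: int = 61
    n_enhancer: int = 24
    beta: float = 1.0                 # module loading on the latent activity
    sigma: float = 1.0                # residual sd on the log2 scale
    panel_loading_sd: float = 0.2     # weak loadings of non-module panel genes
    panel_loading_rho: float = 0.5    # cross-cohort correlation of those loadings
    n_background: int = 3000
    background_loading_range: tuple[float, float] = (-1.0, 1.0)
    n_null_background: int = 500
    de_offset: float = 1.0            # tumor-vs-normal shift on planted DE genes
    de_fraction: float = 0.1          # fraction of genes planted as DE
    n_matched_pairs: int = 114
    gamma: float = 0.5                # log-hazard per unit latent activity
    baseline_hazard: float = 0.1      # events per time unit at a_s = 0
    censor_time: float = 10.0
    n_switch_genes: int = 50
    delta: float = 2.0                # isoform-switch loading on the logit scale
    n_nonswitch_genes: int = 50
    motif_plant_rate_fg: float = 0.8
    motif_plant_rate_bg: float = 0.05
    promoter_length: int = 600
    promoter_offset_start: int = -50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_suppressor + self.n_enhancer > self.panel_size:
            raise ValidationError("n_suppressor + n_enhancer exceeds panel_size")
        if self.sigma <= 0 or self.baseline_hazard <= 0 or self.censor_time <= 0:
            raise ValidationError("sigma, baseline_hazard and censor_time must be > 0")
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")
        for p in (self.motif_plant_rate_fg, self.motif_plant_rate_bg, self.de_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        lo, hi = self.background_loading_range
        if lo > hi:
            raise ValidationError("background_loading_range must be (low, high)")
        if self.n_matched_pairs > self.n_samples:
            raise ValidationError("n_matched_pairs cannot exceed n_samples")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for everything the generator planted."""

    module: dict[str, str]            # panel gene -> suppressor | enhancer | other
    loadings: dict[str, float]        # every expression gene -> latent loading
    panel_genes: list[str]
    de_genes: list[str]
    switch_genes: list[str]
    nonswitch_genes: list[str]
    activity: dict[str, float]        # tumor sample -> a_s
    config: SyntheticConfig

    def module_genes(self, role: str) -> list[str]:
        return [g for g, r in self.module.items() if r == role]

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["config"]["background_loading_range"] = list(
            payload["config"]["background_loading_range"]
        )
        return json.dumps(payload, indent=1)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix          # tumor samples only
    normal_expression: ExpressionMatrix   # matched normal samples
    pair_design: pd.DataFrame             # patient_id, normal_sample, tumor_sample
    isoforms: ExpressionMatrix            # isoforms x tumor samples, log2
    isoform_gene_map: dict[str, str]
    isoform_lengths: dict[str, int]
    clinical: ClinicalTable
    survival: SurvivalTable
    truth: SyntheticTruth


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gene_ids(config: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    panel = [f"SF{i:04d}" for i in range(1, config.panel_size + 1)]
    background = [f"BG{i:05d}" for i in range(1, config.n_background + 1)]
    null = [f"NB{i:05d}" for i in range(1, config.n_null_background + 1)]
    return panel, background, null


def _draw_loadings(config: SyntheticConfig, rng: np.random.Generator) -> tuple[dict[str, float], dict[str, str]]:
    panel, background, null = _gene_ids(config)
    module: dict[str, str] = {}
    loadings: dict[str, float] = {}
    for i, g in enumerate(panel):
        if i < config.n_suppressor:
            module[g] = "suppressor"
            loadings[g] = -config.beta
        elif i < config.n_suppressor + config.n_enhancer:
            module[g] = "enhancer"
            loadings[g] = config.beta
        else:
            module[g] = "other"
            loadings[g] = float(rng.normal(0.0, config.panel_loading_sd))
    lo, hi = config.background_loading_range
    for g in background:
        loadings[g] = float(rng.uniform(lo, hi))
    for g in null:
        loadings[g] = 0.0
    return loadings, module


def _expression_block(
    gene_ids: list[str],
    loadings: np.ndarray,
    mu: np.ndarray,
    activity: np.ndarray,
    sigma: float,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    noise = rng.normal(0.0, sigma, size=(len(gene_ids), len(activity)))
    values = mu[:, None] + loadings[:, None] * activity[None, :] + noise
    return pd.DataFrame(values, index=gene_ids, columns=sample_ids)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _clinical_from_activity(activity: np.ndarray, sample_ids: list[str], rng: np.random.Generator) -> ClinicalTable:
    n = len(activity)
    # cumulative-logistic ordinals: higher activity -> higher grade/scores
    def ordinal(cut_lo: float, cut_hi: float) -> np.ndarray:
        z = activity + rng.logistic(0.0, 1.0, size=n)
        return 1 + (z > cut_lo).astype(int) + (z > cut_hi).astype(int)

    grade = ordinal(-1.5, 1.5)
    mitotic = ordinal(-1.2, 1.2)
    pleo = ordinal(-1.2, 1.2)
    er_neg = rng.random(n) < _logistic(activity)
    z = activity + rng.normal(0.0, 1.0, size=n)
    bins = np.digitize(z, [-1.5, -0.5, 0.5, 1.5])
    subtype = np.array(["NormalLike", "LumA", "LumB", "Her2", "Basal"])[bins]
    df = pd.DataFrame(
        {
            "grade": grade,
            "mitotic_score": mitotic,
            "pleomorphism_score": pleo,
            "er_status": np.where(er_neg, "neg", "pos"),
            "subtype": subtype,
        },
        index=sample_ids,
    )
    return ClinicalTable(df)


def _survival_from_activity(
    activity: np.ndarray, sample_ids: list[str], config: SyntheticConfig, rng: np.random.Generator
) -> SurvivalTable:
    rate = config.baseline_hazard * np.exp(config.gamma * activity)
    raw = rng.exponential(1.0 / rate)
    event = (raw <= config.censor_time).astype(int)
    time = np.minimum(raw, config.censor_time)
    return SurvivalTable(pd.DataFrame({"time": time, "event": event}, index=sample_ids))


def _isoforms_from_activity(
    activity: np.ndarray,
    sample_ids: list[str],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, dict[str, str], dict[str, int], list[str], list[str]]:
    rows: dict[str, np.ndarray] = {}
    gene_map: dict[str, str] = {}
    lengths: dict[str, int] = {}
    switch = [f"SW{i:04d}" for i in range(1, config.n_switch_genes + 1)]
    nonswitch = [f"NS{i:04d}" for i in range(1, config.n_nonswitch_genes + 1)]
    n = len(activity)
    for g in switch:
        mu = rng.normal(8.0, 1.0)
        # total abundance offset is drawn per gene, not per sample, so the
        # isoform-pair correlation reflects usage switching alone
        total = 2.0 ** (mu + rng.normal(0.0, config.sigma))
        eta = rng.normal(0.0, 0.5, size=n)  # variance 0.25
        frac = _logistic(config.delta * activity + eta)
        rows[f"{g}.1"] = np.log2(total * frac + 1.0)
        rows[f"{g}.2"] = np.log2(total * (1.0 - frac) + 1.0)
    for g in nonswitch:
        mu = rng.normal(8.0, 1.0)
        c = rng.uniform(0.3, 0.7)
        base = 2.0**mu
        rows[f"{g}.1"] = np.log2(base * c + 1.0) + rng.normal(0.0, config.sigma, size=n)
        rows[f"{g}.2"] = np.log2(base * (1.0 - c) + 1.0) + rng.normal(0.0, config.sigma, size=n)
    for g in switch + nonswitch:
        for iso in (f"{g}.1", f"{g}.2"):
            gene_map[iso] = g
            lengths[iso] = int(rng.integers(500, 5001))
    iso = ExpressionMatrix(pd.DataFrame(rows, index=sample_ids).T)
    return iso, gene_map, lengths, switch, nonswitch


def _assemble_cohort(
    config: SyntheticConfig,
    loadings: dict[str, float],
    module: dict[str, str],
    gene_ids: list[str],
    mu: np.ndarray,
    seed: int,
    sample_prefix: str,
) -> SyntheticCohort:
    (rng_act, rng_expr, rng_pairs, rng_clin, rng_surv, rng_iso) = _streams(seed, 6)
    n = config.n_samples
    tumor_ids = [f"{sample_prefix}T{i:04d}" for i in range(1, n + 1)]
    activity = rng_act.normal(0.0, 1.0, size=n)

    lam = np.array([loadings[g] for g in gene_ids])
    expr = _expression_block(gene_ids, lam, mu, activity, config.sigma, tumor_ids, rng_expr)

    # matched normals: tumor profile minus de_offset on planted DE genes + fresh noise
    n_pairs = config.n_matched_pairs
    de_genes: list[str] = []
    if config.de_fraction > 0 and config.de_offset != 0.0:
        n_de = int(round(config.de_fraction * len(gene_ids)))
        de_genes = sorted(rng_pairs.choice(gene_ids, size=n_de, replace=False).tolist())
    normal_ids = [f"{sample_prefix}N{i:04d}" for i in range(1, n_pairs + 1)]
    offset = np.zeros(len(gene_ids))
    de_index = {g: i for i, g in enumerate(gene_ids)}
    for g in de_genes:
        offset[de_index[g]] = config.de_offset
    tumor_block = expr.iloc[:, :n_pairs].to_numpy()
    normals = (
        tumor_block
        - offset[:, None]
        + rng_pairs.normal(0.0, config.sigma, size=(len(gene_ids), n_pairs))
    )
    normal_expr = pd.DataFrame(normals, index=gene_ids, columns=normal_ids)
    pair_design = pd.DataFrame(
        {
            "patient_id": [f"{sample_prefix}P{i:04d}" for i in range(1, n_pairs + 1)],
            "normal_sample": normal_ids,
            "tumor_sample": tumor_ids[:n_pairs],
        }
    )

    clinical = _clinical_from_activity(activity, tumor_ids, rng_clin)
    survival = _survival_from_activity(activity, tumor_ids, config, rng_surv)
    iso, gene_map, lengths, switch, nonswitch = _isoforms_from_activity(
        activity, tumor_ids, config, rng_iso
    )

    truth = SyntheticTruth(
        module=module,
        loadings=loadings,
        panel_genes=[g for g in gene_ids if g.startswith("SF")],
        de_genes=de_genes,
        switch_genes=switch,
        nonswitch_genes=nonswitch,
        activity=dict(zip(tumor_ids, activity.astype(float))),
        config=config,
    )
    log.info(
        "synthetic cohort: %d genes x %d tumors, %d matched pairs, seed=%d",
        len(gene_ids), n, n_pairs, seed,
    )
    return SyntheticCohort(
        expression=ExpressionMatrix(expr),
        normal_expression=ExpressionMatrix(normal_expr),
        pair_design=pair_design,
        isoforms=iso,
        isoform_gene_map=gene_map,
        isoform_lengths=lengths,
        clinical=clinical,
        survival=survival,
        truth=truth,
    )


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a discovery cohort with full planted truth.

    Deterministic given ``config.seed``; two calls with the same config
    produce identical cohorts.
    """
    rng_load, rng_mu = _streams(config.seed, 2)
    loadings, module = _draw_loadings(config, rng_load)
    gene_ids = list(loadings)
    mu = rng_mu.normal(8.0, 1.0, size=len(gene_ids))
    return _assemble_cohort(config, loadings, module, gene_ids, mu, config.seed + 1, "")


def generate_validation_cohort(
    truth: SyntheticTruth,
    config: SyntheticConfig | None = None,
    n_drop: int = 9,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate an independent cohort sharing the discovery truth's modules.

    Module memberships (and module loadings) are preserved; the weak
    loadings of non-module panel genes are re-drawn with correlation
    ``panel_loading_rho`` to the discovery values, emulating cohort and
    platform heterogeneity.  ``n_drop`` randomly chosen panel genes are
    absent from the validation matrix (default 9, leaving 235 of 244).
    """
    config = config or truth.config
    seed = config.seed + 1000 if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    min_module = min(truth.config.n_suppressor, truth.config.n_enhancer)
    if n_drop >= min_module:
        raise ValidationError(f"n_drop={n_drop} must be smaller than the smallest module ({min_module})")

    loadings = dict(truth.loadings)
    rho, sd = config.panel_loading_rho, config.panel_loading_sd
    module = dict(truth.module)
    for g, role in module.items():
        if role == "other":
            fresh = rng.normal(0.0, sd)
            loadings[g] = float(rho * truth.loadings[g] + np.sqrt(1.0 - rho**2) * fresh)
    gene_ids = list(loadings)
    if n_drop > 0:
        dropped = set(rng.choice(truth.panel_genes, size=n_drop, replace=False).tolist())
        gene_ids = [g for g in gene_ids if g not in dropped]
        loadings = {g: loadings[g] for g in gene_ids}
        module = {g: r for g, r in module.items() if g not in dropped}
    mu = np.random.default_rng(np.random.SeedSequence(seed + 1).spawn(1)[0]).normal(
        8.0, 1.0, size=len(gene_ids)
    )
    truth_cfg = dataclasses.replace(config, seed=seed)
    cohort = _assemble_cohort(truth_cfg, loadings, module, gene_ids, mu, seed + 2, "V")
    return cohort


# ---------------------------------------------------------------------------
# Promoters and motifs
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def creb_like_pwm() -> PWM:
    """A strong palindromic cAMP-response-element-like motif (TGACGTCA)."""
    consensus = "TGACGTCA"
    counts = np.full((4, len(consensus)), 2.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 94.0
    return PWM("SYN0001", counts, name="CREB_like_synthetic")


def decoy_pwm() -> PWM:
    """An unrelated GATA-like decoy motif (AGATAAGA), never planted."""
    consensus = "AGATAAGA"
    counts = np.full((4, len(consensus)), 2.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 94.0
    return PWM("SYN0002", counts, name="GATA_like_synthetic_decoy")


def generate_promoters(
    config: SyntheticConfig,
    motif: PWM,
    foreground: list[str],
    background: list[str],
    seed: int | None = None,
    window: tuple[int, int] = (-50, 450),
) -> tuple[PromoterSet, dict[str, int | None]]:
    """Generate i.i.d. uniform ACGT promoters with the motif consensus planted.

    The consensus is inserted at a uniform random position inside the scoring
    window with probability ``motif_plant_rate_fg`` for foreground genes and
    ``motif_plant_rate_bg`` for background genes.  Returns the promoter set
    and a truth map gene -> plant offset (TSS coordinates) or None.
    """
    seed = config.seed + 2000 if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    offset_start = config.promoter_offset_start
    offset_end = offset_start + config.promoter_length - 1
    w = motif.width
    if window[0] < offset_start or window[1] > offset_end:
        raise ValidationError(
            f"scoring window {window} exceeds promoter range [{offset_start}, {offset_end}]"
        )
    if window[1] - window[0] + 1 < w:
        raise ValidationError("scoring window shorter than motif width")
    consensus = motif.consensus()
    records: dict[str, str] = {}
    plants: dict[str, int | None] = {}
    fg = set(foreground)
    for gene in list(dict.fromkeys(list(foreground) + list(background))):
        seq = _BASES[rng.integers(0, 4, size=config.promoter_length)]
        rate = config.motif_plant_rate_fg if gene in fg else config.motif_plant_rate_bg
        plants[gene] = None
        if rng.random() < rate:
            pos_offset = int(rng.integers(window[0], window[1] - w + 2))
            i = pos_offset - offset_start
            seq[i : i + w] = list(consensus)
            plants[gene] = pos_offset
        records[gene] = "".join(seq)
    return PromoterSet(records, offset_start, offset_end), plants


def planted_gene_sets(
    truth: SyntheticTruth,
    set_size: int = 100,
    n_random_sets: int = 20,
    loading_cut: float = 0.7,
    seed: int | None = None,
) -> GeneSetCollection:
    """Build a synthetic GMT-style collection from the planted loadings.

    ``PLANTED_POSITIVE`` / ``PLANTED_NEGATIVE`` sample genes with loading
    above ``loading_cut`` (resp. below its negative) among non-panel genes;
    the remaining sets are random draws from the non-panel universe and act
    as nulls for enrichment calibration.
    """
    seed = truth.config.seed + 3000 if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    panel = set(truth.panel_genes)
    universe = [g for g in truth.loadings if g not in panel]
    pos = [g for g in universe if truth.loadings[g] >= loading_cut]
    neg = [g for g in universe if truth.loadings[g] <= -loading_cut]
    sets: dict[str, GeneSet] = {}
    for label, pool in (("PLANTED_POSITIVE", pos), ("PLANTED_NEGATIVE", neg)):
        k = min(set_size, len(pool))
        if k == 0:
            continue
        genes = tuple(sorted(rng.choice(pool, size=k, replace=False).tolist()))
        sets[label] = GeneSet(label, "genes with planted module-tracking loadings", genes)
    for i in range(1, n_random_sets + 1):
        name = f"RANDOM_{i:02d}"
        genes = tuple(sorted(rng.choice(universe, size=set_size, replace=False).tolist()))
        sets[name] = GeneSet(name, "random null gene set", genes)
    return GeneSetCollection(sets)
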