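"""Co-expression module discovery on the panel correlation profile.

The feature vector for gene g is its full row of Pearson coefficients to all
panel genes (self-entry 1 included), clustered agglomeratively under
Euclidean distance and complete linkage.  The number of clusters is chosen
by a clValid-style leave-one-sample-out stability test (APN, lower better);
clusters found independently in two cohorts are matched by maximum total
Jaccard and intersected into consensus modules, which are finally labeled
Enhancer (worse outcome when highly expressed) or Suppressor by median-split
log-rank association with survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .correlation import CorrelationMatrix, pearson_matrix
from .io import ExpressionMatrix, SurvivalTable, ValidationError

log = logging.getLogger("sfcomod")


@dataclass
class ClusterAssignment:
    """Partition of panel genes into clusters 1..k, with the linkage record."""

    labels: dict[str, int]
    k: int
    merge_heights: np.ndarray | None = None

    def __post_init__(self) -> None:
        present = set(self.labels.values())
        if present != set(range(1, self.k + 1)):
            raise ValidationError(f"cluster labels must cover 1..{self.k}, got {sorted(present)}")

    def members(self, label: int) -> set[str]:
        return {g for g, c in self.labels.items() if c == label}

    def clusters(self) -> list[set[str]]:
        return [self.members(c) for c in range(1, self.k + 1)]


@dataclass
class StabilityReport:
    """Per-k APN/AD stability measures and the chosen cluster number."""

    apn: dict[int, float]
    ad: dict[int, float]
    chosen_k: int
    excluded_k: list[int] = field(default_factory=list)


@dataclass
class ConsensusModules:
    """Cross-cohort consensus modules with provenance and optional role labels."""

    modules: dict[str, set[str]]                      # module name -> gene set
    provenance: dict[str, tuple[int, int, float]]     # name -> (cluster A, cluster B, Jaccard)
    roles: dict[str, str] = field(default_factory=dict)   # module name -> Enhancer | Suppressor
    label_stats: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.modules)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self.modules[a] & self.modules[b]:
                    raise ValidationError(f"consensus modules {a!r} and {b!r} overlap")

    def role_genes(self, role: str) -> set[str]:
        for name, r in self.roles.items():
            if r == role:
                return set(self.modules[name])
        raise KeyError(f"no module labeled {role!r}")


def _cluster_rows(values: np.ndarray, ids: Sequence[str], k: int) -> ClusterAssignment:
    """Complete-linkage Euclidean clustering of row vectors, cut at exactly k."""
    n = len(ids)
    if not 2 <= k <= n - 1:
        raise ValidationError(f"k={k} out of range [2, {n - 1}]")
    Z = linkage(values, method="complete", metric="euclidean")
    flat = fcluster(Z, t=k, criterion="maxclust")
    if len(set(flat)) != k:
        # tied merge heights can make maxclust skip a level; fall back to cutting
        # the merge sequence directly
        flat = fcluster(Z, t=Z[-(k - 1), 2] - 1e-12, criterion="distance")
    # relabel clusters by order of first appearance for determinism
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for gid, c in zip(ids, flat):
        if c not in remap:
            remap[c] = len(remap) + 1
        labels[gid] = remap[c]
    return ClusterAssignment(labels, k=len(remap), merge_heights=Z[:, 2].copy())


def cluster_correlation_rows(C: CorrelationMatrix, k: int) -> ClusterAssignment:
    """Cluster the rows of a symmetric panel correlation matrix into k groups."""
    if not C.symmetric:
        raise ValidationError("cluster_correlation_rows expects a symmetric correlation matrix")
    return _cluster_rows(C.values, C.ids_rows, k)


def cluster_rows_with_distance(
    values: np.ndarray, ids: Sequence[str], k: int, metric: str = "euclidean"
) -> ClusterAssignment:
    """Complete-linkage clustering of arbitrary row vectors.

    ``metric="correlation"`` uses the 1 - Pearson distance (used for the
    clinical heatmap clustering of median-normalized expression).
    """
    n = len(ids)
    if not 2 <= k <= n - 1:
        raise ValidationError(f"k={k} out of range [2, {n - 1}]")
    Z = linkage(values, method="complete", metric=metric)
    flat = fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for gid, c in zip(ids, flat):
        if c not in remap:
            remap[c] = len(remap) + 1
        labels[gid] = remap[c]
    return ClusterAssignment(labels, k=len(remap), merge_heights=Z[:, 2].copy())


def _has_anticorrelated_pair(
    C: CorrelationMatrix,
    assignment: ClusterAssignment,
    min_size: int,
    coherence: float,
) -> bool:
    """True iff two clusters are each internally coherent (mean within-PC >=
    ``coherence``) and mutually anti-correlated (mean cross-PC <= -coherence)."""
    clusters = [sorted(c) for c in assignment.clusters() if len(c) >= max(2, min_size)]
    within = []
    for genes in clusters:
        block = C.data.loc[genes, genes].to_numpy()
        off = ~np.eye(len(genes), dtype=bool)
        within.append(float(block[off].mean()))
    for i in range(len(clusters)):
        if within[i] < coherence:
            continue
        for j in range(i + 1, len(clusters)):
            if within[j] < coherence:
                continue
            cross = float(C.data.loc[clusters[i], clusters[j]].to_numpy().mean())
            if cross <= -coherence:
                return True
    return False


def stability_select_k(
    X: ExpressionMatrix,
    panel: Sequence[str],
    k_min: int = 2,
    k_max: int = 6,
    n_remove: int | None = None,
    min_size: int = 5,
    seed: int = 0,
    on_missing: str = "error",
    coherence: float = 0.25,
) -> tuple[StabilityReport, dict[int, ClusterAssignment]]:
    """Choose the cluster number by leave-one-sample-out stability (APN).

    For each candidate k the panel is clustered on all samples; then, for
    each of ``n_remove`` randomly chosen samples, the correlation matrix is
    recomputed without that sample and re-clustered.  APN is the average
    over genes and removals of one minus the overlap fraction between the
    gene's full-data cluster and its reduced-data cluster; AD averages the
    full-data distances between the two cluster memberships.

    The chosen k minimizes APN among candidates that (a) have no cluster
    smaller than ``min_size`` and (b) represent the major groups: the
    clustering must contain a pair of clusters that are each internally
    co-expressed (mean within-cluster PC >= ``coherence``) and mutually
    anti-correlated (mean between-cluster PC <= -``coherence``), the
    defining feature of the panel's two main modules.  Ties break toward
    smaller k.  If no candidate satisfies (b), the requirement is dropped
    with a warning.

    Returns the report and the full-data assignment for every candidate k.
    """
    if k_min < 2:
        raise ValidationError("k_min must be >= 2")
    C_full = pearson_matrix(X, panel, on_missing=on_missing)
    genes = C_full.ids_rows
    if k_max > len(genes) - 1:
        raise ValidationError(f"k_max={k_max} exceeds panel size - 1 ({len(genes) - 1})")
    samples = X.sample_ids
    if n_remove is None:
        n_remove = min(30, len(samples))
    if len(samples) < n_remove + 3:
        raise ValidationError("fewer samples than n_remove + 3")
    rng = np.random.default_rng(seed)
    removed = rng.choice(samples, size=n_remove, replace=False)

    ks = list(range(k_min, k_max + 1))
    full_assign = {k: _cluster_rows(C_full.values, genes, k) for k in ks}
    D_full = squareform(pdist(C_full.values, metric="euclidean"))
    gene_index = {g: i for i, g in enumerate(genes)}

    apn_acc = {k: 0.0 for k in ks}
    ad_acc = {k: 0.0 for k in ks}
    count = 0
    for s in removed:
        kept = [c for c in samples if c != s]
        C_red = pearson_matrix(ExpressionMatrix(X.data[kept]), genes)
        for k in ks:
            red = _cluster_rows(C_red.values, genes, k)
            apn_sum = 0.0
            ad_sum = 0.0
            full_members = {c: full_assign[k].members(c) for c in range(1, full_assign[k].k + 1)}
            red_members = {c: red.members(c) for c in range(1, red.k + 1)}
            for g in genes:
                S_full = full_members[full_assign[k].labels[g]]
                S_red = red_members[red.labels[g]]
                apn_sum += 1.0 - len(S_full & S_red) / len(S_full)
                idx_f = [gene_index[x] for x in S_full]
                idx_r = [gene_index[x] for x in S_red]
                ad_sum += float(D_full[np.ix_(idx_f, idx_r)].mean())
            apn_acc[k] += apn_sum / len(genes)
            ad_acc[k] += ad_sum / len(genes)
        count += 1

    apn = {k: apn_acc[k] / count for k in ks}
    ad = {k: ad_acc[k] / count for k in ks}

    excluded = [
        k for k in ks if min(len(m) for m in full_assign[k].clusters()) < min_size
    ]
    eligible = [k for k in ks if k not in excluded]
    if not eligible:
        raise ValidationError("no candidate k satisfies the min_size guard")
    represented = [
        k for k in eligible
        if _has_anticorrelated_pair(C_full, full_assign[k], min_size, coherence)
    ]
    if represented:
        excluded = excluded + [k for k in eligible if k not in represented]
        eligible = represented
    else:
        log.warning(
            "no candidate k shows an anti-correlated coherent cluster pair; "
            "falling back to the min_size guard alone"
        )
    chosen = eligible[0]
    for k in eligible[1:]:
        if apn[k] < apn[chosen]:
            chosen = k
    log.info("stability selection: APN=%s, chosen k=%d", {k: round(v, 4) for k, v in apn.items()}, chosen)
    return StabilityReport(apn=apn, ad=ad, chosen_k=chosen, excluded_k=excluded), full_assign


def consensus_overlap(
    A: ClusterAssignment, B: ClusterAssignment, min_size: int = 5
) -> ConsensusModules:
    """Match clusters across two cohorts by maximum total Jaccard and intersect.

    Clusters of A are paired one-to-one with clusters of B via optimal
    assignment over min(kA, kB) pairings; each consensus module is the
    intersection of a matched pair, restricted to the shared gene universe.
    Modules smaller than ``min_size`` are discarded with a warning.
    """
    universe = set(A.labels) & set(B.labels)
    if len(universe) < 2:
        raise ValidationError("gene universes overlap in fewer than 2 genes")
    clusters_a = A.clusters()
    clusters_b = B.clusters()
    J = np.zeros((A.k, B.k))
    for i, ca in enumerate(clusters_a):
        for j, cb in enumerate(clusters_b):
            union = len(ca | cb)
            J[i, j] = len(ca & cb) / union if union else 0.0
    rows, cols = linear_sum_assignment(-J)
    modules: dict[str, set[str]] = {}
    provenance: dict[str, tuple[int, int, float]] = {}
    pairs = sorted(zip(rows, cols), key=lambda rc: -J[rc[0], rc[1]])
    idx = 0
    for i, j in pairs:
        genes = clusters_a[i] & clusters_b[j]
        if len(genes) < min_size:
            log.warning(
                "consensus module from clusters A%d/B%d has %d genes (< %d); discarded",
                i + 1, j + 1, len(genes), min_size,
            )
            continue
        idx += 1
        name = f"module_{idx}"
        modules[name] = genes
        provenance[name] = (i + 1, j + 1, float(J[i, j]))
    return ConsensusModules(modules=modules, provenance=provenance)


def label_modules(
    modules: ConsensusModules,
    X: ExpressionMatrix,
    survival: SurvivalTable,
    alpha: float = 0.05,
) -> ConsensusModules:
    """Label the two main anti-correlated consensus modules Enhancer / Suppressor.

    Among all consensus-module pairs, the pair whose mean between-module
    Pearson correlation (in ``X``) is most negative is taken as the main
    module pair — the panel's defining feature is two clusters that
    correlate positively within and negatively between themselves.  Each of
    the two is then scored per patient (mean expression), the cohort is
    median-split, and a log-rank test with O/E hazard ratio (high vs low)
    is computed.  The module whose high group has the worse outcome
    (HR > 1) is the Enhancer, the other the Suppressor.  Labels are
    withheld (with a warning) when the best pair is not anti-correlated,
    when both modules associate in the same direction, or when neither
    association reaches ``alpha``.
    """
    from .survival import logrank_km, median_split, module_score

    if len(modules.modules) < 2:
        raise ValidationError("need at least two consensus modules to label")
    present = set(X.gene_ids)
    names = sorted(modules.modules)
    best_pair: tuple[str, str] | None = None
    best_cross = np.inf
    all_genes = sorted(
        g for n in names for g in modules.modules[n] if g in present
    )
    C = pearson_matrix(X, all_genes)
    for i, a in enumerate(names):
        ga = [g for g in modules.modules[a] if g in present]
        for b in names[i + 1 :]:
            gb = [g for g in modules.modules[b] if g in present]
            if not ga or not gb:
                continue
            cross = float(C.data.loc[ga, gb].to_numpy().mean())
            if cross < best_cross:
                best_cross = cross
                best_pair = (a, b)
    if best_pair is None or best_cross >= 0:
        log.warning(
            "module labels withheld: no anti-correlated module pair "
            "(best mean cross-PC %.3f)", best_cross,
        )
        modules.roles = {}
        return modules
    top_two = list(best_pair)
    stats: dict[str, dict] = {}
    for name in top_two:
        genes = [g for g in modules.modules[name] if g in set(X.gene_ids)]
        score = module_score(X, genes)
        groups = median_split(score)
        shared = [s for s in survival.data.index if s in groups.index]
        km = logrank_km(
            SurvivalTable(survival.data.loc[shared]), groups.loc[shared]
        )
        stats[name] = {
            "hazard_ratio": km.hazard_ratio,
            "chi_square": km.chi_square,
            "p_value": km.p_value,
        }
    modules.label_stats = stats
    modules.label_stats["_pair_mean_cross_pc"] = {"value": best_cross}
    hr = {name: stats[name]["hazard_ratio"] for name in top_two}
    pvals = {name: stats[name]["p_value"] for name in top_two}
    a, b = top_two
    opposite = (hr[a] - 1.0) * (hr[b] - 1.0) < 0
    significant = min(pvals.values()) < alpha
    if not opposite or not significant:
        log.warning(
            "module labels withheld: HRs %s, p-values %s do not show a significant "
            "opposite survival association", hr, pvals,
        )
        modules.roles = {}
        return modules
    enhancer = a if hr[a] > 1.0 else b
    suppressor = b if enhancer == a else a
    modules.roles = {enhancer: "Enhancer", suppressor: "Suppressor"}
    log.info(
        "labeled %s as Enhancer (HR=%.3f) and %s as Suppressor (HR=%.3f)",
        enhancer, hr[enhancer], suppressor, hr[suppressor],
    )
    return modules
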