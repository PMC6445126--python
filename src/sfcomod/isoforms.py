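"""Isoform-switch detection and isoform–module correlation clustering.

A gene "switches isoforms" when the expression of its individual transcripts
anti-correlates across tumors — one isoform replaces the other rather than
both tracking total gene expression.  Selected isoforms are then correlated
against the Enhancer/Suppressor module genes and partitioned into two
clusters; genes with isoforms in both clusters link the splicing-factor
switch to a downstream isoform-usage switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation import pearson_cross, pearson_matrix
from .io import ExpressionMatrix, ValidationError
from .modules import ClusterAssignment, ConsensusModules, _cluster_rows
from .survival import compare_groups

log = logging.getLogger("sfcomod")


@dataclass
class IsoformTable:
    """Isoform x sample log2 expression with isoform->gene map and lengths."""

    expression: ExpressionMatrix
    gene_map: dict[str, str]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for iso in self.expression.gene_ids:
            if iso not in self.gene_map:
                raise ValidationError(f"isoform {iso!r} missing from gene map")
            if self.lengths.get(iso, 0) < 1:
                raise ValidationError(f"isoform {iso!r} has invalid length")

    def isoforms_of(self, gene: str) -> list[str]:
        return [i for i in self.expression.gene_ids if self.gene_map[i] == gene]


@dataclass
class SwitchGeneSet:
    """Genes passing the negative isoform-pair correlation filter."""

    genes: list[str]
    best_pair: dict[str, tuple[str, str, float]]  # gene -> (iso_a, iso_b, most negative PC)
    selected_isoforms: list[str] = field(default_factory=list)


def detect_switch_genes(
    iso: IsoformTable,
    pc_threshold: float = -0.3,
    min_expression: float = 1.0,
) -> SwitchGeneSet:
    """Select genes whose isoform pair correlations drop below ``pc_threshold``.

    Isoforms with mean log2 expression below ``min_expression`` are dropped
    first; a gene with >= 2 remaining isoforms is selected iff its most
    negative isoform-pair Pearson correlation is <= the threshold.
    """
    if pc_threshold >= 0:
        raise ValidationError("pc_threshold must be negative")
    if iso.expression.shape[1] < 3:
        raise ValidationError("detect_switch_genes requires >= 3 samples")
    means = iso.expression.data.mean(axis=1)
    expressed = sorted(means.index[means >= min_expression])
    by_gene: dict[str, list[str]] = {}
    for i in expressed:
        by_gene.setdefault(iso.gene_map[i], []).append(i)
    multi = {g: isos for g, isos in by_gene.items() if len(isos) >= 2}
    if not multi:
        log.warning("no gene with >= 2 expressed isoforms; empty switch set")
        return SwitchGeneSet(genes=[], best_pair={})
    genes: list[str] = []
    best: dict[str, tuple[str, str, float]] = {}
    selected_isoforms: list[str] = []
    for g in sorted(multi):
        isos = multi[g]
        C = pearson_matrix(iso.expression, isos)
        vals = C.data.to_numpy().copy()
        np.fill_diagonal(vals, np.inf)
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        pc = float(vals[i, j])
        if pc <= pc_threshold:
            genes.append(g)
            best[g] = (isos[i], isos[j], pc)
            selected_isoforms.extend(isos)
    return SwitchGeneSet(genes=genes, best_pair=best, selected_isoforms=sorted(set(selected_isoforms)))


def isoform_module_clusters(
    iso: IsoformTable,
    switch: SwitchGeneSet,
    X: ExpressionMatrix,
    modules: ConsensusModules | Mapping[str, Sequence[str]],
) -> tuple[ClusterAssignment, list[str], float]:
    """Cluster selected isoforms by their correlation to module genes (k=2).

    Each selected isoform's feature vector is its Pearson correlation to all
    Enhancer plus Suppressor genes; rows are clustered with Euclidean
    distance and complete linkage into exactly 2 clusters.  Returns the
    assignment, the list of genes with at least one isoform in each cluster,
    and that list's fraction of the switch-gene set.
    """
    if isinstance(modules, ConsensusModules):
        module_genes = sorted(set().union(*modules.modules.values()))
    else:
        module_genes = sorted(set().union(*[set(v) for v in modules.values()]))
    isoforms = [i for i in switch.selected_isoforms if i in set(iso.expression.gene_ids)]
    if len(isoforms) < 2:
        raise ValidationError("need >= 2 selected isoforms to cluster")
    module_genes = [g for g in module_genes if g in set(X.gene_ids)]
    cross = pearson_cross(iso.expression, isoforms, module_genes, Y=X)
    assignment = _cluster_rows(cross.values, isoforms, k=2)
    in_both: list[str] = []
    for g in switch.genes:
        labels = {assignment.labels[i] for i in iso.isoforms_of(g) if i in assignment.labels}
        if len(labels) == 2:
            in_both.append(g)
    frac = len(in_both) / len(switch.genes) if switch.genes else 0.0
    return assignment, sorted(in_both), frac


def isoform_length_compare(assignment: ClusterAssignment, iso: IsoformTable) -> dict[str, float]:
    """Equal-variance t-test on isoform lengths between the two clusters."""
    lengths = {1: [], 2: []}
    for isoform, c in assignment.labels.items():
        lengths[c].append(iso.lengths[isoform])
    for c in (1, 2):
        if len(lengths[c]) < 2:
            raise ValidationError(f"cluster {c} has fewer than 2 isoforms")
    a = pd.Series(lengths[1], dtype=float)
    b = pd.Series(lengths[2], dtype=float)
    values = pd.concat([a, b], ignore_index=True)
    labels = pd.Series([1] * len(a) + [2] * len(b))
    if values.nunique() == 1 or (a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] != b.iloc[0]):
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValidationError("zero pooled variance; length comparison degenerate")
    res = compare_groups(values, labels)
    res.update({"mean_cluster1": float(a.mean()), "mean_cluster2": float(b.mean())})
    return res


def isoform_fraction_histogram(iso: IsoformTable, genes: Sequence[str], bins: int = 20) -> pd.DataFrame:
    """Per-gene histogram of the first-isoform usage fraction across samples.

    Descriptive output: bimodal usage (mass near 0 and 1, little in between)
    indicates mutually exclusive isoform expression across tumors.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    rows = []
    for g in genes:
        isos = iso.isoforms_of(g)
        if len(isos) < 2:
            continue
        linear = 2.0 ** iso.expression.data.loc[isos[:2]] - 1.0
        linear = linear.clip(lower=0.0)
        total = linear.sum(axis=0)
        frac = (linear.iloc[0] / total.replace(0.0, np.nan)).dropna()
        hist, _ = np.histogram(frac, bins=edges)
        rows.append([g, *hist])
    cols = ["gene_id"] + [f"bin_{edges[i]:.2f}_{edges[i+1]:.2f}" for i in range(bins)]
    return pd.DataFrame(rows, columns=cols)
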