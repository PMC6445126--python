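"""Correlation primitives: panel auto-correlation, panel-vs-genome
cross-correlation, per-gene Spearman RNA–protein agreement, and mean
panel-to-gene-set correlation.

All Pearson computations operate on log2 expression across samples.  Results
are independent of evaluation order and batching, and invariant under
per-gene affine transforms with positive scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ValidationError

log = logging.getLogger("sfcomod")


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson coefficients with row/column gene ids.

    When ``symmetric`` the matrix equals its transpose and the diagonal is
    exactly 1.
    """

    data: pd.DataFrame
    symmetric: bool = False

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and (np.abs(values) > 1 + 1e-9).any():
            raise ValidationError("correlation values outside [-1, 1]")
        if self.symmetric:
            if list(self.data.index) != list(self.data.columns):
                raise ValidationError("symmetric correlation matrix requires identical row/col ids")
            if not np.allclose(values, values.T, atol=1e-12):
                raise ValidationError("symmetric flag set but matrix is not symmetric")

    @property
    def ids_rows(self) -> list[str]:
        return list(self.data.index)

    @property
    def ids_cols(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def _check_panel(X: ExpressionMatrix, panel: Sequence[str], on_missing: str) -> list[str]:
    panel = list(dict.fromkeys(panel))
    missing = [g for g in panel if g not in X.data.index]
    if missing:
        if on_missing == "error":
            raise ValidationError(f"panel genes absent from matrix: {missing[:20]}")
        log.warning("dropping %d panel genes absent from matrix", len(missing))
        panel = [g for g in panel if g not in set(missing)]
    return panel


def _standardize(values: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    zero = np.flatnonzero(norm == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance gene(s): {[ids[i] for i in zero[:10]]}"
        )
    return centered / norm[:, None]


def pearson_matrix(
    X: ExpressionMatrix, panel: Sequence[str], on_missing: str = "error"
) -> CorrelationMatrix:
    """All-pairs Pearson correlation of the panel genes across samples.

    Requires >= 3 samples and nonzero variance for every panel gene.
    ``on_missing`` is ``"error"`` (default) or ``"drop"`` (warn and drop
    panel genes absent from the matrix).
    """
    panel = _check_panel(X, panel, on_missing)
    sub = X.data.loc[panel]
    if sub.shape[1] < 3:
        raise ValidationError("pearson_matrix requires >= 3 samples")
    Z = _standardize(sub.to_numpy(dtype=float), panel)
    C = Z @ Z.T
    np.clip(C, -1.0, 1.0, out=C)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(pd.DataFrame(C, index=panel, columns=panel), symmetric=True)


def pearson_cross(
    X: ExpressionMatrix,
    rows: Sequence[str],
    cols: Sequence[str],
    Y: ExpressionMatrix | None = None,
    on_missing: str = "error",
) -> CorrelationMatrix:
    """Pearson correlation of ``rows`` genes (from X) against ``cols`` genes.

    ``cols`` are taken from ``Y`` when given (e.g. an isoform matrix),
    otherwise from ``X``; samples are aligned by id and must match.
    """
    rows = _check_panel(X, rows, on_missing)
    other = Y if Y is not None else X
    cols = _check_panel(other, cols, on_missing)
    if Y is not None:
        if set(X.sample_ids) != set(Y.sample_ids):
            raise ValidationError("sample-id mismatch between the two matrices")
        other = ExpressionMatrix(Y.data[X.sample_ids])
    a = X.data.loc[rows]
    b = other.data.loc[cols]
    if a.shape[1] < 3:
        raise ValidationError("pearson_cross requires >= 3 samples")
    Za = _standardize(a.to_numpy(dtype=float), rows)
    Zb = _standardize(b.to_numpy(dtype=float), cols)
    C = Za @ Zb.T
    np.clip(C, -1.0, 1.0, out=C)
    return CorrelationMatrix(pd.DataFrame(C, index=rows, columns=cols), symmetric=False)


def mean_panel_correlation(
    C: CorrelationMatrix, panel_subset: Sequence[str], target_set: Sequence[str]
) -> tuple[pd.Series, float]:
    """Mean Pearson correlation of each panel gene to a target gene set.

    Self-pairs (row id equals column id) are excluded.  Returns the
    per-gene means and the grand mean across panel genes.
    """
    panel_subset = list(dict.fromkeys(panel_subset))
    target_set = list(dict.fromkeys(target_set))
    missing = [g for g in panel_subset if g not in C.data.index]
    if missing:
        raise ValidationError(f"panel genes absent from correlation rows: {missing[:10]}")
    missing = [g for g in target_set if g not in C.data.columns]
    if missing:
        raise ValidationError(f"target genes absent from correlation columns: {missing[:10]}")
    per_gene = {}
    for g in panel_subset:
        targets = [t for t in target_set if t != g]
        if not targets:
            raise ValidationError(f"empty target set after self-exclusion for gene {g!r}")
        per_gene[g] = float(C.data.loc[g, targets].mean())
    series = pd.Series(per_gene, name="mean_pc")
    return series, float(series.mean())


def spearman_per_gene(
    rna: ExpressionMatrix, protein: ExpressionMatrix, genes: Sequence[str]
) -> tuple[pd.Series, float]:
    """Per-gene Spearman rho between RNA and protein over shared samples.

    Ties use average ranks.  A gene with a constant vector in either matrix
    gets rho = NaN (flagged undefined) and is excluded from the mean with a
    warning.  Returns (per-gene rho, unweighted mean over defined genes).
    """
    shared = [s for s in rna.sample_ids if s in set(protein.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("spearman_per_gene requires >= 3 shared samples")
    genes = list(dict.fromkeys(genes))
    for name, M in (("rna", rna), ("protein", protein)):
        missing = [g for g in genes if g not in M.data.index]
        if missing:
            raise ValidationError(f"genes absent from {name} matrix: {missing[:10]}")
    rhos = {}
    n_undefined = 0
    for g in genes:
        x = rna.data.loc[g, shared].to_numpy(dtype=float)
        y = protein.data.loc[g, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rhos[g] = np.nan
            n_undefined += 1
            continue
        rhos[g] = float(stats.spearmanr(x, y).statistic)
    if n_undefined:
        log.warning("spearman_per_gene: %d gene(s) with constant vectors excluded from mean", n_undefined)
    series = pd.Series(rhos, name="spearman_rho")
    return series, float(series.dropna().mean())
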