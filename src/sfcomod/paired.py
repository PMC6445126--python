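"""Matched-pair differential expression between tissue states.

The per-patient log2 fold change of a gene is the difference of its log2
expression between the two conditions of the pair (e.g. tumor minus
normal); significance comes from a two-sided paired t-test and
Benjamini–Hochberg correction applied across exactly the tested gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError

log = logging.getLogger("sfcomod")


@dataclass
class PairedDesign:
    """Patient-matched sample pairs between two conditions."""

    pairs: pd.DataFrame  # columns: patient_id, sample_condition1, sample_condition2
    condition_names: tuple[str, str] = ("condition1", "condition2")

    def __post_init__(self) -> None:
        cols = {"patient_id", "sample_condition1", "sample_condition2"}
        if not cols <= set(self.pairs.columns):
            raise ValidationError(f"paired design requires columns {sorted(cols)}")
        used = pd.concat([self.pairs["sample_condition1"], self.pairs["sample_condition2"]])
        if used.duplicated().any():
            raise ValidationError("a sample appears in more than one pair")


def paired_log2fc(
    X: ExpressionMatrix, design: PairedDesign, genes: Sequence[str]
) -> pd.DataFrame:
    """Per-gene mean log2FC (condition2 - condition1), paired t-test and BH q.

    Pairs with a missing sample are dropped with a warning.  Genes whose
    per-patient differences have zero variance get an undefined (NaN)
    p-value and are excluded from the BH correction.
    """
    present = set(X.sample_ids)
    keep = design.pairs[
        design.pairs["sample_condition1"].isin(present)
        & design.pairs["sample_condition2"].isin(present)
    ]
    dropped = len(design.pairs) - len(keep)
    if dropped:
        log.warning("paired_log2fc: %d pair(s) dropped for missing samples", dropped)
    if len(keep) < 3:
        raise ValidationError("paired_log2fc requires >= 3 complete pairs")
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in set(X.gene_ids)]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:10]}")
    c1 = X.data.loc[genes, keep["sample_condition1"].tolist()].to_numpy(dtype=float)
    c2 = X.data.loc[genes, keep["sample_condition2"].tolist()].to_numpy(dtype=float)
    diffs = c2 - c1
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = sd == 0
    if zero_var.any():
        log.warning(
            "paired_log2fc: %d gene(s) with zero-variance differences; p undefined, "
            "excluded from BH", int(zero_var.sum()),
        )
        t = np.where(zero_var, np.nan, t)
        p = np.where(zero_var, np.nan, p)
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "mean_log2fc": mean,
            "t_statistic": t,
            "df": df,
            "p_value": p,
            "q_value": q,
        }
    )


def fold_change_summary(result: pd.DataFrame) -> dict[str, float]:
    """Summary statistics of the mean log2 fold-change distribution.

    The grand mean supports the question of whether the panel as a whole is
    shifted between conditions (near 0 means no net regulation).
    """
    if result.empty:
        raise ValidationError("fold_change_summary requires a non-empty result")
    fc = result["mean_log2fc"].to_numpy(dtype=float)
    quantiles = np.quantile(fc, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {
        "mean": float(fc.mean()),
        "sd": float(fc.std(ddof=1)) if fc.size > 1 else 0.0,
        "q05": float(quantiles[0]),
        "q25": float(quantiles[1]),
        "median": float(quantiles[2]),
        "q75": float(quantiles[3]),
        "q95": float(quantiles[4]),
        "n_genes": int(fc.size),
    }


def plot_fold_change_density(result: pd.DataFrame, path: str) -> None:
    """Density plot of mean log2 fold changes (matplotlib, written to file)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fc = result["mean_log2fc"].dropna()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    fc.plot.kde(ax=ax)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("mean log2 fold change")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
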