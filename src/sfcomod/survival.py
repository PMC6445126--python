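"""Module scoring, clinical group comparisons and median-split survival.

The per-patient module score is the arithmetic mean of log2 expression over
the module's genes.  Survival comparisons follow the median-split design:
patients above the median score form the high group, ties go to low, and
the two groups are compared with a two-sample log-rank test whose effect
size is reported as the O/E hazard ratio
``HR = (O_high / E_high) / (O_low / E_low)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SurvivalTable, ValidationError

log = logging.getLogger("sfcomod")


def module_score(X: ExpressionMatrix, module: Sequence[str], on_missing: str = "error") -> pd.Series:
    """Per-sample mean log2 expression over the module genes."""
    module = list(dict.fromkeys(module))
    missing = [g for g in module if g not in set(X.gene_ids)]
    if missing:
        if on_missing == "error":
            raise ValidationError(f"module genes absent from matrix: {missing[:10]}")
        log.warning("module_score: dropping %d absent gene(s)", len(missing))
        module = [g for g in module if g not in set(missing)]
    if not module:
        raise ValidationError("no module genes present in matrix")
    return X.data.loc[module].mean(axis=0).rename("module_score")


def median_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples; output rows have median 0.

    Idempotent: applying it twice equals applying it once.  Uses the
    midpoint convention for even sample counts.
    """
    med = X.data.median(axis=1)
    return ExpressionMatrix(X.data.sub(med, axis=0))


def compare_groups(values: pd.Series, labels: pd.Series) -> dict[str, float]:
    """Two groups: pooled-variance two-sided t-test; more: one-way ANOVA F.

    ``values`` and ``labels`` are aligned by index; every group needs at
    least 2 samples.
    """
    aligned = pd.DataFrame({"value": values, "label": labels}).dropna()
    groups = [grp["value"].to_numpy(dtype=float) for _, grp in aligned.groupby("label")]
    if len(groups) < 2:
        raise ValidationError("compare_groups requires >= 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValidationError("every group needs >= 2 samples")
    if len(groups) == 2:
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
        return {
            "test": "t",
            "statistic": float(t),
            "df": float(len(groups[0]) + len(groups[1]) - 2),
            "p_value": float(p),
        }
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return {"test": "anova", "statistic": float(f), "df": float(df1), "df2": float(df2), "p_value": float(p)}


def median_split(score: pd.Series) -> pd.Series:
    """Dichotomize at the median: strictly greater -> 'high', ties -> 'low'."""
    if len(score) < 4:
        raise ValidationError("median_split requires >= 4 samples")
    med = float(score.median())
    if score.nunique() == 1:
        raise ValidationError("all scores identical; no median split possible")
    labels = pd.Series(np.where(score > med, "high", "low"), index=score.index, name="group")
    if labels.nunique() < 2:
        raise ValidationError("median split produced an empty group")
    return labels


@dataclass
class KMResult:
    """Kaplan–Meier curves per group plus the log-rank test and O/E hazard ratio."""

    curves: dict[str, pd.DataFrame]     # group -> columns time, survival, at_risk, events
    chi_square: float
    p_value: float
    hazard_ratio: float                 # (O_high/E_high)/(O_low/E_low); NaN if undefined
    observed: dict[str, float]
    expected: dict[str, float]
    groups: tuple[str, str] = ("high", "low")


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = [(0.0, 1.0, len(time), 0)]
    surv = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((float(t), surv, at_risk, d))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "events"])


def logrank_km(survival: SurvivalTable, groups: pd.Series) -> KMResult:
    """Two-sample log-rank test with Kaplan–Meier curves and O/E hazard ratio.

    ``groups`` maps sample ids to exactly two labels; the hazard ratio is
    oriented as first-label-vs-second with labels sorted so 'high' comes
    first when present.  A group with zero events leaves the HR undefined
    (NaN) while the chi-square is still computed.
    """
    shared = [s for s in groups.index if s in set(survival.data.index)]
    if not shared:
        raise ValidationError("no shared samples between survival table and groups")
    groups = groups.loc[shared]
    labels = sorted(groups.unique(), key=lambda x: (x != "high", str(x)))
    if len(labels) != 2:
        raise ValidationError(f"logrank_km requires exactly 2 groups, got {list(labels)}")
    g1, g2 = labels
    time = survival.data.loc[shared, "time"].to_numpy(dtype=float)
    event = survival.data.loc[shared, "event"].to_numpy(dtype=int)
    in_g1 = (groups == g1).to_numpy()

    if event.sum() == 0:
        raise ValidationError("no events observed in either group")

    O1 = float(event[in_g1].sum())
    O2 = float(event[~in_g1].sum())
    E1 = 0.0
    V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & in_g1).sum())
        d = float(((time == t) & (event == 1)).sum())
        E1 += d * n1 / n
        if n > 1:
            V += d * (n - d) * n1 * (n - n1) / (n**2 * (n - 1))
    E2 = (O1 + O2) - E1
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    if O1 == 0 or O2 == 0 or E1 == 0 or E2 == 0:
        log.warning("logrank_km: a group has zero observed/expected events; HR undefined")
        hr = float("nan")
    else:
        hr = (O1 / E1) / (O2 / E2)
    curves = {
        g1: _km_curve(time[in_g1], event[in_g1]),
        g2: _km_curve(time[~in_g1], event[~in_g1]),
    }
    return KMResult(
        curves=curves,
        chi_square=float(chi2),
        p_value=p,
        hazard_ratio=hr,
        observed={g1: O1, g2: O2},
        expected={g1: E1, g2: E2},
        groups=(g1, g2),
    )
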