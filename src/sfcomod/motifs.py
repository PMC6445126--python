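"""Pscan-style promoter motif enrichment.

Each promoter window (default −50..+450 around the TSS) is scored with a
PWM converted to log-odds against background base frequencies; the best hit
over all window positions and both strands is min-max normalized to [0, 1].
A foreground gene set's mean best-hit score is compared to the background
universe's with a z statistic
``z = (mean_fg − mean_bg) / (sd_bg / sqrt(n_fg))`` and a one-tailed normal
p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PromoterSet, PWM, ValidationError

log = logging.getLogger("sfcomod")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

DEFAULT_WINDOW = (-50, 450)


def pwm_log_odds(
    pwm: PWM,
    background_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float | None = None,
) -> np.ndarray:
    """Log2-odds scoring matrix from a count PWM.

    entry(b, j) = log2((count(b,j) + pc * bg_b) / (col_total_j + pc)) - log2(bg_b).
    ``pseudocount=None`` uses 0.01 x the column total (per column).
    """
    bg = np.asarray(background_freqs, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise ValidationError("background_freqs must be 4 positive probabilities summing to 1")
    counts = pwm.counts
    totals = counts.sum(axis=0)
    if pseudocount is None:
        pc = 0.01 * totals
    else:
        if pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        pc = np.full_like(totals, float(pseudocount))
    if ((totals + pc) == 0).any():
        raise ValidationError("zero column total with zero pseudocount")
    with np.errstate(divide="ignore"):
        mat = np.log2((counts + pc[None, :] * bg[:, None]) / (totals + pc)[None, :]) - np.log2(bg)[:, None]
    if not np.isfinite(mat).all():
        raise ValidationError("log-odds matrix contains -inf; use a positive pseudocount")
    return mat


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValidationError(f"illegal base {exc.args[0]!r} in sequence") from None


def _scan_best(codes: np.ndarray, matrix5: np.ndarray) -> float:
    """Best summed score over all start positions of one strand.

    ``matrix5`` is the log-odds matrix extended with a 5th row holding each
    column's minimum (the score of an N base).
    """
    w = matrix5.shape[1]
    if len(codes) < w:
        raise ValidationError("window shorter than motif width")
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = matrix5[windows, np.arange(w)].sum(axis=1)
    return float(scores.max())


def best_promoter_score(
    seq: str,
    matrix: np.ndarray,
    window: tuple[int, int] = DEFAULT_WINDOW,
    offset_start: int | None = None,
) -> float:
    """Min-max normalized best log-odds hit over both strands of the window.

    ``seq`` is the promoter sequence; when ``offset_start`` is given, the
    subsequence covering TSS offsets ``window`` (inclusive) is extracted
    first, otherwise the whole sequence is scanned.  N positions score as
    the column minimum.  Returned scores always lie in [0, 1]; the
    normalization uses the analytic per-column min/max of the matrix, so a
    sequence containing the consensus scores exactly 1.
    """
    seq = seq.upper()
    if offset_start is not None:
        i = window[0] - offset_start
        if i < 0 or i + (window[1] - window[0] + 1) > len(seq):
            raise ValidationError("window not covered by sequence")
        seq = seq[i : i + (window[1] - window[0] + 1)]
    w = matrix.shape[1]
    if len(seq) < w:
        raise ValidationError("window shorter than motif width")
    col_min = matrix.min(axis=0)
    matrix5 = np.vstack([matrix, col_min])
    codes = _encode(seq)
    rc = _COMPLEMENT[codes][::-1]
    best = max(_scan_best(codes, matrix5), _scan_best(rc, matrix5))
    smin = float(col_min.sum())
    smax = float(matrix.max(axis=0).sum())
    if smax == smin:
        return 0.0
    return (best - smin) / (smax - smin)


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    fg_mean: float
    bg_mean: float
    bg_sd: float
    z: float
    p_value: float
    n_fg: int
    n_bg: int


def promoter_scores(
    promoters: PromoterSet,
    pwm: PWM,
    window: tuple[int, int] = DEFAULT_WINDOW,
    background_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float | None = None,
) -> pd.Series:
    """Best-hit score for every promoter in the set."""
    matrix = pwm_log_odds(pwm, background_freqs, pseudocount)
    scores = {
        gene: best_promoter_score(
            promoters.records[gene], matrix, window=window, offset_start=promoters.offset_start
        )
        for gene in promoters.records
    }
    return pd.Series(scores, name=pwm.motif_id)


def motif_z_enrichment(
    foreground: Sequence[str],
    promoters: PromoterSet,
    pwm: PWM,
    background: Sequence[str] | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    background_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float | None = None,
) -> MotifEnrichmentResult:
    """Pscan-style z-test of foreground vs background mean best-hit score.

    The background defaults to every promoter in the set (the foreground
    must be a subset of it).  z is invariant under affine rescaling applied
    identically to all scores.
    """
    fg = list(dict.fromkeys(foreground))
    bg = list(dict.fromkeys(background)) if background is not None else list(promoters.records)
    if not set(fg) <= set(bg):
        raise ValidationError("foreground must be a subset of the background universe")
    if len(fg) < 2:
        raise ValidationError("need >= 2 foreground promoters")
    if len(bg) < 10:
        raise ValidationError("need >= 10 background promoters")
    missing = [g for g in bg if g not in promoters.records]
    if missing:
        raise ValidationError(f"promoters missing for: {missing[:10]}")
    scores = promoter_scores(promoters, pwm, window, background_freqs, pseudocount)
    fg_scores = scores.loc[fg]
    bg_scores = scores.loc[bg]
    sd_bg = float(bg_scores.std(ddof=1))
    if sd_bg == 0:
        raise ValidationError("degenerate background: zero score variance")
    z = (float(fg_scores.mean()) - float(bg_scores.mean())) / (sd_bg / np.sqrt(len(fg)))
    p = float(stats.norm.sf(z))
    return MotifEnrichmentResult(
        motif_id=pwm.motif_id,
        fg_mean=float(fg_scores.mean()),
        bg_mean=float(bg_scores.mean()),
        bg_sd=sd_bg,
        z=float(z),
        p_value=p,
        n_fg=len(fg),
        n_bg=len(bg),
    )


def motif_enrichment_table(
    foreground: Sequence[str],
    promoters: PromoterSet,
    pwms: Sequence[PWM],
    **kwargs,
) -> pd.DataFrame:
    """Run the z-enrichment for a list of PWMs; one row per motif."""
    rows = [motif_z_enrichment(foreground, promoters, pwm, **kwargs) for pwm in pwms]
    return pd.DataFrame(
        [
            (r.motif_id, r.fg_mean, r.bg_mean, r.bg_sd, r.z, r.p_value, r.n_fg, r.n_bg)
            for r in rows
        ],
        columns=["motif_id", "fg_mean", "bg_mean", "bg_sd", "z", "p_value", "n_fg", "n_bg"],
    ).sort_values("p_value").reset_index(drop=True)
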