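"""LIBRA-seq scores (LSS) and combined LSS / signal-probability calls.

The LSS is the standard per-sample binding score: counts below a floor
(default 4) are zeroed as unreliable, each cell's counts are centered
log-ratio (CLR) transformed across the antigen panel, and each antigen
column is Z-scored across cells.  An LSS >= 1 conventionally calls
binding; combining it with the mixture-model signal posterior
(call = bind iff LSS >= 1 AND p_signal >= 0.9 by default) removes the
false positives that score highly only through inflated noise counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ScoreMatrix, UmiCountMatrix
from .errors import AlignmentError
from .mixture import PosteriorResult

logger = logging.getLogger(__name__)

__all__ = [
    "zero_low_counts",
    "clr_transform",
    "zscore_by_antigen",
    "compute_lss",
    "combine_calls",
]


def zero_low_counts(matrix: UmiCountMatrix, floor: int = 4) -> UmiCountMatrix:
    """Set entries strictly below ``floor`` to zero (LSS path only)."""
    if floor < 0:
        raise ValueError("floor must be >= 0")
    counts = matrix.counts.copy()
    counts[counts < floor] = 0
    return UmiCountMatrix(list(matrix.cell_ids), list(matrix.antigen_ids), counts)


def clr_transform(matrix: UmiCountMatrix, pseudocount: float = 1.0) -> ScoreMatrix:
    """Centered log-ratio per cell: ln(x + pc) minus the row mean of ln(x + pc)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logged = np.log(matrix.counts + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return ScoreMatrix(list(matrix.cell_ids), list(matrix.antigen_ids), centered)


def zscore_by_antigen(matrix: ScoreMatrix, ddof: int = 1) -> ScoreMatrix:
    """Z-score each antigen column across cells (sample sd by default).

    Zero-variance columns become all zeros with a warning; fewer than two
    cells is an error (a Z-score is undefined).
    """
    if len(matrix.cell_ids) < 2:
        raise ValueError("zscore_by_antigen requires >= 2 cells")
    x = matrix.scores
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    out = np.zeros_like(x)
    nonconstant = sd > 0
    out[:, nonconstant] = (x[:, nonconstant] - mean[nonconstant]) / sd[nonconstant]
    for j in np.flatnonzero(~nonconstant):
        logger.warning("antigen %r has zero variance; its Z-scores are set to 0",
                       matrix.antigen_ids[j])
    return ScoreMatrix(list(matrix.cell_ids), list(matrix.antigen_ids), out)


def compute_lss(matrix: UmiCountMatrix, floor: int = 4,
                pseudocount: float = 1.0, ddof: int = 1) -> ScoreMatrix:
    """Full LSS: zero_low_counts -> clr_transform -> zscore_by_antigen."""
    return zscore_by_antigen(clr_transform(zero_low_counts(matrix, floor),
                                           pseudocount), ddof)


def combine_calls(lss: ScoreMatrix, posteriors: dict[str, PosteriorResult],
                  lss_threshold: float = 1.0,
                  ps_threshold: float = 0.9) -> pd.DataFrame:
    """Per-(cell, antigen) binding calls: bind iff LSS >= t_lss AND p_signal >= t_ps.

    ``posteriors`` maps antigen id to a :class:`PosteriorResult` carrying
    cell ids.  Returns a long-format frame with columns (cell_id,
    antigen_id, lss, p_signal, call); only antigens present in both inputs
    are reported, and each posterior's cell set must be a subset of the
    score matrix's cells.
    """
    rows = []
    lss_cells = set(lss.cell_ids)
    for antigen_id, post in posteriors.items():
        if antigen_id not in lss.antigen_ids:
            raise AlignmentError(f"antigen {antigen_id!r} absent from score matrix")
        if post.cell_ids is None:
            raise AlignmentError(f"posterior for {antigen_id!r} lacks cell ids")
        missing = set(post.cell_ids) - lss_cells
        if missing:
            raise AlignmentError(
                f"{len(missing)} posterior cells absent from score matrix "
                f"(e.g. {sorted(missing)[0]!r})")
        col = pd.Series(lss.column(antigen_id), index=lss.cell_ids)
        for cell_id, p_s in zip(post.cell_ids, post.p_signal):
            score = float(col[cell_id])
            bind = (score >= lss_threshold) and (p_s >= ps_threshold)
            rows.append((cell_id, antigen_id, score, float(p_s),
                         "bind" if bind else "no_bind"))
    return pd.DataFrame(rows, columns=["cell_id", "antigen_id", "lss",
                                       "p_signal", "call"])
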