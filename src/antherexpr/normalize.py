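"""Two-step normalization for two-color arrays.

Within each array an intensity-dependent dye bias is removed by locally
weighted regression (loess) of M = log2(R/G) on A = (log2 R + log2 G)/2;
between arrays the column distributions are aligned, by default with
rank-mean quantile normalization.  Per-channel normalized intensities are
reconstructed from the corrected (M, A) pair so that downstream detection
thresholds operate on a normalized linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CHANNELS, ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_PROBES_FOR_LOESS = 50


@dataclass
class MAPair:
    """Per-probe M (log2 channel ratio) and A (mean log2 intensity) of one array."""

    probes: pd.Index
    M: np.ndarray
    A: np.ndarray
    array_id: str
    channel_order: tuple[str, str] = CHANNELS  # M = log2(first) - log2(second)


def ma_transform(matrix: ExpressionMatrix, array_id: str) -> MAPair:
    """M/A construction for one array; channel order is fixed as Cy5 over Cy3."""
    sub = matrix.samples[matrix.samples["array_id"] == array_id]
    if len(sub) != 2 or set(sub["channel"]) != set(CHANNELS):
        raise ValueError(
            f"array {array_id!r} must have exactly the two channels {CHANNELS}, got {list(sub['channel'])}"
        )
    by_channel = {ch: sid for sid, ch in sub["channel"].items()}
    log_r = np.log2(matrix.values[by_channel[CHANNELS[0]]].to_numpy())
    log_g = np.log2(matrix.values[by_channel[CHANNELS[1]]].to_numpy())
    return MAPair(matrix.probes, log_r - log_g, (log_r + log_g) / 2.0, array_id)


def ma_inverse(ma: MAPair) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the two linear channels from (M, A); exact inverse of ma_transform."""
    return 2.0 ** (ma.A + ma.M / 2.0), 2.0 ** (ma.A - ma.M / 2.0)


def within_array_loess(ma: MAPair, span: float = 0.4, iterations: int = 2) -> MAPair:
    """Subtract the loess fit of M on A (tricube weights, robustness iterations).

    A is unchanged.  Requires at least MIN_PROBES_FOR_LOESS probes for a
    stable fit.
    """
    n = len(ma.M)
    if n < MIN_PROBES_FOR_LOESS:
        raise ValueError(
            f"array {ma.array_id!r} has {n} probes; need >= {MIN_PROBES_FOR_LOESS} "
            "for a stable loess fit (skip within-array correction for tiny arrays)"
        )
    fit = lowess(ma.M, ma.A, frac=span, it=iterations, return_sorted=False)
    return MAPair(ma.probes, ma.M - fit, ma.A.copy(), ma.array_id, ma.channel_order)


def between_array_quantile(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rank-mean quantile normalization of log2 intensities across all columns.

    Every column's sorted values are mapped onto the across-column mean of
    sorted values; ties receive the mean of their positions' reference
    values (average ranks interpolated into the reference distribution).
    """
    if matrix.values.shape[1] < 2:
        logger.warning("quantile normalization with <2 columns is the identity")
        return ExpressionMatrix(matrix.values.copy(), matrix.samples.copy())
    log_v = np.log2(matrix.values.to_numpy(dtype=float))
    reference = np.sort(log_v, axis=0).mean(axis=1)
    n = log_v.shape[0]
    out = np.empty_like(log_v)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(log_v.shape[1]):
        ranks = rankdata(log_v[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    values = pd.DataFrame(2.0 ** out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.samples.copy())


def between_array_q75(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Upper-quartile scaling: each column scaled so its 75th percentile matches
    the geometric mean of the columns' 75th percentiles (literal 'quartile' reading)."""
    v = matrix.values.to_numpy(dtype=float)
    q = np.quantile(v, 0.75, axis=0)
    target = float(np.exp(np.mean(np.log(q))))
    values = pd.DataFrame(v * (target / q), index=matrix.values.index,
                          columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.samples.copy())


def normalize_experiment(
    matrix: ExpressionMatrix,
    span: float = 0.4,
    method: str = "q75",
    skip_loess: bool = False,
) -> ExpressionMatrix:
    """Full two-step normalization returning per-channel normalized intensities.

    Step 1 (per array): loess-correct M on A and reconstruct both channels.
    Step 2 (across arrays): distribution alignment, ``method`` one of
    "q75" (default, upper-quartile scaling: presence calls are invariant to
    per-column scaling) or "quantile" (rank-mean quantile normalization).
    """
    values = matrix.values.copy()
    if not skip_loess:
        for array_id in matrix.arrays():
            ma = within_array_loess(ma_transform(matrix, array_id), span=span)
            ch1, ch2 = ma_inverse(ma)
            sub = matrix.samples[matrix.samples["array_id"] == array_id]
            by_channel = {ch: sid for sid, ch in sub["channel"].items()}
            values[by_channel[CHANNELS[0]]] = ch1
            values[by_channel[CHANNELS[1]]] = ch2
    interim = ExpressionMatrix(values, matrix.samples.copy())
    if method == "quantile":
        logger.info("between-array alignment: quantile (rank-mean) normalization")
        return between_array_quantile(interim)
    if method == "q75":
        logger.info("between-array alignment: 75th-percentile scaling")
        return between_array_q75(interim)
    raise ValueError(f"unknown between-array method {method!r} (expected 'quantile' or 'q75')")
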