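"""Present/absent (ON/OFF) detection calls from negative-control statistics.

A probe measurement is scored ON when its intensity exceeds the mean plus
``multiplier`` (default 3.0) sample standard deviations of the same array
channel's negative-control foregrounds.  Per biological group (stage x
genotype x tissue) the fraction of ON measurements (the *support*) yields a
three-valued call: ON when support >= 0.75, OFF when support = 0, otherwise
AMBIGUOUS (excluded downstream).  Under a Gaussian background model the
expected false-ON rate of the rule is the standard-normal upper tail beyond
the multiplier, 0.13% at 3.0 SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_MULTIPLIER = 3.0
SUPPORT_THRESHOLD = 0.75
MIN_NEGATIVE_CONTROLS = 30

ON, OFF, AMBIGUOUS = "ON", "OFF", "AMBIGUOUS"


@dataclass
class DetectionThreshold:
    sample_id: str  # one array channel
    negctrl_mean: float
    negctrl_sd: float
    multiplier: float

    @property
    def threshold(self) -> float:
        return self.negctrl_mean + self.multiplier * self.negctrl_sd


def compute_threshold(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    sample_id: str,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> DetectionThreshold:
    """Negative-control mean + multiplier * sample SD for one array channel."""
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    neg = annotation.negative_controls
    if len(neg) < MIN_NEGATIVE_CONTROLS:
        raise ValueError(
            f"only {len(neg)} negative-control probes; need >= {MIN_NEGATIVE_CONTROLS}"
        )
    x = matrix.values.loc[neg, sample_id].to_numpy(dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        warnings.warn(f"negative-control SD is 0 on {sample_id}; threshold equals the mean")
    return DetectionThreshold(sample_id, float(np.mean(x)), sd, multiplier)


def compute_all_thresholds(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation, multiplier: float = DEFAULT_MULTIPLIER
) -> dict[str, DetectionThreshold]:
    return {
        sid: compute_threshold(matrix, annotation, sid, multiplier)
        for sid in matrix.values.columns
    }


def estimate_fdr(multiplier: float) -> float:
    """Analytic false-ON rate for null probes under the Gaussian background model.

    The upper-tail probability of a standard normal beyond ``multiplier``;
    at 3.0 this is 0.00135, which displays as 0.13%.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    return float(norm.sf(multiplier))


def empirical_null_rate(n_draws: int, multiplier: float, rng: np.random.Generator) -> float:
    """Fraction of simulated Gaussian null measurements scored ON.

    Draws ``n_draws`` null intensities and applies the mean + multiplier*SD
    rule with moments estimated from the draws themselves; converges to
    :func:`estimate_fdr` as n grows.
    """
    x = rng.standard_normal(n_draws)
    threshold = x.mean() + multiplier * x.std(ddof=1)
    return float(np.mean(x > threshold))


def call_detection(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    thresholds: dict[str, DetectionThreshold],
    group_by: tuple[str, ...] = ("stage", "genotype", "tissue"),
) -> pd.DataFrame:
    """Three-valued detection call per probe per biological group.

    Returns a long DataFrame with columns: probe, the ``group_by`` columns,
    n (replicate measurements), support (fraction ON), call.
    Negative-control probes are excluded from the output.
    """
    missing = [sid for sid in matrix.values.columns if sid not in thresholds]
    if missing:
        raise ValueError(f"samples without thresholds: {missing}")
    probes = annotation.regular_probes.intersection(matrix.probes)
    values = matrix.values.loc[probes]
    above = values.to_numpy() > np.array([thresholds[s].threshold for s in values.columns])

    groups = matrix.samples.loc[values.columns, list(group_by)]
    records = []
    for key, sub in groups.groupby(list(group_by), sort=False):
        cols = [values.columns.get_loc(s) for s in sub.index]
        if len(cols) == 0:
            raise ValueError(f"group {key} has no replicate measurements")
        support = above[:, cols].mean(axis=1)
        call = np.where(support >= SUPPORT_THRESHOLD, ON,
                        np.where(support == 0.0, OFF, AMBIGUOUS))
        df = pd.DataFrame({"probe": probes, "support": support, "call": call})
        df["n"] = len(cols)
        for name, val in zip(group_by, key if isinstance(key, tuple) else (key,)):
            df[name] = val
        records.append(df)
    out = pd.concat(records, ignore_index=True)
    return out[["probe", *group_by, "n", "support", "call"]]


def call_matrix(
    calls: pd.DataFrame,
    stage_order: list[str],
    genotype: str = "wild-type",
    tissue: str = "whole",
) -> pd.DataFrame:
    """Pivot the long call table to a probe x stage call matrix for one condition."""
    sub = calls
    if "genotype" in calls.columns:
        sub = sub[sub["genotype"] == genotype]
    if "tissue" in calls.columns:
        sub = sub[sub["tissue"] == tissue]
    wide = sub.pivot(index="probe", columns="stage", values="call")
    unknown = [s for s in stage_order if s not in wide.columns]
    if unknown:
        raise ValueError(f"stages missing from call table: {unknown}")
    return wide[stage_order]
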