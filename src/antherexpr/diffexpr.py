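"""Differential expression with fold-change plus p-value rules.

The standard contrast is 1.5-fold (|log2 ratio| >= log2 1.5 ~ 0.58) at
p <= 0.05 from a two-sided t-test on replicate log2 intensities; a bare
two-fold ratio-of-averages rule (no test) serves the constitutive
stage-series comparison and pathway flagging.  log2(1.5) is evaluated at
full precision; 0.58 is display rounding only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .patterns import constitutive_probes

logger = logging.getLogger(__name__)

UP, DOWN, NS = "UP", "DOWN", "NS"
DEFAULT_FOLD = 1.5
DEFAULT_ALPHA = 0.05
PATHWAY_FOLD = 2.0


def log2_fold_threshold(fold: float = DEFAULT_FOLD) -> float:
    """The log2 cutoff for a fold-change rule, e.g. 0.585 for 1.5-fold."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    return float(np.log2(fold))


def displayed_threshold(fold: float = DEFAULT_FOLD, decimals: int = 2) -> float:
    """log2 cutoff rounded for display (1.5-fold prints as 0.58)."""
    return round(log2_fold_threshold(fold), decimals)


def _classify(log2_ratio: np.ndarray, p: np.ndarray, fold: float, alpha: float) -> np.ndarray:
    cut = log2_fold_threshold(fold)
    sig = p <= alpha
    return np.where(sig & (log2_ratio >= cut), UP,
                    np.where(sig & (log2_ratio <= -cut), DOWN, NS))


def de_test(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    fold: float = DEFAULT_FOLD,
    alpha: float = DEFAULT_ALPHA,
    paired: bool = False,
    probes: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-probe differential test of condition A vs B (log2 A - log2 B).

    ``paired=True`` runs a one-sample t-test on per-array log2 ratios (the
    two conditions co-hybridized in the same order); otherwise a Welch
    two-sample t on log2 intensities.  Returns a probe-indexed DataFrame
    with columns log2_ratio, p_value, call; thresholds recorded in attrs.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        short = "A" if len(group_a) < 2 else "B"
        raise ValueError(f"group {short} has <2 replicates")
    idx = matrix.probes if probes is None else pd.Index(probes)
    a = np.log2(matrix.values.loc[idx, group_a].to_numpy(dtype=float))
    b = np.log2(matrix.values.loc[idx, group_b].to_numpy(dtype=float))
    ratio = a.mean(axis=1) - b.mean(axis=1)
    if paired:
        if len(group_a) != len(group_b):
            raise ValueError("paired test needs equal group sizes")
        _, p = stats.ttest_1samp(a - b, 0.0, axis=1)
    else:
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)  # zero-variance probes are never significant
    out = pd.DataFrame(
        {"log2_ratio": ratio, "p_value": p, "call": _classify(ratio, p, fold, alpha)},
        index=idx,
    )
    out.attrs["fold"] = fold
    out.attrs["alpha"] = alpha
    return out


def de_calls(result: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """(UP set, DOWN set) of a differential result."""
    return result.index[result["call"] == UP], result.index[result["call"] == DOWN]


def constitutive_de_series(
    matrix: ExpressionMatrix,
    patterns: pd.DataFrame,
    stage_order: list[str],
    fold: float = PATHWAY_FOLD,
    **criteria: str,
) -> dict[tuple[str, str], dict[str, pd.Index]]:
    """Fold-only UP/DOWN sets among constitutive probes per consecutive stage pair.

    Uses the ratio of stage-mean normalized intensities (no replicate test),
    matching the two-fold constitutive screen.  Keys are (previous, current).
    """
    const = constitutive_probes(patterns)
    cut = log2_fold_threshold(fold)
    means = {
        s: matrix.values.loc[const, matrix.sample_ids(stage=s, **criteria)].mean(axis=1)
        for s in stage_order
    }
    out: dict[tuple[str, str], dict[str, pd.Index]] = {}
    for prev, cur in zip(stage_order, stage_order[1:]):
        ratio = np.log2(means[cur]) - np.log2(means[prev])
        out[(prev, cur)] = {
            UP: const[ratio.to_numpy() >= cut],
            DOWN: const[ratio.to_numpy() <= -cut],
        }
    return out


def pathway_flags(
    changed_genes: set[str] | list[str],
    gene_set_map: dict[str, list[str]],
    rule: str = "any",
    fraction: float = 0.45,
) -> pd.DataFrame:
    """Flag gene sets containing changed/enriched members.

    rule="any" flags a set when >=1 mapped member changed; rule="fraction"
    when the changed fraction strictly exceeds ``fraction`` (e.g. the >45%
    zone-enrichment criterion).  Sets with zero mapped members are skipped
    with a warning.  Fraction = changed members / mapped members.
    """
    if rule not in ("any", "fraction"):
        raise ValueError(f"unknown rule {rule!r} (expected 'any' or 'fraction')")
    changed = set(changed_genes)
    rows = []
    for set_id, genes in gene_set_map.items():
        mapped = list(dict.fromkeys(genes))
        if not mapped:
            logger.warning("gene set %s has no mapped members; skipped", set_id)
            continue
        n_changed = sum(g in changed for g in mapped)
        frac = n_changed / len(mapped)
        flagged = n_changed >= 1 if rule == "any" else frac > fraction
        rows.append({"set_id": set_id, "n_mapped": len(mapped), "n_changed": n_changed,
                     "fraction": frac, "flagged": flagged})
    return pd.DataFrame(rows, columns=["set_id", "n_mapped", "n_changed", "fraction", "flagged"])
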