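"""Sequential marker filters and curated-list scoring.

Covers three analyses over the staged series and the mutant condition:

* a conjunctive sequential filter (e.g. pluripotency candidates: significant
  downregulation across the first two transitions, then low-or-OFF at all
  later stages);
* constitutive-fraction scoring of curated gene lists (a gene counts as
  constitutive when any of its probes is constitutively detected);
* mutant persistence of probes shut off in the wild type, and the overlap of
  mutant-vs-wild-type contrasts at two stages (direct-target candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import ON
from .diffexpr import DOWN, UP, log2_fold_threshold
from .io import ProbeAnnotation
from .patterns import CONSTITUTIVE_ON

logger = logging.getLogger(__name__)


@dataclass
class Criterion:
    """One step of a sequential marker filter.

    kind: "de" tests the log2 ratio and p-value of a transition's
    differential result; "call" tests the detection call at a stage;
    "low_or_off" requires call != ON or stage-mean intensity below the
    stage's lower quartile.
    """

    kind: str
    target: str | tuple[str, str]  # stage, or (prev, cur) transition
    relation: str = "log2_below"   # for kind="de": log2_below | log2_above
    threshold: float = -log2_fold_threshold(1.5)
    alpha: float = 0.05
    call: str = ON                 # for kind="call"


@dataclass
class MarkerFilterSpec:
    criteria: list[Criterion] = field(default_factory=list)


def pluripotency_spec(stage_order: list[str], fold: float = 1.5, alpha: float = 0.05) -> MarkerFilterSpec:
    """The three-step pluripotency-decline filter over a 5-stage series:
    significantly down across the first transition, down again across the
    second, then low-or-OFF at every stage after the third."""
    cut = log2_fold_threshold(fold)
    t1 = (stage_order[0], stage_order[1])
    t2 = (stage_order[1], stage_order[2])
    crits = [
        Criterion("de", t1, "log2_below", -cut, alpha),
        Criterion("de", t2, "log2_below", -cut, alpha),
    ]
    for s in stage_order[3:]:
        crits.append(Criterion("low_or_off", s))
    return MarkerFilterSpec(crits)


def _apply_criterion(
    probes: pd.Index,
    crit: Criterion,
    de_by_transition: dict[tuple[str, str], pd.DataFrame],
    call_matrix: pd.DataFrame,
    stage_intensity: dict[str, pd.Series] | None,
) -> pd.Index:
    if crit.kind == "de":
        if crit.target not in de_by_transition:
            raise ValueError(f"criterion references missing transition {crit.target}")
        de = de_by_transition[crit.target]
        sub = de.loc[de.index.intersection(probes)]
        sig = sub["p_value"] <= crit.alpha
        if crit.relation == "log2_below":
            keep = sig & (sub["log2_ratio"] < crit.threshold)
        elif crit.relation == "log2_above":
            keep = sig & (sub["log2_ratio"] > crit.threshold)
        else:
            raise ValueError(f"unknown relation {crit.relation!r}")
        return sub.index[keep]
    if crit.kind == "call":
        if crit.target not in call_matrix.columns:
            raise ValueError(f"criterion references missing stage {crit.target!r}")
        sub = call_matrix.loc[call_matrix.index.intersection(probes), crit.target]
        return sub.index[sub == crit.call]
    if crit.kind == "low_or_off":
        stage = crit.target
        if stage not in call_matrix.columns:
            raise ValueError(f"criterion references missing stage {stage!r}")
        idx = call_matrix.index.intersection(probes)
        not_on = call_matrix.loc[idx, stage] != ON
        if stage_intensity is not None and stage in stage_intensity:
            ref = stage_intensity[stage]
            q1 = float(np.quantile(ref.to_numpy(), 0.25))
            low = ref.loc[idx] < q1
            keep = not_on | low
        else:
            keep = not_on
        return idx[keep]
    raise ValueError(f"unknown criterion kind {crit.kind!r}")


def sequential_filter(
    de_by_transition: dict[tuple[str, str], pd.DataFrame],
    call_matrix: pd.DataFrame,
    spec: MarkerFilterSpec,
    universe: pd.Index | None = None,
    stage_intensity: dict[str, pd.Series] | None = None,
) -> list[pd.Index]:
    """Apply the criteria in order; returns the surviving set after each step.

    Sets are nested (each a subset of the previous).  The initial universe
    defaults to all probes of the call matrix.
    """
    surviving = call_matrix.index if universe is None else pd.Index(universe)
    out = []
    for crit in spec.criteria:
        surviving = _apply_criterion(surviving, crit, de_by_transition, call_matrix, stage_intensity)
        out.append(surviving)
    return out if spec.criteria else [surviving]


# ---------------------------------------------------------------------------
# curated-list scoring
# ---------------------------------------------------------------------------

def constitutive_fraction(
    gene_list: list[str],
    patterns: pd.DataFrame,
    annotation: ProbeAnnotation,
) -> dict:
    """Fraction of a curated gene list expressed constitutively.

    A gene is constitutive when at least one of its probes is labelled
    constitutive_on.  Genes with no probe on the array are reported as n_na
    and excluded from the denominator.  Percentage is rounded to one decimal
    and is NaN when no listed gene has a probe.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    const_probes = set(patterns.index[patterns["pattern"] == CONSTITUTIVE_ON])
    by_gene = annotation.probes_for_genes(gene_list)
    n_total = 0
    n_const = 0
    n_na = 0
    for gene in gene_list:
        probes = by_gene.get(gene, [])
        if not probes:
            n_na += 1
            continue
        n_total += 1
        if any(p in const_probes for p in probes):
            n_const += 1
    pct = round(100.0 * n_const / n_total, 1) if n_total else float("nan")
    return {"n_constitutive": n_const, "n_total": n_total, "n_na": n_na, "percentage": pct}


def array_coverage(gene_list: list[str], annotation: ProbeAnnotation) -> dict:
    """How much of a curated gene list is represented by at least one probe.

    Returns counts of represented/absent genes and the represented
    percentage (one decimal).
    """
    if not gene_list:
        raise ValueError("empty gene list")
    by_gene = annotation.probes_for_genes(gene_list)
    n_rep = sum(1 for g in gene_list if by_gene.get(g))
    return {"n_represented": n_rep, "n_total": len(gene_list),
            "percentage": round(100.0 * n_rep / len(gene_list), 1)}


def persistence_fraction(
    reference_probes: pd.Index | list[str],
    mutant_call_matrix: pd.DataFrame,
    stage: str,
) -> dict:
    """Fraction of a wild-type-derived probe set that stays ON in the mutant.

    ``reference_probes`` is typically the set shut off at ``stage`` in the
    wild type after being ON at the earlier stages (see
    :func:`antherexpr.patterns.off_after_on`).
    """
    ref = pd.Index(reference_probes)
    if len(ref) == 0:
        return {"n_on": 0, "n_total": 0, "percentage": float("nan")}
    calls = mutant_call_matrix.loc[mutant_call_matrix.index.intersection(ref), stage]
    n_on = int((calls == ON).sum())
    return {"n_on": n_on, "n_total": len(ref), "percentage": round(100.0 * n_on / len(ref), 1)}


def direct_target_overlap(
    de_early: pd.DataFrame, de_later: pd.DataFrame
) -> tuple[pd.Index, pd.Index]:
    """Probes differential in the same direction at both stages vs the same
    reference genotype: (shared DOWN, shared UP) — direct-target candidates."""
    down = de_early.index[de_early["call"] == DOWN].intersection(
        de_later.index[de_later["call"] == DOWN])
    up = de_early.index[de_early["call"] == UP].intersection(
        de_later.index[de_later["call"] == UP])
    return down, up
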