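"""Stage-pattern taxonomy over an ordered developmental series.

Each probe's call vector over the ordered stages is classified into
constitutive_on (ON everywhere), constitutive_off (detected nowhere),
stage_specific(s) (ON only at stage s), trough(s) (ON everywhere except
stage s) or other.  "Not detected" means call != ON, i.e. OFF and
AMBIGUOUS both count as not detected; probes missing a call at any stage
are labelled "excluded".  The transition ledger accounts for every probe
gained or lost between consecutive stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detect import ON
from .io import ExpressionMatrix

CONSTITUTIVE_ON = "constitutive_on"
CONSTITUTIVE_OFF = "constitutive_off"
OTHER = "other"
EXCLUDED = "excluded"


def label_stage_specific(stage: str) -> str:
    return f"stage_specific:{stage}"


def label_trough(stage: str) -> str:
    return f"trough:{stage}"


def classify_vector(on_vector: tuple[bool, ...], stages: list[str]) -> str:
    """Pattern label for one boolean detected-vector (brute-force rule)."""
    n_on = sum(on_vector)
    if n_on == len(stages):
        return CONSTITUTIVE_ON
    if n_on == 0:
        return CONSTITUTIVE_OFF
    if n_on == 1:
        return label_stage_specific(stages[on_vector.index(True)])
    if n_on == len(stages) - 1:
        return label_trough(stages[on_vector.index(False)])
    return OTHER


def classify_patterns(call_matrix: pd.DataFrame, stage_order: list[str]) -> pd.DataFrame:
    """Classify every probe's call vector; vectorized equivalent of classify_vector.

    ``call_matrix`` is probe x stage (as from :func:`antherexpr.detect.call_matrix`).
    Returns a DataFrame indexed by probe with columns ``pattern`` and
    ``anchor_stage`` (the defining stage for trough/stage-specific, else NA).
    """
    unknown = [s for s in stage_order if s not in call_matrix.columns]
    if unknown:
        raise ValueError(f"unknown stage(s) in order list: {unknown}")
    if len(stage_order) < 2:
        raise ValueError("need at least 2 stages")
    calls = call_matrix[stage_order]
    on = (calls == ON).to_numpy()
    has_call = calls.notna().all(axis=1).to_numpy()
    n_on = on.sum(axis=1)
    n_stages = len(stage_order)
    stages_arr = np.array(stage_order)

    pattern = np.full(len(calls), OTHER, dtype=object)
    anchor = np.full(len(calls), None, dtype=object)
    pattern[n_on == n_stages] = CONSTITUTIVE_ON
    pattern[n_on == 0] = CONSTITUTIVE_OFF
    single = n_on == 1
    if single.any():
        s = stages_arr[on[single].argmax(axis=1)]
        pattern[single] = [label_stage_specific(x) for x in s]
        anchor[single] = s
    # for a 2-stage series "ON at one stage" is stage-specific, not trough
    all_but_one = (n_on == n_stages - 1) & ~single
    if all_but_one.any():
        s = stages_arr[(~on[all_but_one]).argmax(axis=1)]
        pattern[all_but_one] = [label_trough(x) for x in s]
        anchor[all_but_one] = s
    pattern[~has_call] = EXCLUDED
    anchor[~has_call] = None
    return pd.DataFrame({"pattern": pattern, "anchor_stage": anchor}, index=calls.index)


def constitutive_probes(patterns: pd.DataFrame) -> pd.Index:
    return patterns.index[patterns["pattern"] == CONSTITUTIVE_ON]


def trough_probes(patterns: pd.DataFrame, stage: str) -> pd.Index:
    return patterns.index[patterns["pattern"] == label_trough(stage)]


def missing_only_at(call_matrix: pd.DataFrame, stage: str, stage_order: list[str]) -> pd.Index:
    """Probes not detected at ``stage`` but detected at every other stage.

    Named filter equivalent to the strict trough class; exposed separately
    because looser 'missing only here' universes (e.g. restricted to probes
    detected at the preceding stage) are also of interest.
    """
    on = call_matrix[stage_order] == ON
    others = [s for s in stage_order if s != stage]
    mask = (~on[stage]) & on[others].all(axis=1)
    return call_matrix.index[mask]


def off_after_on(call_matrix: pd.DataFrame, prior_stages: list[str], focal_stage: str) -> pd.Index:
    """Probes ON at every prior stage listed but not detected at the focal stage.

    This is the looser 'shut off at the focal stage' universe (no constraint
    on later stages), e.g. ON at 0.15 and 0.25 mm but OFF at 0.4 mm.
    """
    on = call_matrix == ON
    mask = on[prior_stages].all(axis=1) & ~on[focal_stage]
    return call_matrix.index[mask]


# ---------------------------------------------------------------------------
# transition accounting
# ---------------------------------------------------------------------------

def transition_ledger(call_matrix: pd.DataFrame, stage_order: list[str]) -> pd.DataFrame:
    """Per consecutive stage pair, the gain/loss accounting of detected probes.

    For each stage t the probes ON at t are split disjointly into
    ``shared`` (also ON at t-1), ``newly`` (not ON at t-1, not stage-specific)
    and ``stage_specific`` (ON only at t over the whole series); the three sum
    to |ON at t|.  ``lost`` counts probes ON at t-1 but not at t, split by
    their own category at t-1.  The first stage reports all its ON probes as
    newly (stage-specific still flagged separately).
    """
    unknown = [s for s in stage_order if s not in call_matrix.columns]
    if unknown:
        raise ValueError(f"unknown stage(s) in order list: {unknown}")
    on = (call_matrix[stage_order] == ON).to_numpy()
    n_on_total = on.sum(axis=1)
    specific = on & (n_on_total == 1)[:, None]  # ON only at that one stage

    rows = []
    prev_category: np.ndarray | None = None  # 0 shared, 1 newly, 2 specific
    for t, stage in enumerate(stage_order):
        on_t = on[:, t]
        spec_t = specific[:, t]
        if t == 0:
            shared = np.zeros_like(on_t)
            newly = on_t & ~spec_t
            lost = {"lost_shared": 0, "lost_newly": 0, "lost_stage_specific": 0, "lost_total": 0}
        else:
            on_prev = on[:, t - 1]
            shared = on_t & on_prev & ~spec_t
            newly = on_t & ~on_prev & ~spec_t
            lost_mask = on_prev & ~on_t
            lost = {
                "lost_shared": int((lost_mask & (prev_category == 0)).sum()),
                "lost_newly": int((lost_mask & (prev_category == 1)).sum()),
                "lost_stage_specific": int((lost_mask & (prev_category == 2)).sum()),
                "lost_total": int(lost_mask.sum()),
            }
        category = np.full(len(on_t), -1)
        category[shared] = 0
        category[newly] = 1
        category[spec_t] = 2
        rows.append({
            "stage": stage,
            "on_total": int(on_t.sum()),
            "shared": int(shared.sum()),
            "newly": int(newly.sum()),
            "stage_specific": int(spec_t.sum()),
            **lost,
        })
        prev_category = category
    return pd.DataFrame(rows)


def venn_three(call_matrix: pd.DataFrame, stages: tuple[str, str, str]) -> dict[str, int]:
    """Counts of the 7 membership regions of ON sets at three stages.

    Keys are '100', '010', '001', '110', '101', '011', '111' in the order of
    ``stages``; values sum to the size of the union of the three ON sets.
    """
    if len(set(stages)) != 3:
        raise ValueError(f"need three distinct stage labels, got {stages}")
    on = call_matrix[list(stages)] == ON
    regions = {}
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                if a + b + c == 0:
                    continue
                mask = (
                    (on[stages[0]] == bool(a))
                    & (on[stages[1]] == bool(b))
                    & (on[stages[2]] == bool(c))
                )
                regions[f"{a}{b}{c}"] = int(mask.sum())
    return regions


# ---------------------------------------------------------------------------
# intensity placement and annotation histograms
# ---------------------------------------------------------------------------

def stage_mean_intensity(matrix: ExpressionMatrix, stage: str, **criteria: str) -> pd.Series:
    """Per-probe mean of replicate normalized intensities at one stage."""
    cols = matrix.sample_ids(stage=stage, **criteria)
    if not cols:
        raise ValueError(f"no samples at stage {stage!r} matching {criteria}")
    return matrix.values[cols].mean(axis=1)


def intensity_placement(
    query_probes: pd.Index | list[str],
    reference: pd.Series,
    universe: pd.Index | None = None,
) -> dict:
    """Place a probe set within the intensity quartiles of a reference stage.

    ``reference`` maps probe -> stage-mean intensity; quartile boundaries are
    computed over ``universe`` (default: all probes in ``reference``).
    Returns counts/fractions below the median, in the lowest quartile, and
    per quartile bin.
    """
    query = pd.Index(query_probes)
    if len(query) == 0:
        return {"n": 0, "below_median": 0, "lowest_quartile": 0, "per_quartile": [0, 0, 0, 0],
                "frac_below_median": float("nan"), "frac_lowest_quartile": float("nan")}
    ref = reference if universe is None else reference.loc[universe]
    q1, q2, q3 = np.quantile(ref.to_numpy(), [0.25, 0.5, 0.75])
    x = reference.loc[query].to_numpy()
    per_quartile = [
        int((x <= q1).sum()),
        int(((x > q1) & (x <= q2)).sum()),
        int(((x > q2) & (x <= q3)).sum()),
        int((x > q3).sum()),
    ]
    below_median = int((x < q2).sum())
    return {
        "n": len(query),
        "below_median": below_median,
        "lowest_quartile": per_quartile[0],
        "per_quartile": per_quartile,
        "frac_below_median": below_median / len(query),
        "frac_lowest_quartile": per_quartile[0] / len(query),
    }


def reexpression_fraction(
    probes: pd.Index | list[str], call_matrix: pd.DataFrame, stage: str
) -> dict:
    """Fraction of a probe set detected (ON) at a given stage.

    Used to ask whether transcripts silent at a trough stage reappear at the
    following stage, or stay off permanently.
    """
    query = pd.Index(probes)
    if len(query) == 0:
        return {"n_on": 0, "n_total": 0, "percentage": float("nan")}
    on = (call_matrix.loc[call_matrix.index.intersection(query), stage] == ON).sum()
    return {"n_on": int(on), "n_total": len(query),
            "percentage": round(100.0 * int(on) / len(query), 1)}


def annotate_counts(
    probes: pd.Index | list[str], tags: dict[str, list[str]] | pd.Series
) -> tuple[dict[str, int], int]:
    """Histogram of annotation tags over a probe set.

    ``tags`` maps probe -> list of tags (or a Series of ';'-joined strings).
    Probes without any tag are excluded; their count is returned alongside.
    """
    if isinstance(tags, pd.Series):
        tags = {
            p: [t for t in str(v).split(";") if t]
            for p, v in tags.items()
            if pd.notna(v)
        }
    hist: dict[str, int] = {}
    untagged = 0
    for p in probes:
        plist = tags.get(p, [])
        if not plist:
            untagged += 1
            continue
        for t in plist:
            hist[t] = hist.get(t, 0) + 1
    return hist, untagged
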