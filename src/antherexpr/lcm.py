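"""Laser-capture-microdissection zone analysis at one stage.

Each dissected zone (archesporial cells AR, inner somatic ML/TAP, outer
somatic EPI/EN) is contrasted against equivalently staged whole anthers;
enriched probes are partitioned by zone sharing, probes depressed or absent
in every zone are assigned to non-lobe tissues (vasculature/connective),
transcription-factor families are tabulated per zone, and a trough set from
the whole-anther series can be spatially refined against the zone data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import ON
from .diffexpr import DOWN, UP, de_test
from .io import ExpressionMatrix

ZONES = ("AR", "ML/TAP", "EPI/EN")

DOWN_IN_ALL = "down_in_all_three"
ABSENT_ABOVE_MEDIAN = "absent_in_LCM_above_whole_median"


@dataclass
class ZoneEnrichment:
    """Per-zone differential results vs whole anther plus detection flags.

    ``de`` maps zone -> probe-indexed DataFrame (log2_ratio, p_value, call);
    ``enriched`` and ``detected`` are probe x zone boolean DataFrames.
    """

    de: dict[str, pd.DataFrame]
    enriched: pd.DataFrame
    detected: pd.DataFrame

    def enriched_in(self, zone: str) -> pd.Index:
        return self.enriched.index[self.enriched[zone]]

    def zone_partition(self) -> dict[str, pd.Index]:
        """Disjoint exhaustive partition of enriched probes by zone membership.

        Keys: each single zone, each unordered pair "Z1+Z2", and "all_three".
        """
        zones = list(self.enriched.columns)
        if not zones:
            return {"all_three": self.enriched.index[:0]}
        any_enriched = self.enriched.any(axis=1)
        counts = self.enriched.sum(axis=1)
        out: dict[str, pd.Index] = {}
        for z in zones:
            out[z] = self.enriched.index[self.enriched[z] & (counts == 1)]
        for i, z1 in enumerate(zones):
            for z2 in zones[i + 1:]:
                mask = self.enriched[z1] & self.enriched[z2] & (counts == 2)
                out[f"{z1}+{z2}"] = self.enriched.index[mask]
        out["all_three"] = self.enriched.index[counts == len(zones)]
        assert sum(len(v) for v in out.values()) == int(any_enriched.sum())
        return out


def enrichment_vs_whole(
    matrix: ExpressionMatrix,
    zone_samples: dict[str, list[str]],
    whole_samples: list[str],
    calls: pd.DataFrame | None = None,
    fold: float = 1.5,
    alpha: float = 0.05,
) -> ZoneEnrichment:
    """Zone-vs-whole differential expression for each dissected zone.

    A probe is *enriched* in a zone when it is UP vs whole at the fold/alpha
    rule and (when a call table is given) detected in that zone.  ``calls``
    is the long detection table; detection is looked up by tissue.
    """
    if not whole_samples:
        raise ValueError("missing whole-anther sample group")
    unknown = set(zone_samples) - set(ZONES)
    if unknown:
        raise ValueError(f"unknown zone label(s): {sorted(unknown)} (expected {ZONES})")
    de: dict[str, pd.DataFrame] = {}
    detected = pd.DataFrame(True, index=matrix.probes, columns=list(zone_samples))
    for zone, samples in zone_samples.items():
        de[zone] = de_test(matrix, samples, whole_samples, fold=fold, alpha=alpha)
        if calls is not None:
            sub = calls[calls["tissue"] == zone].set_index("probe")["call"]
            detected[zone] = (sub == ON).reindex(matrix.probes, fill_value=False)
    enriched = pd.DataFrame(
        {z: (de[z]["call"] == UP).reindex(matrix.probes, fill_value=False) & detected[z]
         for z in zone_samples},
        index=matrix.probes,
    )
    detected = detected.reindex(matrix.probes)
    return ZoneEnrichment(de, enriched, detected)


def nonlobe_assignment(
    enrichment: ZoneEnrichment,
    whole_on: pd.Index,
    whole_intensity: pd.Series,
) -> pd.DataFrame:
    """Assign probes to non-lobe tissues (vasculature and connective cells).

    Two disjoint reason classes, whose union is the assignment:

    * ``down_in_all_three`` — significantly DOWN vs whole in every zone;
    * ``absent_in_LCM_above_whole_median`` — detected in whole anther but in
      no zone, with whole-anther intensity above the median of detected
      whole-anther probes.

    Returns a DataFrame indexed by probe with a ``reason`` column.
    """
    zones = list(enrichment.de)
    down_all = None
    for z in zones:
        # DOWN is a statement about a detected transcript; absence is reason (ii)
        d = (enrichment.de[z]["call"] == DOWN) & enrichment.detected[z]
        down_all = d if down_all is None else (down_all & d)
    down_idx = down_all.index[down_all]

    absent_all = ~enrichment.detected[zones].any(axis=1)
    absent_idx = absent_all.index[absent_all].intersection(whole_on)
    median = float(np.median(whole_intensity.loc[whole_on].to_numpy()))
    absent_idx = absent_idx[whole_intensity.loc[absent_idx] > median]
    absent_idx = absent_idx.difference(down_idx)  # DOWN requires detection; guard anyway

    rows = pd.concat([
        pd.Series(DOWN_IN_ALL, index=down_idx),
        pd.Series(ABSENT_ABOVE_MEDIAN, index=absent_idx),
    ])
    return pd.DataFrame({"reason": rows})


def absent_set_placement(
    absent_probes: pd.Index | list[str],
    whole_on: pd.Index,
    whole_intensity: pd.Series,
) -> dict:
    """Where an absent-from-LCM set sits in the whole-anther intensity distribution.

    Quartile boundaries are computed over probes detected in whole anther;
    returns counts/fractions of the query set above the first quartile and
    above the median.
    """
    query = pd.Index(absent_probes)
    if len(query) == 0:
        return {"n": 0, "above_q1": 0, "above_median": 0,
                "pct_above_q1": float("nan"), "pct_above_median": float("nan")}
    ref = whole_intensity.loc[whole_on].to_numpy()
    q1, med = np.quantile(ref, [0.25, 0.5])
    x = whole_intensity.loc[query].to_numpy()
    above_q1 = int((x > q1).sum())
    above_med = int((x > med).sum())
    return {
        "n": len(query),
        "above_q1": above_q1,
        "above_median": above_med,
        "pct_above_q1": round(100.0 * above_q1 / len(query), 1),
        "pct_above_median": round(100.0 * above_med / len(query), 1),
    }


def family_tabulation(enrichment: ZoneEnrichment, families: pd.Series) -> pd.DataFrame:
    """Zone x family counts of exclusively-enriched probes.

    ``families`` maps probe -> family label (e.g. TF family); unlabelled
    probes are ignored.  Row sums equal the per-zone exclusive counts among
    labelled probes.
    """
    fam = families.dropna()
    fam = fam[fam != ""]
    partition = enrichment.zone_partition()
    zones = [z for z in partition if "+" not in z and z != "all_three"]
    all_families = sorted(fam.unique())
    table = pd.DataFrame(0, index=zones, columns=all_families, dtype=int)
    for z in zones:
        labelled = fam.loc[fam.index.intersection(partition[z])]
        for f, count in labelled.value_counts().items():
            table.loc[z, f] = int(count)
    return table


def trough_refinement(
    trough_probes: pd.Index | list[str],
    enrichment: ZoneEnrichment,
    later_on: pd.Index,
) -> pd.DataFrame:
    """Spatial fate at a later stage of probes silent at an earlier trough stage.

    Disjoint exhaustive partition of the trough set: ``off`` (not detected in
    whole anther at the later stage), ``no_enrichment`` (detected but enriched
    in no zone), one category per single zone, per zone pair and ``all_three``.
    Returns counts and fractions (fractions sum to 1).
    """
    trough = pd.Index(trough_probes)
    if len(trough) == 0:
        return pd.DataFrame(columns=["count", "fraction"])
    on = trough.intersection(later_on)
    off = trough.difference(later_on)
    partition = enrichment.zone_partition()
    rows: dict[str, int] = {"off": len(off)}
    assigned: pd.Index = pd.Index([])
    for key, members in partition.items():
        in_cat = on.intersection(members)
        rows[key] = len(in_cat)
        assigned = assigned.union(in_cat)
    rows["no_enrichment"] = len(on.difference(assigned))
    out = pd.DataFrame({"count": pd.Series(rows, dtype=int)})
    out["fraction"] = out["count"] / len(trough)
    assert int(out["count"].sum()) == len(trough)
    return out
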