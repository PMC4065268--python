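"""LCM zone enrichment, non-lobe assignment, TF families, trough fates.

Each dissected zone (AR, ML/TAP, EPI/EN) is contrasted against whole
anther at the same stage; enriched probes are partitioned by zone sharing,
probes depressed or absent in every zone are assigned to non-lobe tissues,
TF families are tabulated over exclusively-enriched probes, and the
placement of the absent set in the whole-anther distribution is reported.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import lcm_experiment, results_dir

from antherexpr import lcm


def main() -> None:
    run = lcm_experiment()
    out = results_dir()
    norm, calls, truth = run["norm"], run["calls"], run["truth"]

    zone_samples = {z: norm.sample_ids(tissue=z) for z in lcm.ZONES}
    whole = norm.sample_ids(tissue="whole")
    enrichment = lcm.enrichment_vs_whole(norm, zone_samples, whole, calls=calls)
    partition = enrichment.zone_partition()
    part_table = pd.Series({k: len(v) for k, v in partition.items()}, name="n_probes")
    part_table.to_csv(out / "06_zone_partition.tsv", sep="\t", index_label="region")
    print("enriched-probe partition by zone sharing:")
    print(part_table.to_string())

    wc = calls[calls["tissue"] == "whole"].set_index("probe")
    whole_on = wc.index[wc["call"] == "ON"]
    whole_intensity = norm.values[whole].mean(axis=1)
    assigned = lcm.nonlobe_assignment(enrichment, whole_on, whole_intensity)
    planted = truth.index[truth["zone"] == "non-lobe"]
    print(f"non-lobe assignment: {len(assigned)} probes "
          f"({assigned['reason'].value_counts().to_dict()}); "
          f"{len(assigned.index.intersection(planted))}/{len(planted)} planted recovered")

    absent = enrichment.detected.index[~enrichment.detected.any(axis=1)]
    absent = absent.intersection(whole_on)
    placement = lcm.absent_set_placement(absent, whole_on, whole_intensity)
    print(f"absent-from-LCM set (n={placement['n']}): "
          f"{placement['pct_above_q1']}% above Q1, "
          f"{placement['pct_above_median']}% above the whole-anther median")

    fam = run["annotation"].table["tf_family"].replace("", pd.NA)
    table = lcm.family_tabulation(enrichment, fam)
    table.to_csv(out / "06_tf_families.tsv", sep="\t", index_label="zone")

    # spatial fate of the planted zone-restricted + non-lobe probes
    refinement = lcm.trough_refinement(truth.index[truth["zone"] != "broad"],
                                       enrichment, whole_on)
    refinement.to_csv(out / "06_trough_refinement.tsv", sep="\t", index_label="category")

    summary = {"assigned_nonlobe": len(assigned),
               "planted_nonlobe": len(planted),
               "recovered": len(assigned.index.intersection(planted)),
               "absent_placement": placement}
    (out / "06_lcm_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
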