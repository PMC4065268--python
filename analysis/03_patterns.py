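"""Classify stage patterns, account for gains/losses, place the trough.

Produces the pattern-class table, the per-transition gain/loss ledger, the
three-stage overlap regions for the early and late halves of the series,
and the quartile placement of trough transcripts at the stage before their
trough (the study's signature: trough transcripts are low-abundance).
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import STAGES, results_dir, staged_experiment

from antherexpr import patterns


def main() -> None:
    run = staged_experiment()
    out = results_dir()
    cm, pat, norm = run["call_matrix"], run["patterns"], run["norm"]

    counts = pat["pattern"].value_counts().rename("n_probes")
    counts.to_csv(out / "03_pattern_counts.tsv", sep="\t", index_label="pattern")
    print("recovered pattern classes:")
    print(counts.to_string())

    ledger = patterns.transition_ledger(cm, STAGES)
    ledger.to_csv(out / "03_transition_ledger.tsv", sep="\t", index=False)

    venns = {"early": patterns.venn_three(cm, ("0.15", "0.25", "0.4")),
             "late": patterns.venn_three(cm, ("0.4", "0.7", "1.0"))}
    (out / "03_venn_regions.json").write_text(json.dumps(venns, indent=2))
    print(f"common to 0.15/0.25/0.4: {venns['early']['111']}; "
          f"common to 0.4/0.7/1.0: {venns['late']['111']}")

    trough = patterns.trough_probes(pat, "0.4")
    ref = patterns.stage_mean_intensity(norm, "0.25", genotype="wild-type", tissue="whole")
    expressed = cm.index[cm["0.25"] == "ON"]
    placement = patterns.intensity_placement(trough, ref, universe=expressed)
    re_expr = patterns.reexpression_fraction(trough, cm, "0.7")
    summary = {
        "n_trough_04": placement["n"],
        "below_median_at_025": placement["below_median"],
        "lowest_quartile_at_025": placement["lowest_quartile"],
        "pct_below_median": round(100 * placement["frac_below_median"], 1),
        "pct_lowest_quartile": round(100 * placement["frac_lowest_quartile"], 1),
        "reexpressed_at_07_pct": re_expr["percentage"],
    }
    (out / "03_trough_placement.json").write_text(json.dumps(summary, indent=2))
    print(f"trough at 0.4 mm: {summary['n_trough_04']} probes, "
          f"{summary['pct_below_median']}% below the 0.25 mm median, "
          f"{summary['reexpressed_at_07_pct']}% re-expressed at 0.7 mm")


if __name__ == "__main__":
    main()
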