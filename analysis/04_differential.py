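"""Two-fold screening of constitutive transcripts and pathway flagging.

Among constitutively detected probes, consecutive-stage ratios of mean
normalized intensities are screened at two-fold; synthetic gene sets built
from the probe annotation are then flagged under the any-member and the
>45%-of-members rules.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import STAGES, results_dir, staged_experiment

from antherexpr import diffexpr


def main() -> None:
    run = staged_experiment()
    out = results_dir()

    series = diffexpr.constitutive_de_series(
        run["norm"], run["patterns"], STAGES, genotype="wild-type", tissue="whole")
    rows = [{"previous": prev, "current": cur,
             "n_up": len(sets["UP"]), "n_down": len(sets["DOWN"])}
            for (prev, cur), sets in series.items()]
    table = pd.DataFrame(rows)
    table.to_csv(out / "04_constitutive_twofold.tsv", sep="\t", index=False)
    print("two-fold changes among constitutive transcripts per transition:")
    print(table.to_string(index=False))

    # synthetic pathways: random gene sets over the annotated genes
    rng = np.random.default_rng(4)
    genes = list(run["annotation"].gene_map())
    gene_sets = {f"pwy{k:03d}": list(rng.choice(genes, rng.integers(5, 25), replace=False))
                 for k in range(40)}
    changed = set()
    gene_map = run["annotation"].gene_map()
    for sets in series.values():
        for idx in sets.values():
            changed |= set(gene_map.reindex(idx).dropna())
    flags_any = diffexpr.pathway_flags(changed, gene_sets, rule="any")
    flags_any.to_csv(out / "04_pathway_flags_any.tsv", sep="\t", index=False)
    flags_frac = diffexpr.pathway_flags(changed, gene_sets, rule="fraction", fraction=0.45)
    flags_frac.to_csv(out / "04_pathway_flags_frac45.tsv", sep="\t", index=False)
    print(f"{int(flags_any['flagged'].sum())}/40 sets flagged under any-member; "
          f"{int(flags_frac['flagged'].sum())}/40 under the >45% rule "
          f"(log2 1.5-fold cutoff displays as {diffexpr.displayed_threshold(1.5)})")


if __name__ == "__main__":
    main()
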