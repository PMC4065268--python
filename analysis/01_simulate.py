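"""Generate the synthetic staged-anther experiment and tabulate its design.

Emulates the study structure: five ordered stages (0.15-1.0 mm), balanced
dye-swap loops, a mac1 mutant condition co-hybridized at two stages, 100
negative-control probes, and planted pattern classes.  Writes the planted
class counts and the sample layout; the full matrix goes to scratch/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import SCRATCH, results_dir, staged_experiment

from antherexpr import io


def main() -> None:
    run = staged_experiment()
    out = results_dir()
    (SCRATCH / "sim").mkdir(parents=True, exist_ok=True)
    io.write_matrix(run["matrix"], SCRATCH / "sim" / "matrix.tsv",
                    SCRATCH / "sim" / "samples.tsv")
    io.write_annotation(run["annotation"], SCRATCH / "sim" / "probes.tsv")
    run["truth"].to_csv(SCRATCH / "sim" / "truth.tsv", sep="\t", index_label="probe_id")

    counts = run["truth"]["pattern"].value_counts().rename("n_probes")
    counts.to_csv(out / "01_truth_class_counts.tsv", sep="\t", index_label="pattern")
    layout = (run["matrix"].samples.groupby(["stage", "genotype"])
              .size().rename("n_measurements").reset_index())
    layout.to_csv(out / "01_sample_layout.tsv", sep="\t", index=False)

    print(f"simulated {len(run['truth'])} probes x {run['matrix'].values.shape[1]} "
          f"sample channels over {len(run['matrix'].arrays())} arrays")
    print(counts.to_string())


if __name__ == "__main__":
    main()
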