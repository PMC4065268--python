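"""Shared fixtures: simulated experiments are expensive, so the staged
whole-anther run and the LCM run are session-scoped and reused by the
module tests and the acceptance suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from antherexpr import detect, lcm, normalize, patterns
from antherexpr.io import ExpressionMatrix, ProbeAnnotation
from antherexpr.simulate import SimulationConfig, generate_experiment, generate_lcm_experiment


@pytest.fixture(scope="session")
def staged_run():
    """Default-condition staged experiment, fully processed (seed 1)."""
    config = SimulationConfig(n_probes=2000, seed=1)
    matrix, annotation, truth = generate_experiment(config)
    norm = normalize.normalize_experiment(matrix)
    thresholds = detect.compute_all_thresholds(norm, annotation)
    calls = detect.call_detection(norm, annotation, thresholds)
    cm = detect.call_matrix(calls, list(config.stages))
    pattern_table = patterns.classify_patterns(cm, list(config.stages))
    return {
        "config": config, "matrix": matrix, "annotation": annotation, "truth": truth,
        "norm": norm, "thresholds": thresholds, "calls": calls,
        "call_matrix": cm, "patterns": pattern_table,
    }


@pytest.fixture(scope="session")
def lcm_run():
    """LCM zone-vs-whole experiment, processed through enrichment (seed 2)."""
    config = SimulationConfig(n_probes=1000, seed=2)
    zone_fractions = {"AR": 0.3, "ML/TAP": 0.3, "EPI/EN": 0.3, "non-lobe": 0.1}
    matrix, annotation, truth = generate_lcm_experiment(config, zone_fractions)
    norm = normalize.normalize_experiment(matrix)
    calls = detect.call_detection(norm, annotation,
                                  detect.compute_all_thresholds(norm, annotation))
    zone_samples = {z: norm.sample_ids(tissue=z) for z in lcm.ZONES}
    whole_samples = norm.sample_ids(tissue="whole")
    enrichment = lcm.enrichment_vs_whole(norm, zone_samples, whole_samples, calls=calls)
    whole_calls = calls[calls["tissue"] == "whole"].set_index("probe")
    whole_on = whole_calls.index[whole_calls["call"] == "ON"]
    whole_intensity = norm.values[whole_samples].mean(axis=1)
    return {
        "config": config, "truth": truth, "norm": norm, "calls": calls,
        "enrichment": enrichment, "whole_on": whole_on,
        "whole_intensity": whole_intensity, "annotation": annotation,
    }


def tiny_matrix(values: np.ndarray, n_arrays: int, stage: str = "0.4") -> ExpressionMatrix:
    """Helper: probe x (2*n_arrays) matrix with one stage, dye-swapped pairs."""
    n_probes = values.shape[0]
    cols, meta = [], {}
    for a in range(n_arrays):
        for ch in ("Cy5", "Cy3"):
            sid = f"A{a:02d}.{ch}"
            cols.append(sid)
            meta[sid] = {"array_id": f"A{a:02d}", "channel": ch, "stage": stage,
                         "genotype": "wild-type", "tissue": "whole",
                         "replicate": 2 * a + (1 if ch == "Cy5" else 2)}
    probes = pd.Index([f"P{i:04d}" for i in range(n_probes)], name="probe_id")
    return ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=cols),
        pd.DataFrame.from_dict(meta, orient="index"),
    )


def annotation_for(matrix: ExpressionMatrix, negctrl: list[str] | None = None) -> ProbeAnnotation:
    negctrl = set(negctrl or [])
    t = pd.DataFrame({
        "gene_id": ["" if p in negctrl else f"G{p}" for p in matrix.probes],
        "is_negative_control": [p in negctrl for p in matrix.probes],
        "tf_family": "",
        "tags": "",
    }, index=matrix.probes)
    return ProbeAnnotation(t)
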