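"""Shared setup for the numbered analysis drivers.

Each driver regenerates the synthetic experiments deterministically (fixed
seeds) so the scripts can run independently and in any order; heavyweight
intermediates go under scratch/, small summary tables under results/.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

from antherexpr import detect, normalize, patterns
from antherexpr.simulate import SimulationConfig, generate_experiment, generate_lcm_experiment

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STAGED_SEED = 11
LCM_SEED = 12

STAGES = ["0.15", "0.25", "0.4", "0.7", "1.0"]


@lru_cache(maxsize=1)
def staged_experiment():
    """The staged whole-anther experiment, processed through classification."""
    config = SimulationConfig(n_probes=2000, seed=STAGED_SEED)
    matrix, annotation, truth = generate_experiment(config)
    norm = normalize.normalize_experiment(matrix)
    calls = detect.call_detection(norm, annotation,
                                  detect.compute_all_thresholds(norm, annotation))
    cm = detect.call_matrix(calls, STAGES)
    pattern_table = patterns.classify_patterns(cm, STAGES)
    return {
        "config": config, "matrix": matrix, "annotation": annotation, "truth": truth,
        "norm": norm, "calls": calls, "call_matrix": cm, "patterns": pattern_table,
    }


@lru_cache(maxsize=1)
def lcm_experiment():
    config = SimulationConfig(n_probes=1000, seed=LCM_SEED)
    matrix, annotation, truth = generate_lcm_experiment(
        config, {"AR": 0.3, "ML/TAP": 0.3, "EPI/EN": 0.3, "non-lobe": 0.1})
    norm = normalize.normalize_experiment(matrix)
    calls = detect.call_detection(norm, annotation,
                                  detect.compute_all_thresholds(norm, annotation))
    return {"config": config, "truth": truth, "norm": norm, "calls": calls,
            "annotation": annotation}


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
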