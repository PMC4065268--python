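"""Sequential marker filters, curated-list scoring, mutant persistence."""

import numpy as np
import pandas as pd
import pytest

from antherexpr import detect, markers, normalize
from antherexpr.detect import OFF, ON, call_detection, call_matrix, compute_all_thresholds
from antherexpr.io import ProbeAnnotation
from antherexpr.markers import (Criterion, MarkerFilterSpec, array_coverage,
                                constitutive_fraction, direct_target_overlap,
                                persistence_fraction, pluripotency_spec,
                                sequential_filter)
from antherexpr.simulate import SimulationConfig, default_pattern_fractions, generate_experiment

STAGES = ["0.15", "0.25", "0.4", "0.7", "1.0"]


def _de(table: dict[str, tuple[float, float]]) -> pd.DataFrame:
    idx = pd.Index(list(table))
    return pd.DataFrame({
        "log2_ratio": [v[0] for v in table.values()],
        "p_value": [v[1] for v in table.values()],
    }, index=idx)


def _calls(rows: dict[str, list[str]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=STAGES)


def test_empty_universe_stays_empty():
    spec = pluripotency_spec(STAGES)
    de = {("0.15", "0.25"): _de({}), ("0.25", "0.4"): _de({})}
    cm = _calls({})
    steps = sequential_filter(de, cm, spec, universe=pd.Index([]))
    assert all(len(s) == 0 for s in steps)


def test_no_criteria_is_identity():
    cm = _calls({"P0": [ON] * 5})
    steps = sequential_filter({}, cm, MarkerFilterSpec([]))
    assert list(steps[-1]) == ["P0"]


def test_missing_transition_rejected():
    spec = MarkerFilterSpec([Criterion("de", ("0.4", "0.7"))])
    with pytest.raises(ValueError, match="missing transition"):
        sequential_filter({}, _calls({"P0": [ON] * 5}), spec)


def test_constructed_filter_recovers_planted_and_rejects_decoys():
    """25 planted decline probes pass all three criteria; each decoy family
    fails exactly one step and is removed there."""
    planted = [f"T{i}" for i in range(25)]
    decoy1 = [f"D1_{i}" for i in range(5)]   # not down at transition 1
    decoy2 = [f"D2_{i}" for i in range(5)]   # not down at transition 2
    decoy3 = [f"D3_{i}" for i in range(5)]   # stays ON later
    de1 = _de({**{p: (-1.0, 0.001) for p in planted + decoy2 + decoy3},
               **{p: (0.2, 0.5) for p in decoy1}})
    de2 = _de({**{p: (-1.0, 0.001) for p in planted + decoy1 + decoy3},
               **{p: (0.1, 0.8) for p in decoy2}})
    calls = _calls({**{p: [ON, ON, OFF, OFF, OFF] for p in planted + decoy1 + decoy2},
                    **{p: [ON, ON, ON, ON, ON] for p in decoy3}})
    spec = pluripotency_spec(STAGES)
    steps = sequential_filter({("0.15", "0.25"): de1, ("0.25", "0.4"): de2}, calls, spec)
    assert set(steps[0]) == set(planted + decoy2 + decoy3)
    assert set(steps[1]) == set(planted + decoy3)
    assert set(steps[-1]) == set(planted)


def test_steps_are_nested(staged_run):
    """On real simulated output the surviving sets shrink monotonically."""
    norm, cm = staged_run["norm"], staged_run["call_matrix"]
    from antherexpr.diffexpr import de_test
    de = {}
    for prev, cur in zip(STAGES, STAGES[1:]):
        ga = norm.sample_ids(stage=cur, genotype="wild-type", tissue="whole")
        gb = norm.sample_ids(stage=prev, genotype="wild-type", tissue="whole")
        de[(prev, cur)] = de_test(norm, ga, gb)
    steps = sequential_filter(de, cm, pluripotency_spec(STAGES))
    for a, b in zip(steps, steps[1:]):
        assert set(b) <= set(a)


def test_pipeline_recovers_planted_pluripotency_probes(staged_run):
    """Most planted decline probes survive the full three-step filter."""
    norm, cm, truth = staged_run["norm"], staged_run["call_matrix"], staged_run["truth"]
    from antherexpr.diffexpr import de_test
    de = {}
    for prev, cur in zip(STAGES, STAGES[1:]):
        ga = norm.sample_ids(stage=cur, genotype="wild-type", tissue="whole")
        gb = norm.sample_ids(stage=prev, genotype="wild-type", tissue="whole")
        de[(prev, cur)] = de_test(norm, ga, gb)
    steps = sequential_filter(de, cm, pluripotency_spec(STAGES))
    planted = set(truth.index[truth["pattern"] == "pluripotency_decline"])
    recovered = planted & set(steps[-1])
    assert len(recovered) >= 0.9 * len(planted)
    # constitutive probes do not slip through
    const = set(truth.index[truth["pattern"] == "constitutive_on"])
    assert len(const & set(steps[-1])) == 0


# ---------------------------------------------------------------------------
# curated-list scoring
# ---------------------------------------------------------------------------

def _annotation(gene_to_probe: dict[str, str | None]) -> ProbeAnnotation:
    rows = {}
    for i, (gene, probe) in enumerate(gene_to_probe.items()):
        if probe is not None:
            rows[probe] = {"gene_id": gene, "is_negative_control": False,
                           "tf_family": "", "tags": ""}
    columns = ["gene_id", "is_negative_control", "tf_family", "tags"]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns) \
        if rows else pd.DataFrame(columns=columns)
    return ProbeAnnotation(table)


def test_constitutive_fraction_printed_example():
    """172 constitutive of 222 annotated genes scores 77.5%."""
    genes = [f"G{i}" for i in range(222)]
    ann = _annotation({g: f"P{i}" for i, g in enumerate(genes)})
    pat = pd.DataFrame({"pattern": ["constitutive_on"] * 172 + ["other"] * 50},
                       index=[f"P{i}" for i in range(222)])
    out = constitutive_fraction(genes, pat, ann)
    assert out == {"n_constitutive": 172, "n_total": 222, "n_na": 0, "percentage": 77.5}


def test_constitutive_fraction_zero_and_na_cases():
    genes = [f"G{i}" for i in range(10)]
    ann = _annotation({g: f"P{i}" for i, g in enumerate(genes)})
    pat = pd.DataFrame({"pattern": ["other"] * 10}, index=[f"P{i}" for i in range(10)])
    assert constitutive_fraction(genes, pat, ann)["percentage"] == 0.0
    # no gene on the array: defined result, undefined percentage
    missing = _annotation({})
    out = constitutive_fraction(genes, pat, missing)
    assert out["n_total"] == 0 and out["n_na"] == 10 and np.isnan(out["percentage"])


def test_constitutive_fraction_any_probe_rule():
    ann = ProbeAnnotation(pd.DataFrame({
        "gene_id": ["G0", "G0"], "is_negative_control": [False, False],
        "tf_family": ["", ""], "tags": ["", ""]}, index=["Pa", "Pb"]))
    pat = pd.DataFrame({"pattern": ["other", "constitutive_on"]}, index=["Pa", "Pb"])
    assert constitutive_fraction(["G0"], pat, ann)["n_constitutive"] == 1


def test_complementary_fractions_sum_to_100(staged_run):
    truth, pat, ann = staged_run["truth"], staged_run["patterns"], staged_run["annotation"]
    genes = list(ann.gene_map().loc[truth.index[:500]])
    out = constitutive_fraction(genes, pat, ann)
    non_const = out["n_total"] - out["n_constitutive"]
    assert out["percentage"] + round(100 * non_const / out["n_total"], 1) == pytest.approx(100.0, abs=0.1)


def test_array_coverage():
    genes = [f"G{i}" for i in range(2298)]
    ann = _annotation({g: (f"P{i}" if i < 1208 else None) for i, g in enumerate(genes)})
    out = array_coverage(genes, ann)
    assert out == {"n_represented": 1208, "n_total": 2298, "percentage": 52.6}


# ---------------------------------------------------------------------------
# mutant persistence and direct targets
# ---------------------------------------------------------------------------

def test_persistence_printed_example():
    """3252 of 3871 reference probes ON in the mutant gives 84.0%."""
    probes = [f"P{i}" for i in range(3871)]
    mutant_cm = pd.DataFrame(
        {"0.4": [ON] * 3252 + [OFF] * 619}, index=probes)
    out = persistence_fraction(probes, mutant_cm, "0.4")
    assert out["n_on"] == 3252 and out["percentage"] == 84.0


def test_persistence_empty_reference():
    out = persistence_fraction([], pd.DataFrame({"0.4": []}), "0.4")
    assert out["n_total"] == 0 and np.isnan(out["percentage"])


def test_mutant_retention_recovered_from_simulation():
    """Planting 80% retention over ~500 trough probes, the recovered
    persistence fraction lands in the binomial band (75%, 85%)."""
    fractions = default_pattern_fractions()
    fractions["trough:0.4"] = 0.25
    fractions["constitutive_on"] = 0.33
    config = SimulationConfig(n_probes=2000, seed=4, mutant_retention=0.80,
                              pattern_fractions=fractions)
    matrix, ann, truth = generate_experiment(config)
    norm = normalize.normalize_experiment(matrix)
    calls = call_detection(norm, ann, compute_all_thresholds(norm, ann))
    mut_cm = call_matrix(calls, ["0.25", "0.4"], genotype="mac1")
    planted = truth.index[truth["pattern"] == "trough:0.4"]
    out = persistence_fraction(planted, mut_cm, "0.4")
    assert out["n_total"] == 500
    assert 75.0 < out["percentage"] < 85.0


def test_direct_target_overlap_oracle():
    rng = np.random.default_rng(9)
    probes = [f"P{i}" for i in range(300)]
    def rand_de():
        calls = rng.choice(["UP", "DOWN", "NS"], 300)
        return pd.DataFrame({"call": calls, "log2_ratio": 0.0, "p_value": 1.0}, index=probes)
    a, b = rand_de(), rand_de()
    down, up = direct_target_overlap(a, b)
    assert set(down) == {p for p in probes
                         if a.loc[p, "call"] == "DOWN" and b.loc[p, "call"] == "DOWN"}
    assert set(up) == {p for p in probes
                       if a.loc[p, "call"] == "UP" and b.loc[p, "call"] == "UP"}


def test_planted_direct_targets_recovered(staged_run):
    """Pluripotency-decline probes stay elevated in the mutant at both
    profiled stages, so they surface as shared UP candidates."""
    from antherexpr.diffexpr import de_test
    norm, truth = staged_run["norm"], staged_run["truth"]

    def contrast(stage):
        mut = norm.sample_ids(stage=stage, genotype="mac1")
        arrays = [norm.samples.loc[s, "array_id"] for s in mut]
        wt = [next(s for s in norm.sample_ids(stage=stage, genotype="wild-type")
                   if norm.samples.loc[s, "array_id"] == a) for a in arrays]
        return de_test(norm, mut, wt, paired=True)

    down, up = direct_target_overlap(contrast("0.25"), contrast("0.4"))
    planted = set(truth.index[truth["pattern"] == "pluripotency_decline"])
    assert len(planted & set(up)) >= 0.9 * len(planted)
    # trough probes retained only at the focal stage do not share both contrasts
    trough = set(truth.index[truth["pattern"] == "trough:0.4"])
    assert len(trough & set(up)) == 0


def test_direct_target_trivial_cases():
    de_a = pd.DataFrame({"call": ["DOWN", "UP"]}, index=["P0", "P1"])
    de_b = pd.DataFrame({"call": ["NS", "NS"]}, index=["P0", "P1"])
    down, up = direct_target_overlap(de_a, de_b)
    assert len(down) == 0 and len(up) == 0
    down, up = direct_target_overlap(de_a, de_a)
    assert list(down) == ["P0"] and list(up) == ["P1"]
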