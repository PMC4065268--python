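"""Stage-pattern taxonomy, transition ledger, Venn regions, placements."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antherexpr import patterns
from antherexpr.detect import AMBIGUOUS, OFF, ON
from antherexpr.patterns import (annotate_counts, classify_patterns, classify_vector,
                                 intensity_placement, missing_only_at, off_after_on,
                                 reexpression_fraction, transition_ledger, venn_three)


def _cm(vectors, stages):
    """Call matrix from boolean detected-vectors."""
    data = [[ON if v else OFF for v in vec] for vec in vectors]
    return pd.DataFrame(data, columns=stages,
                        index=pd.Index([f"P{i}" for i in range(len(vectors))]))


STAGES5 = ["0.15", "0.25", "0.4", "0.7", "1.0"]


def test_all_on_is_constitutive():
    out = classify_patterns(_cm([(1, 1, 1, 1, 1)], STAGES5), STAGES5)
    assert out["pattern"].iloc[0] == "constitutive_on"


def test_trough_at_middle_stage():
    """ON everywhere except 0.4 mm: the trough pattern anchored at 0.4."""
    out = classify_patterns(_cm([(1, 1, 0, 1, 1)], STAGES5), STAGES5)
    assert out["pattern"].iloc[0] == "trough:0.4"
    assert out["anchor_stage"].iloc[0] == "0.4"


def test_exhaustive_enumeration_class_counts():
    """All 32 detected-vectors over 5 stages: 1 constitutive_on, 1 constitutive_off,
    5 stage-specific, 5 trough, 20 other."""
    vectors = list(itertools.product([0, 1], repeat=5))
    out = classify_patterns(_cm(vectors, STAGES5), STAGES5)
    counts = out["pattern"].value_counts()
    assert counts["constitutive_on"] == 1
    assert counts["constitutive_off"] == 1
    assert sum(c for p, c in counts.items() if p.startswith("stage_specific")) == 5
    assert sum(c for p, c in counts.items() if p.startswith("trough")) == 5
    assert counts["other"] == 20


@pytest.mark.parametrize("n_stages", [2, 3, 4, 5, 6])
def test_classifier_agrees_with_brute_force(n_stages):
    stages = [f"s{i}" for i in range(n_stages)]
    vectors = list(itertools.product([False, True], repeat=n_stages))
    out = classify_patterns(_cm(vectors, stages), stages)
    for vec, label in zip(vectors, out["pattern"]):
        assert label == classify_vector(tuple(vec), stages)


def test_ambiguous_counts_as_not_detected():
    cm = pd.DataFrame([[ON, ON, AMBIGUOUS, ON, ON]], columns=STAGES5, index=["P0"])
    out = classify_patterns(cm, STAGES5)
    assert out["pattern"].iloc[0] == "trough:0.4"


def test_probe_with_missing_call_excluded():
    cm = pd.DataFrame([[ON, None, ON, ON, ON]], columns=STAGES5, index=["P0"])
    out = classify_patterns(cm, STAGES5)
    assert out["pattern"].iloc[0] == "excluded"


def test_unknown_stage_rejected():
    with pytest.raises(ValueError, match="unknown"):
        classify_patterns(_cm([(1, 1)], ["a", "b"]), ["a", "zz"])


# ---------------------------------------------------------------------------
# transition ledger
# ---------------------------------------------------------------------------

def test_ledger_all_constitutive():
    n = 7
    ledger = transition_ledger(_cm([(1, 1, 1, 1, 1)] * n, STAGES5), STAGES5)
    for _, row in ledger.iloc[1:].iterrows():
        assert row["shared"] == n and row["newly"] == 0 and row["lost_total"] == 0


def test_ledger_single_gain_loss():
    ledger = transition_ledger(_cm([(0, 1, 0)], ["a", "b", "c"]), ["a", "b", "c"])
    assert ledger.loc[1, "stage_specific"] == 1  # ON only at b
    assert ledger.loc[2, "lost_total"] == 1
    assert ledger.loc[2, "lost_stage_specific"] == 1


@settings(deadline=None, max_examples=50)
@given(st.lists(st.tuples(*[st.booleans()] * 5), min_size=1, max_size=40))
def test_ledger_conservation_on_random_tables(vectors):
    """shared + newly + stage_specific = |ON at t| and
    lost_t = |ON at t-1| - (shared_t + specific-shared overlap) for any table."""
    cm = _cm(vectors, STAGES5)
    on = (cm == ON).to_numpy()
    ledger = transition_ledger(cm, STAGES5)
    for t in range(5):
        row = ledger.iloc[t]
        assert row["shared"] + row["newly"] + row["stage_specific"] == on[:, t].sum()
        if t > 0:
            still_on = (on[:, t - 1] & on[:, t]).sum()
            assert row["lost_total"] == on[:, t - 1].sum() - still_on
            assert (row["lost_shared"] + row["lost_newly"]
                    + row["lost_stage_specific"]) == row["lost_total"]


def test_ledger_reconciles_with_simulated_truth(staged_run):
    cm = staged_run["call_matrix"]
    ledger = transition_ledger(cm, STAGES5)
    on = (cm == ON).sum(axis=0)
    for t, s in enumerate(STAGES5):
        row = ledger.iloc[t]
        assert row["on_total"] == on[s]
        assert row["shared"] + row["newly"] + row["stage_specific"] == on[s]


# ---------------------------------------------------------------------------
# Venn regions
# ---------------------------------------------------------------------------

def test_venn_disjoint_singletons():
    cm = _cm([(1, 0, 0), (0, 1, 0), (0, 0, 1)], ["a", "b", "c"])
    regions = venn_three(cm, ("a", "b", "c"))
    assert regions["100"] == regions["010"] == regions["001"] == 1
    assert regions["111"] == 0


def test_venn_identical_sets():
    cm = _cm([(1, 1, 1)] * 4, ["a", "b", "c"])
    regions = venn_three(cm, ("a", "b", "c"))
    assert regions["111"] == 4
    assert sum(regions.values()) == 4


def test_venn_duplicate_stage_rejected():
    cm = _cm([(1, 1, 1)], ["a", "b", "c"])
    with pytest.raises(ValueError, match="distinct"):
        venn_three(cm, ("a", "a", "b"))


def test_venn_regions_sum_to_union_on_random_calls():
    rng = np.random.default_rng(5)
    vectors = rng.integers(0, 2, (500, 3)).astype(bool)
    cm = _cm(vectors, ["a", "b", "c"])
    regions = venn_three(cm, ("a", "b", "c"))
    union = int(vectors.any(axis=1).sum())  # direct set algebra oracle
    assert sum(regions.values()) == union


# ---------------------------------------------------------------------------
# named trough filters
# ---------------------------------------------------------------------------

def test_strict_and_loose_trough_filters_differ():
    cm = _cm([(1, 1, 0, 1, 1),   # strict trough at 0.4
              (1, 1, 0, 0, 1),   # ON early, off at 0.4 and 0.7
              (0, 1, 0, 1, 1)],  # not ON at 0.15
             STAGES5)
    strict = missing_only_at(cm, "0.4", STAGES5)
    loose = off_after_on(cm, ["0.15", "0.25"], "0.4")
    assert list(strict) == ["P0"]
    assert list(loose) == ["P0", "P1"]


# ---------------------------------------------------------------------------
# intensity placement / annotation histograms / re-expression
# ---------------------------------------------------------------------------

def test_placement_self_reference_quarters():
    ref = pd.Series(np.arange(1.0, 101.0), index=[f"P{i}" for i in range(100)])
    out = intensity_placement(ref.index, ref)
    assert out["per_quartile"] == [25, 25, 25, 25]


def test_placement_low_ranks_below_median():
    ref = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8], index=list("abcdefgh"))
    out = intensity_placement(["a", "b", "c", "d"], ref)
    assert out["below_median"] == 4


def test_placement_empty_query():
    ref = pd.Series([1.0, 2.0], index=["a", "b"])
    out = intensity_placement([], ref)
    assert out["n"] == 0 and np.isnan(out["frac_below_median"])


def test_simulated_trough_probes_sit_low_at_prior_stage(staged_run):
    """Planted trough transcripts are low-abundance: at the stage before the
    trough they fall below the expressed-probe median."""
    truth, cm, norm = staged_run["truth"], staged_run["call_matrix"], staged_run["norm"]
    trough = truth.index[truth["pattern"] == "trough:0.4"]
    ref = patterns.stage_mean_intensity(norm, "0.25", genotype="wild-type", tissue="whole")
    expressed = cm.index[cm["0.25"] == ON]
    out = intensity_placement(trough, ref, universe=expressed)
    assert out["frac_below_median"] >= 0.90


def test_annotate_counts_histogram():
    tags = {"P0": ["X"], "P1": ["X"], "P2": ["X", "Y"], "P3": []}
    hist, untagged = annotate_counts(["P0", "P1", "P2", "P3"], tags)
    assert hist == {"X": 3, "Y": 1}
    assert untagged == 1


def test_annotate_counts_total_matches_direct_count(staged_run):
    ann = staged_run["annotation"]
    probes = ann.regular_probes
    hist, untagged = annotate_counts(probes, ann.table["tags"])
    direct = sum(len([t for t in str(v).split(";") if t])
                 for v in ann.table.loc[probes, "tags"])
    assert sum(hist.values()) == direct


def test_reexpression_fraction():
    cm = _cm([(1, 1, 0, 1, 1), (1, 1, 0, 0, 0)], STAGES5)
    out = reexpression_fraction(["P0", "P1"], cm, "0.7")
    assert out == {"n_on": 1, "n_total": 2, "percentage": 50.0}
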