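"""Synthetic two-color microarray experiments with planted, recoverable truth.

The generator emulates the study structure this package analyzes: five
ordered anther stages (0.15/0.25/0.4/0.7/1.0 mm) hybridized in balanced
dye-swap loops, a mutant condition (mac1) co-hybridized with wild type at
two stages, an LCM design (three dissected zones plus whole anther at one
stage), negative-control probes, and planted expression-pattern classes
(constitutive ON/OFF, stage-specific, trough, pluripotency-decline,
mutant-persistent, zone-enriched, non-lobe).

Noise model: intensities are log-normal — replicate noise is additive
Gaussian on the log2 scale.  Negative-control foregrounds are Gaussian on
the linear scale, so the mean + 3 SD detection rule has an analytically
known false-ON rate.  ON probes are planted ``expression_offset`` log2
units above the nominal detection threshold; trough-class and
pluripotency-class probes sit just above it (low-abundance transcripts).
Dye bias is a smooth sinusoid of A applied with opposite sample-wise sign
in swapped pairs, so within-array loess correction is exercised.

One master seed drives everything; per-array substreams are spawned
deterministically, so identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CHANNELS, ExpressionMatrix, ProbeAnnotation, ProteinAbundanceTable
from .patterns import CONSTITUTIVE_OFF, CONSTITUTIVE_ON, label_stage_specific, label_trough

DEFAULT_STAGES = ("0.15", "0.25", "0.4", "0.7", "1.0")

PLURIPOTENCY = "pluripotency_decline"
MUTANT_PERSISTENT = "mutant_persistent"

WILD_TYPE = "wild-type"
MUTANT = "mac1"

LCM_ZONES = ("AR", "ML/TAP", "EPI/EN")
LCM_LABELS = LCM_ZONES + ("whole", "non-lobe")

_TF_FAMILIES = ("Myb", "bHLH", "WRKY", "MADS", "bZIP", "C2H2", "HD")
_GO_TAGS = ("metabolism", "transport", "signaling", "cell_cycle", "transcription",
            "translation", "stress", "development")


class ConfigError(ValueError):
    """A SimulationConfig field violates an invariant; the message names it."""


def default_pattern_fractions(stages: tuple[str, ...] = DEFAULT_STAGES) -> dict[str, float]:
    f = {CONSTITUTIVE_ON: 0.55, CONSTITUTIVE_OFF: 0.15,
         PLURIPOTENCY: 0.03, MUTANT_PERSISTENT: 0.02}
    for s in stages:
        f[label_stage_specific(s)] = 0.02
        f[label_trough(s)] = 0.03
    return f


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    ``noise_sd`` is the log2-scale Gaussian SD of replicate noise;
    ``expression_offset`` places ON probes that many log2 units above the
    nominal detection threshold (negctrl mean + 3 SD);
    ``dye_bias_amplitude`` scales the smooth intensity-dependent M bias;
    ``stage_jitter_sd`` adds per-(probe, stage) log2 variation to
    constitutive probes so stage-to-stage differential expression exists;
    ``mutant_retention`` is the probability that a trough-class probe stays
    ON in the mutant at the focal (last mutant) stage.
    """

    n_probes: int = 2000
    n_negctrl: int = 100
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 4
    noise_sd: float = 0.25
    negctrl_mean: float = 100.0
    negctrl_sd: float = 20.0
    pattern_fractions: dict[str, float] = field(default_factory=default_pattern_fractions)
    expression_offset: float = 1.0
    dye_bias_amplitude: float = 0.3
    seed: int = 0
    mutant_stages: tuple[str, ...] = ("0.25", "0.4")
    mutant_retention: float = 0.84
    stage_jitter_sd: float = 0.5

    def validate(self) -> None:
        if self.n_probes < 0:
            raise ConfigError("n_probes must be non-negative")
        if self.n_negctrl < 30:
            raise ConfigError("n_negctrl must be >= 30 (threshold estimation needs a stable SD)")
        if len(self.stages) < 2:
            raise ConfigError("stages must list at least 2 ordered stage labels")
        if self.replicates_per_stage < 2 or self.replicates_per_stage % 2:
            raise ConfigError("replicates_per_stage must be even and >= 2 (dye-swap pairing)")
        for name in ("noise_sd", "negctrl_sd", "dye_bias_amplitude", "stage_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.negctrl_mean <= 0:
            raise ConfigError("negctrl_mean must be positive")
        if not 0 <= self.mutant_retention <= 1:
            raise ConfigError("mutant_retention must be in [0, 1]")
        total = sum(self.pattern_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"pattern_fractions must sum to 1 (got {total})")
        if any(v < 0 for v in self.pattern_fractions.values()):
            raise ConfigError("pattern_fractions must be non-negative")
        known = set(default_pattern_fractions(self.stages))
        unknown = set(self.pattern_fractions) - known
        if unknown:
            raise ConfigError(f"pattern_fractions has unknown class(es): {sorted(unknown)}")
        for s in self.mutant_stages:
            if s not in self.stages:
                raise ConfigError(f"mutant_stages entry {s!r} not in stages")

    @property
    def nominal_threshold(self) -> float:
        return self.negctrl_mean + 3.0 * self.negctrl_sd

    @property
    def log2_threshold(self) -> float:
        return math.log2(self.nominal_threshold)


def _largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Integer class counts matching the fractions within rounding, summing to n."""
    raw = {k: v * n for k, v in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    counts = _largest_remainder_counts(config.pattern_fractions, config.n_probes)
    labels = np.concatenate([np.repeat(k, c) for k, c in counts.items()]) if counts else np.array([])
    rng.shuffle(labels)
    probes = [f"PROBE{i:06d}" for i in range(config.n_probes)]
    return pd.Series(labels, index=pd.Index(probes, name="probe_id"), name="pattern")


def _true_levels(
    config: SimulationConfig, classes: pd.Series, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(true log2 level per probe x stage, truth per-stage ON states)."""
    stages = list(config.stages)
    n = len(classes)
    base_off = math.log2(config.negctrl_mean)
    on_level = config.log2_threshold + config.expression_offset

    level = np.full((n, len(stages)), base_off)
    on = np.zeros((n, len(stages)), dtype=bool)
    abundance = np.zeros(n)

    cls = classes.to_numpy()
    is_high = (cls == CONSTITUTIVE_ON) | np.char.startswith(cls.astype(str), "stage_specific")
    abundance[is_high] = rng.gamma(2.0, 0.75, is_high.sum())
    is_low = np.isin(cls, [MUTANT_PERSISTENT, PLURIPOTENCY]) | np.char.startswith(
        cls.astype(str), "trough")
    abundance[is_low] = 0.3 + np.abs(rng.normal(0.0, 0.3, is_low.sum()))

    for j, stage in enumerate(stages):
        stage_on = np.zeros(n, dtype=bool)
        stage_on |= cls == CONSTITUTIVE_ON
        stage_on |= cls == label_stage_specific(stage)
        trough_here = np.char.startswith(cls.astype(str), "trough:") & (cls != label_trough(stage))
        stage_on |= trough_here
        # mutant-persistent probes behave as trough at the focal mutant stage
        focal = config.mutant_stages[-1]
        stage_on |= (cls == MUTANT_PERSISTENT) & (stage != focal)
        # pluripotency-decline: ON at the first two stages only
        stage_on |= (cls == PLURIPOTENCY) & (j < 2)
        on[:, j] = stage_on
        level[stage_on, j] = on_level + abundance[stage_on]

    # constitutive probes get per-stage jitter so stage DE exists
    const = cls == CONSTITUTIVE_ON
    if config.stage_jitter_sd > 0 and const.any():
        level[const] += rng.normal(0.0, config.stage_jitter_sd, (const.sum(), len(stages)))

    # pluripotency-decline: stepwise decay crossing the threshold at stage 3
    pluri = cls == PLURIPOTENCY
    if pluri.any():
        drop = 1.2
        start = config.log2_threshold + 0.4
        for j in range(len(stages)):
            if j == 0:
                level[pluri, j] = start + 2 * drop + abundance[pluri]
            elif j == 1:
                level[pluri, j] = start + drop + abundance[pluri]
            elif j == 2:
                level[pluri, j] = start - drop  # below threshold: not detected
            else:
                level[pluri, j] = base_off

    level_df = pd.DataFrame(level, index=classes.index, columns=stages)
    on_df = pd.DataFrame(on, index=classes.index, columns=stages)
    return level_df, on_df


def _mutant_levels(
    config: SimulationConfig,
    classes: pd.Series,
    wt_level: pd.DataFrame,
    wt_on: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mutant true levels/ON states at the mutant stages (defaults to wild type)."""
    stages = list(config.mutant_stages)
    level = wt_level[stages].copy()
    on = wt_on[stages].copy()
    focal = stages[-1]
    on_level = config.log2_threshold + config.expression_offset
    cls = classes.to_numpy()

    persistent = cls == MUTANT_PERSISTENT
    retained = np.char.startswith(cls.astype(str), "trough:") & (
        cls == label_trough(focal)) & (rng.random(len(cls)) < config.mutant_retention)
    for mask in (persistent, retained):
        if mask.any():
            level.loc[mask, focal] = on_level + 0.3 + np.abs(rng.normal(0, 0.3, mask.sum()))
            on.loc[mask, focal] = True
    # pluripotency markers never decline in the mutant: elevated at every
    # mutant stage, so they surface as shared UP (direct-target) candidates
    pluri = cls == PLURIPOTENCY
    if pluri.any():
        for s in stages:
            level.loc[pluri, s] = wt_level.loc[pluri, wt_level.columns[0]].to_numpy()
            on.loc[pluri, s] = True
    return level, on


def _make_annotation(
    probe_classes: pd.Series, negctrl_ids: list[str], rng: np.random.Generator
) -> ProbeAnnotation:
    probes = list(probe_classes.index)
    gene_ids = [f"GENE{i:06d}" for i in range(len(probes))]
    tf = np.where(rng.random(len(probes)) < 0.10,
                  rng.choice(_TF_FAMILIES, len(probes)), "")
    n_tags = rng.integers(0, 3, len(probes))
    tags = [";".join(rng.choice(_GO_TAGS, k, replace=False)) if k else ""
            for k in n_tags]
    reg = pd.DataFrame({
        "gene_id": gene_ids,
        "is_negative_control": False,
        "tf_family": tf,
        "tags": tags,
    }, index=pd.Index(probes, name="probe_id"))
    neg = pd.DataFrame({
        "gene_id": "",
        "is_negative_control": True,
        "tf_family": "",
        "tags": "",
    }, index=pd.Index(negctrl_ids, name="probe_id"))
    return ProbeAnnotation(pd.concat([reg, neg]))


def _hybridize(
    config: SimulationConfig,
    array_id: str,
    sample_a: dict,
    sample_b: dict,
    levels: dict[tuple[str, str], pd.Series],
    swap: bool,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one two-channel array.

    ``sample_a``/``sample_b`` are metadata dicts (stage, genotype, tissue,
    replicate); ``levels`` maps (stage, genotype) -> clean per-probe log2
    levels.  ``swap`` reverses the sample-to-dye assignment; the dye bias is
    attached to the dyes, so swapped pairs carry opposite sample-wise bias.
    """
    clean_a = levels[(sample_a["stage"], sample_a["genotype"])].to_numpy()
    clean_b = levels[(sample_b["stage"], sample_b["genotype"])].to_numpy()
    a_clean = (clean_a + clean_b) / 2.0
    bias = config.dye_bias_amplitude * np.sin(a_clean)

    log_a = clean_a + rng.normal(0.0, config.noise_sd, len(clean_a))
    log_b = clean_b + rng.normal(0.0, config.noise_sd, len(clean_b))
    # Cy5 gains +bias/2, Cy3 loses bias/2
    if not swap:
        log_a, log_b = log_a + bias / 2.0, log_b - bias / 2.0
        ch_a, ch_b = CHANNELS
    else:
        log_a, log_b = log_a - bias / 2.0, log_b + bias / 2.0
        ch_a, ch_b = CHANNELS[1], CHANNELS[0]

    neg = np.clip(
        rng.normal(config.negctrl_mean, config.negctrl_sd, (config.n_negctrl, 2)), 1e-3, None)

    cols = {}
    meta_rows = {}
    for log_v, ch, meta, neg_col in ((log_a, ch_a, sample_a, 0), (log_b, ch_b, sample_b, 1)):
        sid = f"{array_id}.{ch}"
        cols[sid] = np.concatenate([2.0 ** log_v, neg[:, neg_col]])
        meta_rows[sid] = {"array_id": array_id, "channel": ch, **meta}
    return pd.DataFrame(cols), pd.DataFrame.from_dict(meta_rows, orient="index")


def generate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, pd.DataFrame]:
    """Simulate the staged whole-anther experiment with the mutant loop.

    Arrays are arranged in dye-swap loop traversals over the ordered stages
    (stage i vs stage i+1, wrapping around), ``replicates_per_stage/2``
    traversals with alternating dye orientation, plus direct wild-type vs
    mutant arrays at each mutant stage.  Returns the intensity matrix, the
    probe annotation and a truth table (one row per probe: pattern class,
    per-stage ON states, mutant ON states, true log2 levels).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    seqs = root.spawn(5)
    class_rng, level_rng, mutant_rng, annot_rng = [np.random.default_rng(s) for s in seqs[:4]]
    array_seed = seqs[4]

    classes = _assign_classes(config, class_rng)
    wt_level, wt_on = _true_levels(config, classes, level_rng)
    mut_level, mut_on = _mutant_levels(config, classes, wt_level, wt_on, mutant_rng)
    negctrl_ids = [f"NEG{i:05d}" for i in range(config.n_negctrl)]
    annotation = _make_annotation(classes, negctrl_ids, annot_rng)

    levels = {(s, WILD_TYPE): wt_level[s] for s in config.stages}
    for s in config.mutant_stages:
        levels[(s, MUTANT)] = mut_level[s]

    stages = list(config.stages)
    n_stages = len(stages)
    traversals = config.replicates_per_stage // 2
    n_arrays = traversals * n_stages + config.replicates_per_stage * len(config.mutant_stages)
    array_rngs = iter(np.random.default_rng(s) for s in array_seed.spawn(max(n_arrays, 1)))

    value_frames, meta_frames = [], []
    rep_counter: dict[tuple[str, str], int] = {}

    def next_rep(stage: str, genotype: str) -> int:
        key = (stage, genotype)
        rep_counter[key] = rep_counter.get(key, 0) + 1
        return rep_counter[key]

    array_no = 0
    for k in range(traversals):
        for i in range(n_stages):
            array_no += 1
            s_a, s_b = stages[i], stages[(i + 1) % n_stages]
            meta_a = {"stage": s_a, "genotype": WILD_TYPE, "tissue": "whole",
                      "replicate": next_rep(s_a, WILD_TYPE)}
            meta_b = {"stage": s_b, "genotype": WILD_TYPE, "tissue": "whole",
                      "replicate": next_rep(s_b, WILD_TYPE)}
            v, m = _hybridize(config, f"A{array_no:03d}", meta_a, meta_b, levels,
                              swap=bool(k % 2), rng=next(array_rngs))
            value_frames.append(v)
            meta_frames.append(m)
    for s in config.mutant_stages:
        for k in range(config.replicates_per_stage):
            array_no += 1
            meta_wt = {"stage": s, "genotype": WILD_TYPE, "tissue": "whole",
                       "replicate": next_rep(s, WILD_TYPE)}
            meta_mu = {"stage": s, "genotype": MUTANT, "tissue": "whole",
                       "replicate": next_rep(s, MUTANT)}
            v, m = _hybridize(config, f"A{array_no:03d}", meta_wt, meta_mu, levels,
                              swap=bool(k % 2), rng=next(array_rngs))
            value_frames.append(v)
            meta_frames.append(m)

    probe_index = pd.Index(list(classes.index) + negctrl_ids, name="probe_id")
    values = pd.concat(value_frames, axis=1)
    values.index = probe_index
    samples = pd.concat(meta_frames)
    matrix = ExpressionMatrix(values, samples)

    truth = pd.DataFrame({"pattern": classes})
    for s in config.stages:
        truth[f"on:{s}"] = wt_on[s]
        truth[f"level:{s}"] = wt_level[s]
    for s in config.mutant_stages:
        truth[f"mutant_on:{s}"] = mut_on[s]
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# LCM experiment
# ---------------------------------------------------------------------------

def generate_lcm_experiment(
    config: SimulationConfig,
    zone_fractions: dict[str, float],
    zone_enriched_fraction: float = 0.05,
    nonlobe_fraction: float = 0.05,
    enrich_fold: float = 4.0,
    stage: str = "0.7",
) -> tuple[ExpressionMatrix, ProbeAnnotation, pd.DataFrame]:
    """Simulate the zone-vs-whole LCM design at one stage.

    ``zone_fractions`` gives the mixture proportion each compartment (the
    three zones plus "non-lobe") contributes to the whole-anther signal;
    labels must come from the known set.  Per zone with a positive mixture
    fraction, ``zone_enriched_fraction`` of probes are elevated
    ``enrich_fold``-fold only in that zone; ``nonlobe_fraction`` of probes
    carry non-lobe signal, half expressed-but-depressed in every zone and
    half absent from all zones while high in whole anther.  Whole-anther
    columns are linear mixtures of the compartment signals.
    """
    config.validate()
    unknown = set(zone_fractions) - set(LCM_LABELS)
    if unknown:
        raise ConfigError(f"unknown zone label(s) in zone_fractions: {sorted(unknown)}")
    if any(v < 0 for v in zone_fractions.values()):
        raise ConfigError("zone_fractions must be non-negative")

    root = np.random.SeedSequence((config.seed, 7))
    seqs = root.spawn(4)
    class_rng, level_rng, annot_rng = [np.random.default_rng(s) for s in seqs[:3]]
    array_seed = seqs[3]

    zones = [z for z in LCM_ZONES if zone_fractions.get(z, 0) > 0]
    mix = {z: zone_fractions.get(z, 0.0) for z in zones}
    f_nl = zone_fractions.get("non-lobe", 0.0)
    total = sum(mix.values()) + f_nl
    if total > 0:
        mix = {z: v / total for z, v in mix.items()}
        f_nl /= total

    n = config.n_probes
    probes = pd.Index([f"PROBE{i:06d}" for i in range(n)], name="probe_id")
    membership = np.full(n, "broad", dtype=object)
    nonlobe_reason = np.full(n, "", dtype=object)
    cursor = 0
    for z in zones:
        k = int(round(zone_enriched_fraction * n))
        membership[cursor:cursor + k] = z
        cursor += k
    k_nl = int(round(nonlobe_fraction * n))
    membership[cursor:cursor + k_nl] = "non-lobe"
    nonlobe_reason[cursor:cursor + k_nl // 2] = "down_in_all_three"
    nonlobe_reason[cursor + k_nl // 2:cursor + k_nl] = "absent_in_LCM_above_whole_median"
    cursor += k_nl
    order = class_rng.permutation(n)
    membership, nonlobe_reason = membership[order], nonlobe_reason[order]

    base_off = math.log2(config.negctrl_mean)
    on_level = config.log2_threshold + config.expression_offset
    abund = level_rng.gamma(2.0, 0.75, n)
    v = on_level + abund  # broad log2 level

    level = {z: np.full(n, 0.0) for z in zones}
    nl_level = np.full(n, base_off)
    for z in zones:
        level[z][:] = v
    log_fold = math.log2(enrich_fold)
    for z in zones:
        mask = membership == z
        level[z][mask] = v[mask] + log_fold
    down_mask = nonlobe_reason == "down_in_all_three"
    absent_mask = nonlobe_reason == "absent_in_LCM_above_whole_median"
    # the depressed-in-every-zone class stays detectable in the zones by
    # construction (depressed, not absent)
    v[down_mask] = np.maximum(v[down_mask], on_level + 1.0)
    for z in zones:
        level[z][down_mask] = v[down_mask] - 1.2
        level[z][absent_mask] = base_off
    nl_level[down_mask] = v[down_mask] + 3.0
    nl_level[absent_mask] = config.log2_threshold + config.expression_offset + 6.0

    whole_linear = f_nl * 2.0 ** nl_level
    for z in zones:
        whole_linear = whole_linear + mix[z] * 2.0 ** level[z]
    levels = {(stage, z): pd.Series(level[z], index=probes) for z in zones}
    levels[(stage, "whole")] = pd.Series(np.log2(whole_linear), index=probes)

    # reuse the hybridization machinery: tissue rides in the genotype slot of
    # the levels key, and is recorded in the sample metadata
    negctrl_ids = [f"NEG{i:05d}" for i in range(config.n_negctrl)]
    annotation = _make_annotation(pd.Series(membership, index=probes), negctrl_ids, annot_rng)

    array_rngs = iter(np.random.default_rng(s) for s in array_seed.spawn(
        max(len(zones) * config.replicates_per_stage, 1)))
    value_frames, meta_frames = [], []
    array_no = 0
    whole_rep = 0
    for z in zones:
        for r in range(config.replicates_per_stage):
            array_no += 1
            whole_rep += 1
            meta_z = {"stage": stage, "genotype": z, "tissue": z, "replicate": r + 1}
            meta_w = {"stage": stage, "genotype": "whole", "tissue": "whole",
                      "replicate": whole_rep}
            v_df, m = _hybridize(config, f"L{array_no:03d}", meta_z, meta_w, levels,
                                 swap=bool(r % 2), rng=next(array_rngs))
            m["genotype"] = WILD_TYPE
            value_frames.append(v_df)
            meta_frames.append(m)

    if not value_frames:
        empty = pd.DataFrame(index=pd.Index(list(probes) + negctrl_ids, name="probe_id"))
        samples = pd.DataFrame(columns=["array_id", "channel", "stage", "genotype",
                                        "tissue", "replicate"])
        truth = pd.DataFrame({"zone": membership, "nonlobe_reason": nonlobe_reason}, index=probes)
        return ExpressionMatrix(empty, samples), annotation, truth

    values = pd.concat(value_frames, axis=1)
    values.index = pd.Index(list(probes) + negctrl_ids, name="probe_id")
    samples = pd.concat(meta_frames)
    matrix = ExpressionMatrix(values, samples)

    truth = pd.DataFrame({
        "zone": membership,
        "nonlobe_reason": nonlobe_reason,
        "on_whole": levels[(stage, "whole")].to_numpy() > config.log2_threshold,
    }, index=probes)
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# companion protein table
# ---------------------------------------------------------------------------

def generate_protein_table(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rna_protein_corr: float,
    annotation: ProbeAnnotation,
    stages: tuple[str, ...] = ("0.4", "0.7", "1.0"),
    replicates: int = 2,
    replicate_noise_sd: float = 0.05,
) -> ProteinAbundanceTable:
    """Protein abundances whose stage-ratios correlate with the planted RNA
    stage-ratios at ``rna_protein_corr``.

    Only genes whose probe is truly ON at every requested stage get a
    protein (constitutively present, as a ratiometric quantitation requires).
    Per gene the protein log2 level at stage s is
    ``c * rna_level + sqrt(1-c^2) * e`` with e drawn iid at the RNA
    stage-jitter scale, so the across-gene Pearson correlation of any pair
    of stage-ratios recovers c up to sampling error.  Each protein carries
    one of the 11 molecular-weight fraction labels.
    """
    if not -1.0 <= rna_protein_corr <= 1.0:
        raise ConfigError("rna_protein_corr must be in [-1, 1]")
    from .rnaprot import MW_LABELS

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 11)))
    on_all = np.ones(len(truth), dtype=bool)
    for s in stages:
        on_all &= truth[f"on:{s}"].to_numpy()
    sel = truth.index[on_all]
    gene_map = annotation.gene_map()
    genes = gene_map.reindex(sel).dropna()

    c = rna_protein_corr
    jitter = config.stage_jitter_sd if config.stage_jitter_sd > 0 else 1.0
    rows = []
    rna_levels = truth.loc[genes.index, [f"level:{s}" for s in stages]].to_numpy()
    e = rng.normal(0.0, jitter, rna_levels.shape)
    prot_levels = c * rna_levels + math.sqrt(1.0 - c * c) * e + (1 - c) * 10.0
    mw = rng.choice(MW_LABELS, len(genes))
    for i, (probe, gene) in enumerate(genes.items()):
        for j, s in enumerate(stages):
            for r in range(replicates):
                noise = rng.normal(0.0, replicate_noise_sd) if replicate_noise_sd > 0 else 0.0
                rows.append({
                    "protein_id": f"P_{gene}",
                    "gene_id": gene,
                    "mw_fraction": mw[i],
                    "stage": s,
                    "replicate": r + 1,
                    "abundance": 2.0 ** (prot_levels[i, j] + noise),
                })
    return ProteinAbundanceTable(pd.DataFrame(
        rows, columns=["protein_id", "gene_id", "mw_fraction", "stage", "replicate", "abundance"]))
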