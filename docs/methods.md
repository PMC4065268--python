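# Methods

## The analysis

`antherexpr` re-implements, as a tested pipeline over synthetic data with
planted truth, the expression-progression analysis used for staged maize
anther transcriptomes: two-color microarray normalization, presence calls
from negative-control statistics, a stage-pattern taxonomy over an ordered
developmental series (0.15 / 0.25 / 0.4 / 0.7 / 1.0 mm anthers),
fold-change differential screens, sequential marker filters against a
mutant condition (*mac1*), laser-capture-microdissection (LCM) zone
enrichment, and transcript-protein concordance.

### Normalization

Each array is corrected within-array by locally weighted regression
(loess) of M = log2(Cy5/Cy3) on A = (log2 Cy5 + log2 Cy3)/2 — tricube
weights, two robustness iterations, span 0.4 of the data — and the two
channels are reconstructed from the corrected (M, A) pair so that every
downstream step sees normalized per-channel linear intensities.

Between arrays, the default is **upper-quartile scaling**: each column is
multiplied by one factor so all 75th percentiles agree. Rank-mean
**quantile normalization** is implemented and selectable
(`method="quantile"`), with exact tie handling (average ranks interpolated
into the mean-sorted reference) and the usual properties (idempotent on
tie-free data, rank-preserving). Scaling is the default because presence
calls are *invariant* under per-column scaling — the negative-control
threshold scales with the probes — whereas rank-mapping provably distorts
presence calls whenever biological groups differ in how many probes are
expressed: the trough stage has genuinely fewer expressed probes, so its
top background ranks map onto other stages' low-expressed values and flip
OFF calls to ON. On simulated data this cost 10–50% of planted trough
probes; with scaling the calls are unaffected. Quantile normalization
remains the better choice when column compositions are comparable and
quantitative cross-array comparisons dominate.

Loess span 0.4 (rather than a smaller span) keeps the local window wide
enough that clusters of genuinely differential probes at one intensity
region do not dominate the fit; the loess model assumes every A-region is
majority non-differential, and smaller windows track the planted biology
instead of the dye bias.

### Detection calls

A measurement is ON when it exceeds the mean + `multiplier` (default 3.0)
sample standard deviations of the same array channel's negative-control
foregrounds; thresholds are per array-channel on the normalized scale.
Per biological group (stage x genotype x tissue) the fraction of ON
measurements gives a three-valued call: ON at support >= 0.75, OFF at
support = 0, otherwise AMBIGUOUS. AMBIGUOUS probes are excluded from
pattern classes and marker filters; for pattern purposes "not detected"
means call != ON. Under a Gaussian background the analytic false-ON rate
is the standard-normal upper tail beyond the multiplier — 0.135% at 3.0
SD, displayed as 0.13% — and a 10^6-draw simulation reproduces it within
binomial error. Negative-control SD uses the n−1 denominator.

### Stage patterns and transitions

Per probe, the ON/not-ON vector over the ordered stages is classified:
constitutive ON (all), constitutive OFF (none), stage-specific (exactly
one), trough (all but one), other. For a two-stage series, "ON at one
stage" is stage-specific by precedence. Both the strict trough filter and
the looser "ON at the prior stages, off here" universe are exposed as
named filters, since the two definitions yield different counts.
The transition ledger splits each stage's detected probes disjointly into
shared-with-previous, newly-expressed, and stage-specific, and splits the
probes lost at each transition by their category at the previous stage;
conservation (the three classes sum to the stage's ON count; losses equal
the previous ON count minus the carry-over) is property-tested on random
call tables.

### Differential expression

The standard contrast is |log2 ratio| >= log2(1.5) (0.585, displayed as
0.58) with a two-sided t-test p <= 0.05 — one-sample on per-array log2
ratios when the two conditions co-hybridized (dye-swap pairs), Welch
two-sample otherwise. No multiple-testing correction is applied, matching
the bare p-threshold convention of the original analysis style; this is a
per-probe screen, not an inference procedure. The constitutive stage
series uses a bare two-fold cutoff on ratios of stage-mean intensities
(no test), and pathway flagging supports the any-changed-member rule and
the strict >45%-of-members rule.

### Markers, mutant persistence, LCM, protein concordance

The pluripotency filter is a conjunctive sequential filter: significantly
down across the first transition, down again across the second, then
low-or-OFF (call != ON, or stage-mean intensity below the stage's lower
quartile) at every later stage. Curated gene lists are scored gene-wise
with an any-probe rule (a gene is constitutive if any of its probes is).
Mutant persistence is the ON fraction, in the mutant, of the wild-type
shut-off set; direct-target candidates are the same-direction
intersections of the mutant contrasts at two stages.

LCM enrichment delegates per-zone to the differential test against whole
anther (enriched = UP and detected in the zone); enriched probes are
partitioned by zone sharing. Non-lobe assignment unions two disjoint
reason classes: significantly DOWN *and detected* in all three zones, or
detected in no zone while above the whole-anther median (the quantile
universe is probes called ON in whole anther).

Protein-RNA pairing joins replicate-averaged protein log2 stage-ratios to
gene-collapsed RNA stage-ratios (probes collapsed by mean intensity,
proteins by summed abundance); only proteins observed at all compared
stages are ratioed, as a ratiometric quantitation requires. The decile
table bins both axes into tenths with stable first-occurrence tie
breaking, so margins are n/10 ± 1 and tables are bit-reproducible.

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions every recovery test runs under.

* **Design** — five stages in balanced dye-swap loop traversals (stage i
  vs stage i+1, wrapping; orientation alternates between traversals), four
  biological replicate measurements per stage, plus direct wild-type vs
  *mac1* arrays at 0.25 and 0.4 mm. The LCM design hybridizes each
  dissected zone against whole anther; whole-anther signal is a linear
  mixture of the three zone signals plus a non-lobe component
  (0.3/0.3/0.3/0.1 by default).
* **Noise** — intensities are log-normal: replicate noise is Gaussian on
  the log2 scale, SD 0.25. Negative-control foregrounds are Gaussian on
  the *linear* scale (mean 100, SD 20), making the detection rule's false-ON
  rate analytic. Undetected probe states sit at the negative-control mean,
  modulated by the same log2 replicate noise.
* **Planting** — ON states are planted `expression_offset` (default 1.0)
  log2 units above the nominal threshold (mean + 3 SD), plus a per-probe
  abundance drawn Gamma(2, 0.75) for constitutive/stage-specific probes.
  Trough, pluripotency-decline and mutant-persistent probes get a small
  abundance (0.3 + |N(0, 0.3)|): the trough classes are low-abundance by
  construction, which is what makes their quartile placement at the prior
  stage reproduce. The default offset of 1.0 keeps the abundance continuum
  close enough to background that no MA-region is majority-differential;
  at much larger offsets the empty band between background and expressed
  probes is populated only by differential states, and loess correction —
  correctly, given its assumptions — erases real signal there. Tests that
  plant a larger offset therefore skip the loess step to isolate
  detection.
* **Stage variation** — constitutive probes receive per-(probe, stage)
  jitter (SD 0.5 log2) so two-fold stage screens and protein pairing have
  real variance to work with.
* **Mutant** — trough-at-0.4 probes stay ON in the mutant with
  probability `mutant_retention` (default 0.84); mutant-persistent probes
  always; pluripotency-decline probes never decline in the mutant (ON and
  elevated at both mutant stages), making them recoverable as shared-UP
  direct-target candidates.
* **Protein tables** — per gene, protein log2 levels are
  `c * rna_level + sqrt(1-c^2) * e` with e drawn at the RNA jitter scale,
  so the across-gene Pearson correlation of any stage-ratio pair recovers
  the planted `c` up to sampling error and mild attenuation from RNA
  measurement noise (~0.46–0.47 recovered for c = 0.5 at ~1200 pairs).
  Each protein carries one of the 11 gel size-fraction labels
  (3.5–10 kD ... 160–260 kD).
* **Seeding** — one master seed; class assignment, level generation,
  mutant behaviour, annotation and each array draw from deterministically
  spawned substreams, so identical configs are bit-identical.

What the generator does **not** emulate: spatial array artifacts, probe
cross-hybridization, sequence-dependent probe affinity, background
subtraction issues, and realistic (heavy-tailed, correlated) biological
variance. Passing recovery tests therefore demonstrate that the pipeline's
logic is correct and well-calibrated under its stated noise model — not
that the thresholds are optimal for real arrays.

## Problem sizes and numerical choices

Simulated experiments use 2,000 probes (staged) and 1,000 probes (LCM)
with 100 negative controls — large enough that class counts, loess fits
and threshold estimates are stable, small enough that the full pipeline
runs in seconds. The null-rate simulation uses 10^6 draws (binomial SE
~0.004% around 0.135%). Degenerate inputs are handled explicitly: zero
probes give empty outputs; a zero-SD negative-control set warns and
thresholds at the mean; quantile normalization of a single column is the
identity with a warning; empty query sets return explicit empty results
with NaN percentages rather than raising.

## Known limitations

* The trough taxonomy is binary (ON/not-ON); no continuous clustering or
  time-series smoothing is attempted.
* The moderated-variance (empirical-Bayes) test is noted as an extension;
  the default is a plain t-test, which is what the fold + p rule assumes.
* Gene/probe mapping rules (any-probe constitutive; mean-collapse for RNA,
  sum-collapse for proteins) are package conventions; alternatives change
  gene-level counts.
* The "20.8% zone-restricted re-expression" style of summary depends on
  the choice of denominator; `trough_refinement` reports the full
  partition with counts so any denominator can be applied by the caller.
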