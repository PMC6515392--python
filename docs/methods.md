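# Methods

## Encoding model

A steady-state feature `R_ij > 0` of sensor *i* under analyte *j* maps to
a firing latency `t_i = ln(R_ij)/γ_ij`. The package defaults to `γ = 1`
for every sensor: when sensor/gas characteristics are not available, the
relative timing carries the same information as the resistances
themselves, and the firing order equals the order of `ln R` (equivalently
of `R`). Per-sensor and per-(sensor, analyte) γ remain configurable, and
`SensorCharacteristics.calibrate` offers a one-exposure calibration
(`γ_i = ln R_i / t_i^ref` against user-supplied target latencies) as a
convenience — it is a calibration shortcut, not a fitted sensor model.

Latencies reduce to a rank-order signature: `rank_of_sensor[i]` is the
rank (0 = earliest) at which sensor *i* fired. Equal latencies are ranked
by ascending sensor index — a deterministic tie rule, so encoding is a
pure function of the input.

### Byte layout

The network stores byte vectors, so a signature is encoded
rank-by-sensor: component *i* holds `scale × rank_i` with `scale = 16`
(ranks then span 0–240 of the 0–255 byte range, and one rank step is 16
distance units — integer headroom for influence-field thresholds). Two
consequences drive the design:

* **full-frame distances are ordinal** — the Manhattan distance between
  two complete encoded signatures is exactly `scale ×` the Spearman
  footrule distance between the permutations, so a mild shuffle of spikes
  moves a pattern only a little; and
* **masking implements the streaming window** — a partially received
  frame is the same vector with only the received components unmasked, so
  per-spike classification needs no separate code path.

The alternative sensor-by-rank layout (component *j* = which sensor fired
at rank *j*) would make distances nominal rather than ordinal and was
rejected; it is noted here because hardware pattern-matching memories do
not document their broadcast layout.

Non-positive resistances are rejected rather than clamped: a clamped
value would silently reorder ranks.

## Network model

The simulator models a daisy chain of trainable neurons, each with a
256-byte prototype memory, a category, and an active influence field
(AIF). Configuration registers: capacity 1024, `max_if = 3840`,
`min_if = 16`, mode `rbf` or `knn`, `k = 2`.

* **Firing** uses the strict inequality `distance < AIF`. (The looser
  `≤` reading differs only on exact boundary hits; strict keeps a neuron
  shrunk to distance *d* from re-firing on the pattern that shrank it.)
* **max_if = 3840** is a conservative ceiling above the worst-case
  full-frame distance at scale 16 (16 components × 240 = 3840; the
  worst-case footrule of two 16-permutations is 128, i.e. 2048 at scale
  16). **min_if = 16** is one rank step at scale 16 — fields below one
  rank step cannot be meaningful for rank data.
* **Learning**: if no neuron fires on a labelled broadcast, a new neuron
  commits with AIF = max_if. If neurons fire but none carries the target
  category, a new neuron commits with AIF = the distance of the closest
  firing neuron, and every wrong-category firing neuron shrinks its AIF
  to exactly its distance from the broadcast. If a firing neuron already
  identifies the category, nothing commits, but wrong-category firing
  neurons still shrink. AIFs never grow after commit; a shrink clamped at
  min_if flags the neuron *degenerate* but keeps it active (preserving
  its category rather than deleting knowledge).
* **Ties** in the winner-takes-all readout break by lower neuron id
  (commit order), matching daisy-chain search semantics.
* **Windowed distances are not rescaled.** A partial window yields
  smaller distances, so early spikes fire many neurons and the candidate
  set narrows as the window grows — this is the mechanism behind
  continuous classification, not an artifact to correct.

A consequence worth documenting: after learning, every *committed*
prototype is recalled by its own category at distance 0, but a pattern
that was skipped by the no-commit rule (a same-category neuron already
fired on it) carries no such guarantee — a later commit with a fresh
max_if field can capture it. Learning is order-dependent; classification,
given a fixed set of (prototype, category, AIF) triples, is not.

## Reference derivation

For each gas the rank-score matrix `P_ij(k) = N_ij(k)/N(k)` is tallied
over that gas's training signatures; on complete patterns every rank
column sums to 1. One reference signature per gas is extracted by
maximum-probability assignment of sensors to ranks. The default is a
transparent greedy sweep — visit cells in decreasing probability, ties
broken by lower rank then lower sensor index, take a cell when its sensor
and rank are both free — chosen for reproducibility and ease of audit; an
optimal assignment (scipy's Hungarian solver) is available via
`method="optimal"`. On a uniform matrix the tie rules force the identity
permutation. Greedy and optimal coincide whenever the greedy total
probability is optimal (checked against exhaustive enumeration on small
instances in the test suite); at the noise levels the generator produces,
the per-rank argmax is essentially unambiguous and both methods recover
the class template.

Only hard reference signatures are fed to the network; no soft per-rank
matching is performed during classification.

## Streaming decisions

Each arriving spike appends one component to the window, the masked
vector is re-broadcast, and the per-spike results form a trace. Two latch
policies are implemented because "positive recognition" can reasonably be
operationalised either way:

* **stable** (default, used for all reported spikes-to-decision
  metrics): the smallest window *m* whose top-1 category is defined and
  identical for every window *m*..16 — the retrospective criterion that
  matches averaged continuous-classification statistics;
* **first-identified**: the smallest window whose status is *identified*
  (all firing neurons agree), usable online without waiting for the
  frame to end.

A frame that never latches (final window unknown) yields no decision; in
evaluation it counts as an error and lands in the report's explicit
`unknown` column. The confusion matrix is therefore
`n_classes × (n_classes + 1)`: row sums equal per-class test counts while
accuracy = 100 × trace(first n columns)/total stays conservative.
Percentages and spike counts are reported to two decimals.

Full frames whose final status is unknown are logged as anomaly records —
the complete signature stored under the "unknown" category for later
labelling. Incomplete frames (truncated stream, dead sensor) are
classified on the available mask and flagged incomplete, but are not
eligible for anomaly logging, which requires the full signature.

## Synthetic bench generator

The generator emulates a 4 × 4 MOX array exposed to six analytes
(ammonia, acetaldehyde, acetone, ethylene, ethanol, toluene) over bench
concentration grids of 20–500 ppmv with per-class sample counts
(55, 23, 40, 64, 46, 57; 285 exposures total). The log steady-state
response follows a power law in concentration:

```
ln R_i = β_i(k) − α_i(k)·ln(C/C₀) + b·δ·d_i + ε_i,   ε_i ~ N(0, σ²)
```

* `β_i(k)` realises the class template: one *rank spacing* (default 1.0
  log unit) between consecutive template ranks on a base level of 4.0;
* `α` defaults to 0.8 for every sensor. Sensor-constant α makes a
  concentration change a uniform log-shift, so the rank order is
  concentration-invariant; per-analyte heterogeneous α vectors let
  latency curves cross between concentrations, reproducing the
  concentration-dependent signature inconsistencies a steady-state
  encoder exhibits on real arrays;
* drift is `b·δ·d_i` with batch index *b*, rate δ and a fixed unit-norm
  per-sensor direction `d` drawn once from the seed. A scalar shift
  common to all sensors could never change a rank order, so meaningful
  drift must differ across sensors; the fixed direction makes it a slow,
  consistent signature deformation, as ageing arrays show. Default δ = 0;
* `ε` is i.i.d. latency jitter (at γ = 1, log-response noise and latency
  jitter are the same axis; `noise_sd` and `shuffle_sd` combine in
  quadrature). The default `shuffle_sd ≈ 0.471` is calibrated
  analytically so the expected number of adjacent rank swaps per frame is
  1: adjacent template ranks sit one rank spacing apart, two independent
  N(0, σ²) jitters swap them with probability Φ(−Δ/(σ√2)), and
  `jitter_for_mean_swaps` inverts the 15-pair sum. This "about one swap
  per frame" is the moderate-noise study condition.

Class templates default to six random permutations at seed 0 with
pairwise footrule ≥ 40 — except ethylene/ethanol, a deliberately
confusable pair: the ethanol template is the ethylene template with three
adjacent swaps at ranks 8–13 (footrule 6), so the two signatures agree on
their first eight spikes. This reproduces the qualitative structure of
closely related odors: the pair is classified correctly from the full
frame but requires several more spikes to disambiguate than the
well-separated classes, and dominates the per-analyte variance of the
frame fraction.

What the generator does **not** emulate: electrochemical sensor dynamics,
transient (non-steady-state) features, correlated sensor noise,
batch-to-batch humidity/temperature effects, or the batch statistics of
any public drift corpus. Passing tests therefore demonstrate the
classifier's behaviour under the stated statistical structure (templates
plus power law plus i.i.d. log-normal noise plus optional directional
drift), not performance on any particular physical array.

## Evaluation protocol

The learning set is exactly one rank-score reference per class, committed
in a fixed class order (the bench design's order); the test set is every
generated frame, streamed spike-by-spike. The references are derived
summaries — none need equal any individual test frame. A config flag on
`derive_references`/`train_on_references` permits multiple exemplars per
class for ablation. End-to-end runs are pure functions of the
configuration seed: same config, same report.

Problem sizes used in the shipped experiments: 285 streamed frames for
the bench run, 100 frames for the untrained-analyte rejection experiment,
10,000 random vector/mask pairs for the distance checks, 1,000 random
frames for the stream/batch equivalence checks.

## Known limitations

* The skipped-pattern recall caveat above: with many exemplars per class,
  training-set recall is guaranteed only for committed patterns.
* The stable latch policy is retrospective (it needs the full trace); an
  online deployment would use first-identified, which latches later on
  confusable classes.
* Greedy reference extraction can be suboptimal when a class's rank-score
  matrix is strongly multimodal (e.g. a class whose signature genuinely
  alternates); the optimal-assignment flag covers that case.
* Anomaly logging keys on complete frames only; a truncated frame is
  flagged incomplete rather than anomalous.
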