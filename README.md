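# spikenose

Rank-order spiking classification for electronic-nose (e-nose) sensor
arrays: spike-latency encoding of multivariate gas-sensor data, a
nearest-neighbor spiking network with influence-field learning,
probabilistic rank-score reference derivation, and continuous per-spike
streaming classification with open-set anomaly detection.

## The problem

A 4 × 4 metal-oxide (MOX) sensor array exposed to a gas produces 16
steady-state resistance features. A resistance-to-time front end converts
each feature into a spike with firing latency

```
t_i = ln(R_ij) / γ_ij
```

where `R_ij` is the steady-state resistance of sensor *i* under analyte
*j* and `γ_ij` a sensor/gas characteristic constant (1 by default, when
characteristics are unavailable). Discarding absolute timing and keeping
only the **order** in which the 16 sensors fire yields a rank-order
signature — a permutation of the sensors — that is compact and, for a
well-behaved array, concentration-invariant. The classification problem is
to recognise which target gas produced an incoming signature, ideally
before the full 16-spike frame has arrived, and to flag signatures that
match no known gas (the fingerprint of sensor drift or a novel analyte).

## The classifier

Signatures are encoded rank-by-sensor as byte vectors (component *i* =
16 × rank of sensor *i*) and broadcast to a simulated bank of up to 1024
associative neurons. Each neuron stores a prototype `P`, a category, and
an **active influence field** (AIF). On a broadcast `V` it evaluates the
Manhattan distance

```
D = Σ_i |V_i − P_i|
```

(which, for complete signatures, is exactly 16 × the Spearman footrule
distance between the two permutations) and fires iff `D` is strictly
inside its AIF. The winner-takes-all readout returns the k = 2 closest
firing neurons; if none fires the pattern is *unknown*. Supervised
learning commits one neuron per reference pattern and shrinks the AIF of
wrong-category firing neurons to exactly their distance from the
broadcast, carving an open-set decision space.

The learning set is minimal: for each gas *k*, the probability that
sensor *i* fires at rank *j*,

```
P_ij(k) = N_ij(k) / N(k),
```

is tallied over that gas's training signatures, and a single reference
signature per gas is extracted by maximum-probability assignment. During
streaming, each arriving spike widens the pattern-matching window (the
mask of received components), the network is re-queried, and a decision
is latched once the top-1 category stabilises — typically after 2–3 of
the 16 spikes.

## Worked example

```python
from spikenose import GeneratorConfig, run_experiment

result = run_experiment(GeneratorConfig(seed=0))
print(result.report.round())
```

prints

```
{'accuracy_pct': 97.89, 'mean_spikes_to_decision': 2.51,
 'mean_frame_fraction_pct': 15.71, 'n_frames': 285, 'n_unknown': 3,
 'policy': 'stable'}
```

i.e. on the synthetic six-analyte bench dataset (285 exposures with about
one adjacent rank swap of noise per frame, training on one rank-score
reference per gas) 97.9 % of streamed frames latch the correct analyte,
on average after 2.51 spikes — 15.7 % of the 16-element frame. The
per-analyte breakdown (`result.report.per_analyte`) shows the deliberately
confusable ethylene/ethanol pair needs far more spikes (up to a mean of
~9) than the well-separated analytes, which latch on the very first
spike, because the pair's signatures share all of their early firing
ranks.

The `examples/` scripts walk through each capability: encoding an
exposure, deriving references and batch classification, streaming with
early decisions, and anomaly rejection of an untrained gas. A thin CLI
covers the same pipeline from the shell:

```bash
spikenose simulate --out-dir data
spikenose encode --features data/features.csv --out patterns.csv
spikenose train --patterns patterns.csv --network-out net.json
spikenose stream --spikes spikes.csv --network net.json --out results.csv
spikenose evaluate --out report.json
```

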