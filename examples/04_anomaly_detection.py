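"""Open-set anomaly detection of an untrained analyte.

A network trained on six references rejects frames whose signature falls
outside every neuron's influence field; the full frame is then logged
with the 'unknown' category for later labelling — the hook that makes
long-term sensor drift visible.
"""

from spikenose import (
    GeneratorConfig,
    StreamingClassifier,
    anomaly_template,
    run_experiment,
    sample_dataset,
)
from spikenose.evaluate import encode_table

result = run_experiment(GeneratorConfig(seed=0))

far = anomaly_template(result.dataset.templates, seed=0)
print("untrained analyte's signature:", far.rank_of_sensor)
print("footrule distance to nearest trained template:",
      min(far.footrule(t) for t in result.dataset.templates.values()))

templates = dict(result.dataset.templates)
templates["unseen-gas"] = far
cfg = GeneratorConfig(
    analytes=tuple(templates),
    templates=templates,
    concentrations={a: (50, 100, 150) for a in templates},
    samples_per_class={**{a: 0 for a in result.dataset.templates}, "unseen-gas": 50},
    seed=123,
)
frames = encode_table(sample_dataset(cfg).features)

clf = StreamingClassifier(result.net)
for i, pattern in enumerate(frames):
    clf.classify_frame(pattern, frame_id=i)

print(f"\nstreamed {len(frames)} frames of the untrained gas:")
print(f"  logged as anomalies: {len(clf.anomalies)}")
print("  first logged record:", clf.anomalies[0])
print(
    "\nEvery frame far from all stored references ends its stream with"
    "\nstatus 'unknown' and is stored verbatim for later relabelling."
)
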