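"""Stream frames spike-by-spike and latch early decisions.

Runs the full synthetic bench experiment: 285 test frames streamed one
spike at a time through a network trained on six rank-score references,
with decisions latched as soon as the top-1 category stabilises.
"""

from spikenose import GeneratorConfig, run_experiment

result = run_experiment(GeneratorConfig(seed=0))
report = result.report

print("per-spike trace of frame 0 (true analyte:",
      result.dataset.features.loc[0, "analyte"], end="):\n")
for m, res in enumerate(result.traces[0].results, start=1):
    print(f"  spikes={m:2d} status={res.status:10s} top-1={res.category}"
          f" distance={res.distance}")

print("\nsummary over all frames:", report.round())
print("\nper-analyte early-decision statistics:")
print(report.per_analyte.round(2))
print(
    "\naccuracy is the percent of frames whose latched decision matches"
    "\nthe true analyte; mean_frame_fraction is the average percent of the"
    "\n16-spike frame needed before the decision stabilised. The"
    "\nconfusable ethylene/ethanol pair needs the most spikes because"
    "\ntheir signatures share all early firing ranks."
)
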