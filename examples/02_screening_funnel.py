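"""Run the sequential five-stage screen on the packaged score tables.

Stages: SIFT -> PolyPhen -> I-Mutant -> PROVEAN -> three-tool consensus
(PANTHER & SNPs&GO & PHD-SNP).  In label mode the printed categorical calls
are trusted; in threshold mode calls are re-derived from the numeric
values, which drops the one variant whose printed Disease label contradicts
its 0.12 probability.
"""

from saamp import load_table, run_funnel
from saamp.predictors import merge_profiles

merged = merge_profiles(
    load_table("damaging_screen").records,
    load_table("disease_consensus").records,
)

for mode in ("labels", "thresholds"):
    report = run_funnel(merged, mode=mode)
    counts = " -> ".join(f"{s.name}:{s.surviving}" for s in report.stages)
    print(f"{mode:>10}: {counts}")

labels = run_funnel(merged, mode="labels")
thresholds = run_funnel(merged, mode="thresholds")
dropped = set(labels.final_survivors) - set(thresholds.final_survivors)
print(f"dropped by re-thresholding: {sorted(dropped)} "
      "(printed label Disease, probability 0.12)")
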