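"""Visuomotor response and acoustic startle in larvae.

Both assays compare the mean per-second activity in the 15 s after a
stimulus onset with the 60 s before it. Dark-adapted WT larvae freeze
briefly when the light snaps on (negative change); mutants do not.
A sudden loud noise startles both genotypes, but the mutant responds
harder and habituates less across the three presentations.
"""

from swimmetrics.pipeline import run_asr, run_vmr

vmr = run_vmr(n_per_genotype=6, seed=3, adaptation=120)
print("VMR, dark-to-light (activity change, mm per 1-s bin)")
print(vmr.metrics.groupby("genotype")[["change_1", "change_2", "change_3"]].mean().round(3))

asr = run_asr(n_per_genotype=6, seed=4, adaptation=120)
print("\nacoustic startle (activity change per stimulus, habituation index)")
print(asr.metrics.groupby("genotype")[
    ["change_1", "change_2", "change_3", "habituation_index"]
].mean().round(3))
print()
between = asr.comparisons[asr.comparisons["groups"] == "mutant vs WT"]
print(between[["metric", "method", "direction", "p_one"]].to_string(index=False))

# habituation_index = (r1 - r3) / r1: near 1 means the response collapsed
# across repeats (normal habituation), near 0 means it persisted.
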