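"""PTZ seizure-susceptibility challenge.

Each larva is recorded twice through a light-to-dark transition: once in
plain water (baseline) and once with 7.5 mM pentylenetetrazol, a GABA-A
antagonist, in the bath. The response is the change in distance traveled
between the 60 s before and after the transition; the normalized response
is treated-minus-baseline per fish.
"""

from swimmetrics.pipeline import run_ptz_challenge

result = run_ptz_challenge(n_per_genotype=6, seed=5, acclimation=60, spontaneous=120)

print(result.metrics.groupby("genotype")[
    ["baseline_change", "treated_change", "normalized_change"]
].mean().round(3))
print()
print(result.comparisons[["metric", "groups", "method", "p_one"]].to_string(index=False))

# PTZ suppresses the normal dark-transition surge in WT (treated < baseline,
# negative normalized change) but drives seizure-like extra activity in the
# mutant (positive normalized change) — the behavioral readout of its
# weakened GABAergic inhibition.
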