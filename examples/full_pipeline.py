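"""End-to-end pipeline run: every assay, both genotypes, one report.

Equivalent to ``swimmetrics demo`` on the command line. Writes metrics,
comparisons, stereotypy events, the headline-contrast scoreboard and a
manifest to a results directory, then prints the human-readable report.
Takes a few minutes at the default n = 20 per genotype; n is reduced here.
"""

from swimmetrics.pipeline import demo_config, run_pipeline, summarize

config = demo_config(seed=1, out="results/example_demo")
config["n_per_genotype"] = 8
out_dir = run_pipeline(config)
print(summarize(out_dir))

# The scoreboard at the bottom lists the seven shank2b genotype contrasts;
# with the default presets each should PASS (one-sided p < 0.05 by the
# declared test, effect in the expected direction).
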