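"""Forward-simulate a pooled dropout screen with known ground truth.

Builds the 455-gene chromatin-regulator library design (~4700 guides:
4-14 per gene, 100 non-targeting negatives, 6 spike-in essential genes),
plants 20 ALT-selective dependencies (selection coefficient s = 0.4 per
population doubling, ALT arm only), grows the pools for 16 population
doublings, and sequences T0/Tend at 10 million reads per sample.
"""

from dropscreen import screen_scenario, simulate_counts

cfg, planted = screen_scenario(
    seed=1,
    alt_conditions=("ALT1",),
    control_conditions=("CTRL1",),
    n_selective=20,
    s_selective=0.4,
)
result = simulate_counts(cfg)

print(f"library: {len(cfg.library)} guides, "
      f"{len(cfg.library.gene_to_guides)} genes")
print(f"samples: {result.counts.sample_ids}")
print(f"reads per sample: {result.counts.counts.sum(axis=0).to_dict()}")
print(f"planted ALT-selective genes (first 5): {planted[:5]}")

# the truth table records every guide's planted s and efficacy e per
# condition; -s*e*16 approximates the log2FC each guide should show
truth = result.truth
alt_hits = truth[(truth.condition == "ALT1") & (truth.s > 0)]
print(f"guides carrying a fitness cost in ALT1: {len(alt_hits)} "
      f"(planted genes + spike-in essentials)")
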