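"""Adaptive nonparametric comparison (ANC) on a simulated starve/refeed contrast.

ANC compares the full bead distributions of matched sample pairs with a
two-sample KS test, calibrates its alpha on technical-duplicate null
comparisons, and calls a hit when >70% of pairs shift significantly in the
same direction.
"""

import qminet as q

config = q.SimulationConfig(
    n_interactions=40,
    conditions=("starved", "refed"),
    n_biological_replicates=8,
    planted_modules=(q.PlantedModule("response", tuple(range(8)), {"refed": 0.4}),),
    seed=7,
)
beads, meta, traits, truth = q.simulate_experiment(config)

result = q.anc_test(beads, meta, contrast=("starved", "refed"))

print(f"panel:            {result.n_interactions_tested} interactions, "
      f"{result.n_comparisons} matched pairs")
print(f"Bonferroni level: {result.base_alpha / result.n_interactions_tested:.2e}")
print(f"alpha* used:      {result.alpha_used:.2e} "
      f"(calibrated on {result.n_null_comparisons} duplicate-well null comparisons)")
print(f"hits:             {len(result.hits)}")

planted = set(truth.responsive_interactions("refed"))
print(f"planted recovered: {len(planted & set(result.hits))}/{len(planted)}")
print()
print("top hits (fraction of consistent significant pairs, median log2FC):")
hits = result.table[result.table["hit"]].sort_values("median_log2fc", ascending=False)
for interaction, row in hits.head(8).iterrows():
    print(f"  {interaction:10s}  f = {row['f_consistent']:.2f}  "
          f"log2FC = {row['median_log2fc']:+.2f}")
# A hit means the bead distribution shifted the same way in >70% of matched
# pairs at the multiple-comparison-corrected alpha; log2FC ~ +0.4 matches
# the planted effect.
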