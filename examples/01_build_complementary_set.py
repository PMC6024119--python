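"""Build complementary sets of planning units on a synthetic occurrence database.

Simulates a small county-level database (six taxon groups, heavy-tailed
occupancies, ranges clustered within biogeographic strata), then builds
greedy complementary sets (CSs) for all species and for threatened
species only. A CS is a set of units that jointly represents every
species of its universe at least once; its size is the footprint a fully
representative reserve network would need at this resolution.
"""

import comprep as cp

dataset = cp.simulate_dataset(cp.SimulationConfig(seed=1))
print(dataset.incidence)

for universe in ("all", "threatened"):
    cs = cp.build_complementary_set(
        dataset.incidence, dataset.species, cp.SelectionConfig(universe=universe)
    )
    print(f"\n{universe} species universe:")
    print(f"  CS size: {len(cs.members)} units")
    print(f"  species covered: {len(cs.covered_species)}")
    print("  first selections (unit, stage, score, new species):")
    for step in cs.steps[:5]:
        print(
            f"    {step.unit_id}  {step.stage:<9} "
            f"score={step.score:.3f}  +{step.n_new_species}"
        )

# The seed unit is the richest unit within the universe; later steps add
# the unit most complementary (score 1 = completely different species)
# to the pooled species of the set so far, priority species first.
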