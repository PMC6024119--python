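"""Score a protected-area layer against a complementary set.

Computes the ecological representation index I_E = a/(a+b) x 100 under
the PA-presence criterion and a ladder of coverage thresholds, lists the
conservation gaps (CS units without adequate protection and the species
they leave exposed), the congruence between the CS and the PA-holding
units, and the distribution of CS area over PA-coverage classes.
"""

import comprep as cp

dataset = cp.simulate_dataset(cp.SimulationConfig(seed=1))
cs = cp.build_complementary_set(dataset.incidence, dataset.species)
print(f"CS: {len(cs.members)} units covering {len(cs.covered_species)} species\n")

print("criterion        a    b    I_E")
for criterion in ["presence", *cp.DEFAULT_THRESHOLDS]:
    s_p = cp.select_protected_units(dataset.units, criterion)
    r = cp.representation_index(cs, s_p, criterion)
    label = criterion if criterion == "presence" else f"coverage>={criterion:g}"
    print(f"{label:<14} {r.a:4d} {r.b:4d}  {r.i_e:5.1f}%")
# I_E is the share of CS units protected under the criterion; it can only
# fall as the coverage bar rises.

s_p = cp.select_protected_units(dataset.units, "presence")
gaps = cp.identify_gaps(
    cs, s_p, dataset.incidence, set(dataset.incidence.species), dataset.species
)
print(
    f"\ngaps at the presence criterion: {len(gaps.gap_units)} units; "
    f"{len(gaps.uncovered_species)} species in no protected unit "
    f"({len(gaps.threatened_uncovered)} threatened, "
    f"{len(gaps.endemic_uncovered)} endemic)"
)

cong = cp.congruence_summary(cs, s_p, dataset.units)
print(
    f"congruence: {cong.n_common} of {cong.n_union} units in the CS/PA union "
    f"are in both ({cong.pct_common_int:.0f}% of counts, "
    f"{cong.area_pct_common:.1f}% of area)"
)

print("\nCS area by PA-coverage class (share of total CS area):")
classes = cp.coverage_class_areas(cs, dataset.units)
for row in classes.itertuples(index=False):
    print(f"  {row.coverage_class:<12} {row.n_units:3d} units  {row.area_pct:5.1f}%")
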