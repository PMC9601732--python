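"""Compare female, male and integrated marker orders by multipoint likelihood.

On one simulated linkage group, estimates a marker order from the female
data alone, the male data alone, and the merged dataset, then scores all
three orders on the merged data with the multipoint HMM (interval r
re-estimated per order).
"""

from radmap import (
    FEMALE,
    MALE,
    SimConfig,
    bc_matrix_from_records,
    compare_orders,
    harmonize_phases,
    merge_datasets,
    order_markers,
    simulate_f1,
)

sim = simulate_f1(SimConfig(n_chromosomes=1, tags_per_chromosome=15, seed=17))
by_id = {r.marker_id: r for r in sim.records}
ids = [t.tag_id for t in sim.tags]
female = bc_matrix_from_records([by_id[t.snp_f] for t in sim.tags], FEMALE, marker_ids=ids)
male = bc_matrix_from_records([by_id[t.snp_m] for t in sim.tags], MALE, marker_ids=ids)

female_order = order_markers(female, seed=17)
male_order = order_markers(male, seed=17)
merged = merge_datasets(harmonize_phases(female, female_order),
                        harmonize_phases(male, female_order))
integrated_order = order_markers(merged, seed=17)

lls = compare_orders(
    merged,
    {"INTEGRATED": integrated_order, "FEMALE": female_order, "MALE": male_order},
    estimate_error=True,
)
print("order estimated from        log10 L on merged data")
for name, ll in lls.items():
    print(f"  {name:<24} {ll:12.2f}")
print(f"\ntrue order recovered by the integrated search: "
      f"{integrated_order == sim.truth.tag_order['Chr01'] or integrated_order == sim.truth.tag_order['Chr01'][::-1]}")
print("-> the order built from both meioses fits the merged data at least as well")
print("   as either single-parent order: the integrated map's statistical advantage.")
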