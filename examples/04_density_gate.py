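"""The density gate and how particle concentration moves the thrombus site.

Below the minimum uniform density rho_m no thrombus can form anywhere,
whatever the Reynolds number.  Above it, the origin-to-collision distance
shrinks as p = p0*sqrt(rho_m/rho_i), so concentrating particles in a
distal branch (while the trunk falls below the gate) moves the predicted
site distally.
"""

from portalwalk import (
    DensityParams,
    FluidProperties,
    WalkConfig,
    build_tree,
    collision_distance,
    generate_fixture_tree,
    rank_sites,
    thrombus_gate,
)

params = DensityParams(rho_m=1.0, p0=6.0)
for rho in (0.5, 1.0, 4.0):
    gate = thrombus_gate(rho, params.rho_m)
    dist = (collision_distance(rho, params)
            if gate.value == "feasible" else float("nan"))
    print(f"rho_i = {rho:4.1f} rho_m -> gate {gate.value:12s} "
          f"collision distance p = {dist:.2f}")

tree = build_tree(generate_fixture_tree(3, seed=0))
rho_field = {s.id: 0.2 for s in tree.segments}  # trunk & most branches gated
rho_field["mpv_l_l"] = 4.0  # particles concentrated distally
table = rank_sites(tree, rho_field, FluidProperties(), WalkConfig(k=1.0), params)
print()
print(table[["segment_id", "gate", "i_total", "log10_p_r4", "rank",
             "predicted"]].to_string(index=False))
print("\nWith the trunk below rho_m it is excluded outright; the dense")
print("distal branch becomes the predicted thrombus site.")
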