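"""Build a chronospace and rank methodological factors by impact.

Simulates a factorial dating study (40 settings x 2 runs x 200 posterior
chronograms on a 60-tip tree) in which only the clock model truly shifts
node ages (+30 Myr on 10 clades), then asks the between-group PCA which
factor separates the chronograms most.
"""

from chronospace import (
    SimulationConfig,
    factor_impact,
    node_shifts,
    permutation_baseline,
    simulate_chronospace,
)

sim = simulate_chronospace(SimulationConfig(seed=1))
matrix = sim.matrix
print(f"chronospace: {matrix.n_samples} chronograms x {matrix.n_nodes} node ages\n")

table, results = factor_impact(matrix)
print(table[["factor", "n_levels", "n_axes", "variance_explained_pct"]]
      .to_string(index=False))
print("\nThe % of total node-age variance captured by each factor's bgPCA axes")
print("estimates that factor's impact on divergence times. Only the clock is")
print("truly shifted here, so it should rank far above the null factors.\n")

shifts = node_shifts(matrix, "clock", threshold=20.0)
print(f"nodes whose mean age shifts by >20 Myr between clocks: "
      f"{int(shifts['flagged'].sum())} of {matrix.n_nodes}")
print(shifts.head(3)[["node", "max_shift"]].to_string(index=False))

pb = permutation_baseline(matrix, "clock", n_perm=99, seed=1)
print(f"\nobserved clock variance explained: {100 * pb.observed:.1f}%")
print(f"permutation null (label shuffles): median "
      f"{100 * float(pb.quantile(0.5)):.1f}%, observed percentile {pb.percentile:.0f}")
print("bgPCA separates even random groupings somewhat; the permutation")
print("baseline shows the clock effect far exceeds that chance level.")
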