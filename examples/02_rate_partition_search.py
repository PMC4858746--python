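"""Detect a clade with decoupled gain/loss rates by stepwise AIC.

Plants a subclade whose transition rates are 10x the background, then
runs the greedy shift search: every internal node with >= 5 descendant
tips is a candidate, a new (q01, q10) matrix is accepted when AIC improves
by more than 2, and all rates are re-optimized jointly after acceptance.
"""

import mimevol as mv

tree = mv.simulate_yule_tree(n_tips=150, birth_rate=0.05, seed=8)
counts = tree.n_descendant_tips()
clade = max(
    (v for v in range(tree.n_tips, tree.n_nodes) if v != tree.root
     and 25 <= counts[v] <= 60),
    key=lambda v: counts[v],
)
truth = mv.PartitionModel(
    [mv.RateMatrix2(0.001, 0.002), mv.RateMatrix2(0.01, 0.02)],
    shift_nodes={int(clade): 1},
)
traits, _ = mv.simulate_discrete_history(tree, truth, root_state_prob=0.0, seed=9)
print(f"planted shift at node {clade} ({counts[clade]} tips), "
      f"{sum(traits.values())} banded tips")

result = mv.stepwise_partition_search(tree, traits, min_descendants=5,
                                      delta_aic=2.0, seed=3)
print("\nAIC trace (one row per accepted model):")
print(result.trace_table()[["step", "n_matrices", "k", "loglik", "aic",
                            "shift_node"]].to_string(index=False))
print(f"\nstopping reason: {result.stopping_reason}")
for node, idx in result.model.shift_nodes.items():
    m = result.model.matrices[idx]
    print(f"accepted shift at node {node}: q01={m.q01:.4f}, q10={m.q10:.4f} per Myr")
m0 = result.model.matrices[0]
print(f"background rates: q01={m0.q01:.4f}, q10={m0.q10:.4f} per Myr")
# With enough signal the accepted shift lands at (or adjacent to) the
# planted node and the clade rates come out roughly 10x the background.
# When every banded tip falls inside the shifted clade the background
# loss rate is unidentifiable and may sit at an arbitrary/boundary value.
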