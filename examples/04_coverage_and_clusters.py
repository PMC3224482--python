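"""Coverage ("SCs explained") and prediction-pattern clusters.

Coverage asks what fraction of the observed State Changes lie causally
downstream, with consistent sign, of at least one significant hypothesis.
Clusters classify each node's significance pattern across three ordered
comparisons (reference exposed vs sham, perturbed exposed vs sham,
perturbed vs reference under exposure) into dependence classes A-E.
"""

import stressrcr as s

spec = s.SyntheticSpec(n_regulators=20, n_genes=800, mean_out_degree=8.0,
                       seed=77)
net = s.generate_network(spec)
spec = s.choose_active(spec, net, n_active=4)
scs, truth = s.simulate_state_changes(net, spec)

sig = [h for h in s.best_directions(s.run_rcr(net, scs)) if h.significant]
rep = s.coverage(scs, sig, net)
print(f"SCs explained by network: {len(rep.explained)}/{rep.total_sc} "
      f"({rep.fraction:.0%})")

subset = [truth[0][0]]  # restrict to one planted regulator
rep1 = s.coverage_by_nodes(scs, subset, sig, net)
print(f"SCs explained by {s.format_term(subset[0])}: "
      f"{len(rep1.explained)}/{rep1.total_sc} ({rep1.fraction:.0%})")

term = s.parse_term("taof(X)")
for calls in [(+1, 0, -1), (+1, +1, -1), (+1, +1, 0), (+1, 0, 0), (0, +1, 0)]:
    (a,) = s.assign_clusters([s.PredictionPattern(term, calls)])
    print(f"pattern {calls} -> cluster {a.cluster}")
# Full coverage means every planted change sits downstream of a recovered
# regulator with the right sign; the five patterns instantiate the five
# dependence classes.
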