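"""Score upstream hypotheses against State Changes (reverse causal reasoning).

Five regulators are switched on in a 50-regulator network; their transcript
targets all change in the implied direction (q = 1, no background noise).
Every eligible node is scored in both directions: richness is the
hypergeometric upper tail of the target/SC overlap, concordance the binomial
upper tail of the direction agreement.
"""

import stressrcr as s

spec = s.SyntheticSpec(n_regulators=50, n_genes=2000, mean_out_degree=8.0,
                       concordance_prob=1.0, background_sc_rate=0.0, seed=1)
net = s.generate_network(spec)
spec = s.choose_active(spec, net, n_active=5)
scs, truth = s.simulate_state_changes(net, spec)

scores = s.run_rcr(net, scs)  # defaults: n >= 4, c >= 4, both cutoffs 0.1
print("term\tdir\tn\tk\tc\trichness_p\tconcordance_p\tsig")
for h in s.best_directions(scores)[:7]:
    print(f"{s.format_term(h.term)}\t{h.direction[:3]}\t{h.n}\t{h.k}\t{h.c}"
          f"\t{h.richness_p:.2e}\t{h.concordance_p:.2e}\t{h.significant}")

m = s.recovery_metrics(scores, truth)
print(f"precision={m['precision']:.2f} recall={m['recall']:.2f} "
      f"direction_accuracy={m['direction_accuracy']:.2f}")
# The five planted regulators should top the ranking as significant with the
# planted directions (all three metrics 1.00); inactive regulators have no
# overlap and richness 1.
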