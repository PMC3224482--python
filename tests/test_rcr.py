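import math
from fractions import Fraction
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stressrcr as s


def enum_richness(N, K, n, k):
    """Fraction of all K-subsets of an N-population whose overlap with a
    fixed n-draw is >= k (exhaustive oracle, small N only)."""
    draw = set(range(n))
    hits = sum(1 for sub in combinations(range(N), K)
               if len(draw & set(sub)) >= k)
    return Fraction(hits, math.comb(N, K))


def binom_tail(c, contra, p=Fraction(1, 2)):
    """Explicit binomial upper-tail sum, exact fractions for rational p."""
    t = c + contra
    return sum(Fraction(math.comb(t, i)) * p**i * (1 - p)**(t - i)
               for i in range(c, t + 1))


class TestScoreRichness:
    def test_zero_overlap_returns_one(self):
        assert s.score_richness(100, 10, 5, 0) == 1.0

    def test_closed_form_full_overlap(self):
        assert s.score_richness(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_against_enumeration_spot(self):
        expected = float(enum_richness(20, 6, 5, 3))
        assert s.score_richness(20, 6, 5, 3) == pytest.approx(expected, rel=1e-10)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            s.score_richness(10, 5, 5, 6)
        with pytest.raises(ValueError):
            s.score_richness(10, 12, 5, 2)

    def test_monotone_in_overlap(self):
        vals = [s.score_richness(50, 20, 10, k) for k in range(11)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))


class TestScoreConcordance:
    def test_forced_closed_form(self):
        assert s.score_concordance(4, 0, 0.5) == pytest.approx(0.0625, abs=1e-15)

    def test_no_trials(self):
        assert s.score_concordance(0, 0) == 1.0
        assert s.score_concordance(0, 7) == 1.0

    def test_tail_sum_oracle(self):
        assert s.score_concordance(5, 2, 0.5) == pytest.approx(29 / 128, rel=1e-12)

    def test_bad_probability(self):
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                s.score_concordance(3, 1, p)

    def test_more_consistent_never_increases_p(self):
        vals = [s.score_concordance(c, 10 - c) for c in range(1, 11)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    @given(c=st.integers(0, 15), contra=st.integers(0, 15),
           p=st.floats(0.05, 0.95))
    @settings(max_examples=80, derandomize=True)
    def test_matches_explicit_sum(self, c, contra, p):
        t = c + contra
        expected = 1.0 if c == 0 else sum(
            math.comb(t, i) * p**i * (1 - p)**(t - i) for i in range(c, t + 1))
        assert s.score_concordance(c, contra, p) == pytest.approx(
            expected, rel=1e-9, abs=1e-12)


class TestBuildSignatures:
    def test_eligibility_threshold(self, tiny_network):
        sigs = s.build_signatures(tiny_network, {"g1", "g2", "g3", "g4", "g5"})
        # TF1 has 4 measured transcript targets, TF2 only 2 (g3 ambiguous + g5)
        terms = {s.format_term(x.hypothesis_term) for x in sigs}
        assert terms == {"taof(TF1)"}

    def test_ambiguous_sign_zero(self, tiny_network):
        cfg = s.RcrConfig(min_downstream_measured=1)
        sigs = {s.format_term(x.hypothesis_term): x
                for x in s.build_signatures(tiny_network, {"g3", "g5"}, cfg)}
        assert sigs["taof(TF2)"].targets == {"g3": 0, "g5": +1}

    def test_targets_restricted_to_measured(self, tiny_network):
        cfg = s.RcrConfig(min_downstream_measured=2)
        (sig,) = s.build_signatures(tiny_network, {"g1", "g3"}, cfg)
        assert sig.targets == {"g1": +1, "g3": -1}

    def test_self_transcript_excluded(self):
        t = s.parse_term
        net = s.NetworkModel(edges=[
            s.CausalEdge(t("r(A)"), t("r(A)"), 1),
            s.CausalEdge(t("r(A)"), t("r(B)"), 1)])
        cfg = s.RcrConfig(min_downstream_measured=1)
        (sig,) = s.build_signatures(net, {"A", "B"}, cfg)
        assert sig.targets == {"B": +1}


class TestEvaluateHypothesis:
    def _sig(self, targets):
        return s.DownstreamSignature(s.parse_term("taof(X)"), targets)

    def _scs(self, dirs, n_pop=100):
        base = set(dirs) | {f"g{i}" for i in range(9)}
        pop = frozenset(base) | {f"bg{i}" for i in range(n_pop - len(base))}
        changes = [s.StateChange(g, "increased" if d > 0 else "decreased",
                                 2.0, 0.01) for g, d in dirs.items()]
        return s.StateChangeSet("t", pop, changes)

    def test_derived_example(self):
        sig = self._sig({"g1": +1, "g2": +1, "g3": -1, "g4": +1})
        scs = self._scs({"g1": +1, "g2": +1, "g3": -1, "g4": -1})
        inc, dec = s.evaluate_hypothesis(sig, scs)
        assert (inc.N, inc.K, inc.n, inc.k) == (100, 4, 4, 4)
        assert (inc.c, inc.contra, inc.ambiguous) == (3, 1, 0)
        assert inc.concordance_p == pytest.approx(5 / 16)
        assert dec.c == 1 and dec.contra == 3
        assert inc.richness_p == dec.richness_p

    def test_perfect_match_directional_split(self):
        sig = self._sig({f"g{i}": +1 for i in range(5)})
        scs = self._scs({f"g{i}": +1 for i in range(5)})
        inc, dec = s.evaluate_hypothesis(sig, scs)
        assert inc.concordance_p == pytest.approx(0.5 ** 5)
        assert dec.concordance_p == 1.0  # c = 0

    def test_mirror_symmetry(self):
        sig = self._sig({"g1": +1, "g2": -1, "g3": +1, "g4": +1, "g5": -1})
        dirs = {"g1": +1, "g2": +1, "g4": -1, "g5": -1}
        inc, dec = s.evaluate_hypothesis(sig, self._scs(dirs))
        flipped = self._sig({g: -v for g, v in sig.targets.items()})
        inc_f, dec_f = s.evaluate_hypothesis(flipped, self._scs(dirs))
        assert (inc.c, inc.contra, inc.concordance_p) == \
            (dec_f.c, dec_f.contra, dec_f.concordance_p)
        assert (dec.c, dec.contra) == (inc_f.c, inc_f.contra)

    def test_flipping_scs_swaps_directions(self):
        sig = self._sig({"g1": +1, "g2": -1, "g3": +1})
        dirs = {"g1": +1, "g3": -1}
        inc, dec = s.evaluate_hypothesis(sig, self._scs(dirs))
        inc2, dec2 = s.evaluate_hypothesis(
            sig, self._scs({g: -d for g, d in dirs.items()}))
        assert (inc.c, inc.contra) == (dec2.c, dec2.contra)
        assert (dec.c, dec.contra) == (inc2.c, inc2.contra)

    def test_ambiguous_in_k_not_in_trials(self):
        sig = self._sig({"g1": 0, "g2": +1, "g3": +1})
        scs = self._scs({"g1": +1, "g2": +1, "g3": +1})
        inc, _ = s.evaluate_hypothesis(sig, scs)
        assert inc.k == 3 and inc.ambiguous == 1
        assert inc.c + inc.contra + inc.ambiguous == inc.k
        assert inc.concordance_p == pytest.approx(0.25)  # 2 trials, 2 hits

    @given(st.dictionaries(st.sampled_from([f"g{i}" for i in range(8)]),
                           st.sampled_from([-1, 0, 1]), min_size=1),
           st.dictionaries(st.sampled_from([f"g{i}" for i in range(8)]),
                           st.sampled_from([-1, 1])))
    @settings(max_examples=80, derandomize=True)
    def test_count_conservation(self, targets, dirs):
        sig = self._sig(targets)
        scs = self._scs(dirs, n_pop=20)
        inc, dec = s.evaluate_hypothesis(sig, scs)
        for h in (inc, dec):
            assert h.k == h.c + h.contra + h.ambiguous
            assert h.k <= min(h.n, h.K)
            assert 0 < h.richness_p <= 1 and 0 < h.concordance_p <= 1


class TestRunRcr:
    def test_empty_sc_set(self, tiny_network):
        scs = s.StateChangeSet("empty", frozenset({"g1", "g2", "g3", "g4"}), [])
        scores = s.run_rcr(tiny_network, scs)
        assert scores and all(h.richness_p == 1.0 for h in scores)
        assert not any(h.significant for h in scores)

    def test_significance_needs_min_correct(self, tiny_network, tiny_scs):
        scores = s.run_rcr(tiny_network, tiny_scs)
        for h in scores:
            if h.significant:
                assert h.c >= 4
                assert h.richness_p < 0.1 and h.concordance_p < 0.1

    def test_planted_regulator_recovered(self):
        spec = s.SyntheticSpec(n_regulators=10, n_genes=500,
                               mean_out_degree=8, seed=5)
        net = s.generate_network(spec)
        spec = s.choose_active(spec, net, 1)
        scs, truth = s.simulate_state_changes(net, spec)
        best = {h.term: h for h in s.best_directions(s.run_rcr(net, scs))}
        (term, direction), = truth
        assert best[term].significant and best[term].direction == direction

    def test_node_absent_from_network_absent_from_output(self, tiny_network, tiny_scs):
        terms = {s.format_term(h.term) for h in s.run_rcr(tiny_network, tiny_scs)}
        assert "taof(TF99)" not in terms
        assert all(s.parse_term(t) in tiny_network.nodes for t in terms)

    def test_sorted_by_concordance_then_richness(self, tiny_network, tiny_scs):
        cfg = s.RcrConfig(min_downstream_measured=1)
        scores = s.run_rcr(tiny_network, tiny_scs, cfg)
        keys = [(h.concordance_p, h.richness_p) for h in scores]
        assert keys == sorted(keys)

    def test_population_modes(self, tiny_network, tiny_scs):
        cfg = s.RcrConfig(min_downstream_measured=1,
                          population_mode="all-network-downstream-measured")
        scores = s.run_rcr(tiny_network, tiny_scs, cfg)
        # population restricted to genes downstream of some node
        assert all(h.N <= len(tiny_scs.population) for h in scores)
        downstream = {"g1", "g2", "g3", "g4", "g5"}
        assert {h.N for h in scores} == {len(downstream)}


def test_exhaustive_richness_small_grid():
    """Hypergeometric tail equals subset enumeration on a compact grid."""
    for N in (5, 8):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(1, min(n, K) + 1):
                    expected = float(enum_richness(N, K, n, k))
                    assert s.score_richness(N, K, n, k) == pytest.approx(
                        expected, abs=1e-12)
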