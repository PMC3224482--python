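"""Reverse Causal Reasoning: scoring upstream hypotheses against State Changes.

Every network node with enough measured downstream transcripts is a candidate
upstream explanation ("hypothesis") for an observed set of State Changes.
Each hypothesis is scored in both activity directions with two probabilities:

* **richness** — hypergeometric upper tail: how surprising is the overlap
  between the hypothesis's measured downstream transcripts and the SC set,
  ignoring direction;
* **concordance** — binomial upper tail under a direction coin-flip null:
  how surprising is the number of overlaps whose observed direction matches
  the direction the hypothesis implies.

A hypothesis is significant when both probabilities fall below their cutoffs
(default 0.1) and at least ``min_correct`` (default 4) overlaps are
direction-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, TextIO

import pandas as pd
from scipy import stats

from .network import BiologicalTerm, NetworkModel, format_term, parse_term
from .state_changes import StateChangeSet

__all__ = [
    "DownstreamSignature",
    "RcrConfig",
    "HypothesisScore",
    "build_signatures",
    "score_richness",
    "score_concordance",
    "evaluate_hypothesis",
    "run_rcr",
    "best_directions",
    "write_hypotheses_tsv",
    "read_hypotheses_tsv",
]


@dataclass(frozen=True)
class DownstreamSignature:
    """Measured transcripts causally downstream of one node.

    ``targets`` maps gene symbol to the sign its rna-abundance takes when the
    hypothesis node increases; a gene reached by both + and - causal edges is
    stored with sign 0 (ambiguous).
    """

    hypothesis_term: BiologicalTerm
    targets: dict[str, int]

    def __post_init__(self):
        bad = {g: s for g, s in self.targets.items() if s not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"signature signs must be -1/0/+1: {bad}")


@dataclass
class RcrConfig:
    min_downstream_measured: int = 4
    min_correct: int = 4
    richness_cutoff: float = 0.1
    concordance_cutoff: float = 0.1
    binomial_success_prob: float = 0.5
    population_mode: str = "all-measured-genes"  # or "all-network-downstream-measured"

    def __post_init__(self):
        if not (0 < self.richness_cutoff <= 1 and 0 < self.concordance_cutoff <= 1):
            raise ValueError("cutoffs must lie in (0, 1]")
        if self.min_downstream_measured < 1 or self.min_correct < 1:
            raise ValueError("minimum counts must be >= 1")
        if not 0 < self.binomial_success_prob < 1:
            raise ValueError("binomial success probability must lie in (0, 1)")
        if self.population_mode not in ("all-measured-genes",
                                        "all-network-downstream-measured"):
            raise ValueError(f"unknown population mode {self.population_mode!r}")


@dataclass
class HypothesisScore:
    """One candidate upstream regulator in one direction.

    Count bookkeeping: population N contains K State Changes; the hypothesis
    has n measured downstream transcripts of which k are State Changes,
    split into c consistent, ``contra`` contradicting and ``ambiguous``
    (sign-0 edge) overlaps, so k = c + contra + ambiguous always.
    """

    term: BiologicalTerm
    direction: str  # "increase" | "decrease"
    N: int
    K: int
    n: int
    k: int
    c: int
    contra: int
    ambiguous: int
    richness_p: float
    concordance_p: float
    significant: bool

    def __post_init__(self):
        if self.k != self.c + self.contra + self.ambiguous:
            raise ValueError("overlap counts must satisfy k = c + contra + ambiguous")


def score_richness(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts State Changes among the hypothesis's n downstream draws from a
    population of N genes containing K State Changes.  k = 0 returns 1.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def score_concordance(c: int, contra: int, success_prob: float = 0.5) -> float:
    """Upper-tail binomial probability P(X >= c) with X ~ Bin(c + contra, p).

    Ambiguous overlaps never enter the trial count.  c = 0 returns 1.
    """
    if c < 0 or contra < 0:
        raise ValueError("counts must be non-negative")
    if not 0 < success_prob < 1:
        raise ValueError("success probability must lie in (0, 1)")
    if c == 0:
        return 1.0
    return float(stats.binom.sf(c - 1, c + contra, success_prob))


def build_signatures(kam: NetworkModel, measured_genes: Iterable[str],
                     config: RcrConfig | None = None) -> list[DownstreamSignature]:
    """One signature per node with >= ``min_downstream_measured`` measured
    rna-abundance targets reachable by causal edges.

    A node's own transcript is excluded from its signature (a hypothesis
    cannot count itself as evidence); a gene reached by edges of both signs
    gets sign 0.
    """
    config = config or RcrConfig()
    measured = set(measured_genes)
    per_node: dict[BiologicalTerm, dict[str, set[int]]] = {}
    for e in kam.causal_edges:
        if e.target.function != "rna-abundance":
            continue
        gene = e.target.entity
        if gene not in measured:
            continue
        if e.source.function == "rna-abundance" and e.source.entity == gene:
            continue  # self-loop
        per_node.setdefault(e.source, {}).setdefault(gene, set()).add(e.sign)
    sigs = []
    for node, genes in sorted(per_node.items(), key=lambda kv: format_term(kv[0])):
        targets = {g: (next(iter(s)) if len(s) == 1 else 0)
                   for g, s in genes.items()}
        if len(targets) >= config.min_downstream_measured:
            sigs.append(DownstreamSignature(node, targets))
    return sigs


def _population(sig_targets_union: set[str], scs: StateChangeSet,
                config: RcrConfig) -> frozenset[str]:
    if config.population_mode == "all-measured-genes":
        return scs.population
    return frozenset(sig_targets_union & scs.population)


def evaluate_hypothesis(sig: DownstreamSignature, scs: StateChangeSet,
                        config: RcrConfig | None = None,
                        population: frozenset[str] | None = None
                        ) -> tuple[HypothesisScore, HypothesisScore]:
    """Score one signature in both directions against a State Change set.

    Under the *increase* direction a target with implied sign ``s`` and
    observed SC direction ``d`` (+1 increased, -1 decreased) is consistent
    iff ``s * d == +1``; the *decrease* direction mirrors.  Richness is
    direction-blind and identical for both.
    """
    config = config or RcrConfig()
    population = population if population is not None else scs.population
    stray = set(sig.targets) - set(population)
    if stray:
        raise ValueError(f"signature targets outside population: {sorted(stray)}")
    sc_dirs = {g: d for g, d in scs.directions.items() if g in population}
    N = len(population)
    K = len(sc_dirs)
    n = len(sig.targets)
    overlap = {g: s for g, s in sig.targets.items() if g in sc_dirs}
    k = len(overlap)
    ambiguous = sum(1 for s in overlap.values() if s == 0)
    c_inc = sum(1 for g, s in overlap.items() if s != 0 and s * sc_dirs[g] == +1)
    contra_inc = k - ambiguous - c_inc
    rich = score_richness(N, K, n, k)
    out = []
    for direction, c, contra in (("increase", c_inc, contra_inc),
                                 ("decrease", contra_inc, c_inc)):
        conc = score_concordance(c, contra, config.binomial_success_prob)
        significant = (rich < config.richness_cutoff
                       and conc < config.concordance_cutoff
                       and c >= config.min_correct)
        out.append(HypothesisScore(sig.hypothesis_term, direction, N, K, n, k,
                                   c, contra, ambiguous, rich, conc, significant))
    return out[0], out[1]


def run_rcr(kam: NetworkModel, scs: StateChangeSet,
            config: RcrConfig | None = None) -> list[HypothesisScore]:
    """Score every eligible node in both directions, sorted ascending by
    (concordance_p, richness_p, term name, direction)."""
    config = config or RcrConfig()
    sigs = build_signatures(kam, scs.population, config)
    union = {g for s in sigs for g in s.targets}
    population = _population(union, scs, config)
    scores: list[HypothesisScore] = []
    for sig in sigs:
        inc, dec = evaluate_hypothesis(sig, scs, config, population)
        scores.extend((inc, dec))
    scores.sort(key=lambda h: (h.concordance_p, h.richness_p,
                               format_term(h.term), h.direction))
    return scores


def best_directions(scores: Iterable[HypothesisScore]) -> list[HypothesisScore]:
    """Keep, per term, the direction with the smaller concordance_p; ties
    break toward increase."""
    by_term: dict[BiologicalTerm, list[HypothesisScore]] = {}
    for h in scores:
        by_term.setdefault(h.term, []).append(h)
    best = []
    for pair in by_term.values():
        pair.sort(key=lambda h: (h.concordance_p, 0 if h.direction == "increase" else 1))
        best.append(pair[0])
    best.sort(key=lambda h: (h.concordance_p, h.richness_p, format_term(h.term)))
    return best


_COLS = ["term", "direction", "N", "K", "n", "k", "c", "contra", "ambiguous",
         "richness_p", "concordance_p", "significant"]


def write_hypotheses_tsv(scores: Iterable[HypothesisScore], stream: TextIO) -> None:
    stream.write("\t".join(_COLS) + "\n")
    for h in scores:
        stream.write("\t".join([
            format_term(h.term), h.direction, str(h.N), str(h.K), str(h.n),
            str(h.k), str(h.c), str(h.contra), str(h.ambiguous),
            f"{h.richness_p:.6g}", f"{h.concordance_p:.6g}",
            str(h.significant)]) + "\n")


def read_hypotheses_tsv(stream: TextIO) -> list[HypothesisScore]:
    df = pd.read_csv(stream, sep="\t")
    return [HypothesisScore(parse_term(r.term), r.direction, int(r.N), int(r.K),
                            int(r.n), int(r.k), int(r.c), int(r.contra),
                            int(r.ambiguous), float(r.richness_p),
                            float(r.concordance_p),
                            str(r.significant) == "True")
            for r in df.itertuples()]
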