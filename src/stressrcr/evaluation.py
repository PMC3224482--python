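"""Downstream analytics over RCR runs.

Three questions are answered here:

* **coverage** — what fraction of the State Changes lie causally downstream,
  with consistent sign, of at least one significant hypothesis ("SCs
  explained by the network"), optionally restricted to a node subset ("SCs
  explained by Nfe2l2");
* **overlap** — how much do SC sets from different comparisons share, by
  gene and by gene + direction;
* **clusters** — given significance calls for the same nodes across three
  ordered comparisons (exposed vs sham in a reference genotype, exposed vs
  sham in a perturbed genotype, perturbed vs reference under exposure),
  assign each node a dependence pattern A-E.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .network import BiologicalTerm, NetworkModel, format_term
from .rcr import HypothesisScore
from .state_changes import StateChangeSet

__all__ = [
    "CoverageReport",
    "PredictionPattern",
    "ClusterAssignment",
    "coverage",
    "coverage_by_nodes",
    "overlap_statistics",
    "assign_clusters",
    "patterns_from_scores",
]


@dataclass
class CoverageReport:
    label: str
    explained: frozenset[str]
    total_sc: int
    per_hypothesis: dict[str, int]  # term string -> SCs it explains

    @property
    def fraction(self) -> float:
        return len(self.explained) / self.total_sc if self.total_sc else 0.0


def _direction_value(direction: str) -> int:
    return +1 if direction == "increase" else -1


def _explained_genes(scs: StateChangeSet, hyps: Iterable[HypothesisScore],
                     kam: NetworkModel, require_sign_match: bool
                     ) -> tuple[set[str], dict[str, int]]:
    sc_dirs = scs.directions
    downstream: dict[BiologicalTerm, dict[str, set[int]]] = {}
    for e in kam.causal_edges:
        if e.target.function == "rna-abundance":
            downstream.setdefault(e.source, {}) \
                .setdefault(e.target.entity, set()).add(e.sign)
    explained: set[str] = set()
    per_hyp: dict[str, int] = {}
    for h in hyps:
        d = _direction_value(h.direction)
        mine = set()
        for gene, signs in downstream.get(h.term, {}).items():
            if gene not in sc_dirs:
                continue
            if not require_sign_match or any(s * d == sc_dirs[gene] for s in signs):
                mine.add(gene)
        per_hyp[f"{format_term(h.term)}:{h.direction}"] = len(mine)
        explained |= mine
    return explained, per_hyp


def coverage(scs: StateChangeSet, significant: Iterable[HypothesisScore],
             kam: NetworkModel, require_sign_match: bool = True) -> CoverageReport:
    """Fraction of SC genes explained by the significant hypotheses.

    An SC gene g is explained iff some hypothesis (term, direction) has a
    causal edge term -> r(g) whose implied direction (edge sign times
    hypothesis direction) matches g's observed direction; with
    ``require_sign_match=False`` any causal edge to r(g) suffices.
    """
    hyps = [h for h in significant if h.significant]
    explained, per_hyp = _explained_genes(scs, hyps, kam, require_sign_match)
    return CoverageReport(scs.label, frozenset(explained), len(scs), per_hyp)


def coverage_by_nodes(scs: StateChangeSet, node_subset: Iterable[BiologicalTerm],
                      significant: Iterable[HypothesisScore],
                      kam: NetworkModel,
                      require_sign_match: bool = True) -> CoverageReport:
    """Same rule as :func:`coverage`, restricted to hypotheses whose term is
    in ``node_subset``.  Raises if a subset node is absent from the network."""
    subset = set(node_subset)
    missing = subset - kam.nodes
    if missing:
        raise ValueError("nodes not in network: "
                         + ", ".join(sorted(format_term(n) for n in missing)))
    hyps = [h for h in significant if h.significant and h.term in subset]
    explained, per_hyp = _explained_genes(scs, hyps, kam, require_sign_match)
    return CoverageReport(scs.label, frozenset(explained), len(scs), per_hyp)


def overlap_statistics(sets: Sequence[StateChangeSet]) -> list[dict]:
    """Pairwise SC overlap: counts by gene and by gene + direction, with
    fractions relative to each member of the pair."""
    if len(sets) < 2:
        raise ValueError("need at least two state-change sets")
    out = []
    for a, b in combinations(sets, 2):
        ga, gb = set(a.directions), set(b.directions)
        gene_overlap = ga & gb
        dir_overlap = {g for g in gene_overlap
                       if a.directions[g] == b.directions[g]}
        out.append({
            "a": a.label, "b": b.label,
            "n_a": len(ga), "n_b": len(gb),
            "gene_overlap": len(gene_overlap),
            "gene_direction_overlap": len(dir_overlap),
            "fraction_of_a": len(gene_overlap) / len(ga) if ga else 0.0,
            "fraction_of_b": len(gene_overlap) / len(gb) if gb else 0.0,
        })
    return out


@dataclass(frozen=True)
class PredictionPattern:
    """Significance calls for one term over a fixed, ordered comparison list:
    +1 significant-increase, -1 significant-decrease, 0 not significant."""

    term: BiologicalTerm
    calls: tuple[int, ...]

    def __post_init__(self):
        if any(c not in (-1, 0, 1) for c in self.calls):
            raise ValueError("calls must be -1/0/+1")


@dataclass(frozen=True)
class ClusterAssignment:
    term: BiologicalTerm
    cluster: str  # A..E or "unclustered"


def _classify(c1: int, c2: int, c3: int) -> str:
    # ordered first-match rules over the three-comparison pattern
    if c1 != 0 and c2 == 0 and c3 == -c1:
        return "A"   # signal lost in the perturbed genotype, reversed head-to-head
    if c1 != 0 and c2 == c1 and c3 == -c1:
        return "B"   # shared response, partially dependent on the perturbation
    if c1 != 0 and c2 == c1 and c3 == 0:
        return "C"   # shared response, perturbation-independent
    if c1 != 0 and c2 == 0 and c3 == 0:
        return "D"   # reference-genotype-only response
    if c1 == 0 and c2 != 0 and c3 == 0:
        return "E"   # perturbed-genotype-only response
    return "unclustered"


def assign_clusters(patterns: Iterable[PredictionPattern]) -> list[ClusterAssignment]:
    """Assign each 3-comparison pattern its cluster (A-E or unclustered)."""
    out = []
    for p in patterns:
        if len(p.calls) != 3:
            raise ValueError(f"pattern for {format_term(p.term)} must have 3 calls")
        out.append(ClusterAssignment(p.term, _classify(*p.calls)))
    return out


def patterns_from_scores(score_lists: Sequence[Sequence[HypothesisScore]]
                         ) -> list[PredictionPattern]:
    """Build per-term patterns from best-direction score tables of ordered
    comparisons; terms absent from a run get call 0 there."""
    terms: dict[BiologicalTerm, list[int]] = {}
    n = len(score_lists)
    for i, scores in enumerate(score_lists):
        for h in scores:
            calls = terms.setdefault(h.term, [0] * n)
            if h.significant:
                calls[i] = _direction_value(h.direction)
    return [PredictionPattern(t, tuple(c)) for t, c in
            sorted(terms.items(), key=lambda kv: format_term(kv[0]))]
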