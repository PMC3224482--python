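"""Synthetic causal networks and expression experiments with planted truth.

The generator emulates the statistical structure reverse causal reasoning
assumes: a bipartite signed graph from regulator-activity terms to transcript
(rna-abundance) terms, a subset of regulators switched on in known
directions, transcripts that follow their regulators' implied signs with
probability ``concordance_prob``, background false-positive changes, and a
two-group log-normal expression matrix in which the planted changes appear
as mean shifts.  Everything is reproducible from (spec, seed): one
:class:`numpy.random.SeedSequence` spawns an independent stream per stage so
stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import BiologicalTerm, CausalEdge, NetworkModel
from .rcr import HypothesisScore, best_directions
from .state_changes import (ComparisonDesign, ExpressionMatrix, StateChange,
                            StateChangeSet)

__all__ = [
    "SyntheticSpec",
    "SyntheticExperiment",
    "generate_network",
    "choose_active",
    "simulate_state_changes",
    "simulate_expression",
    "generate_experiment",
    "recovery_metrics",
    "standin_stress_network",
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic experiment.

    ``mean_out_degree`` parameterizes the 1 + Poisson(mean - 1) out-degree
    distribution (so every regulator has at least one target);
    ``concordance_prob`` (q) is the probability a target of an active
    regulator changes in the implied direction; of the remaining mass, a
    fraction ``flip_prob`` changes in the *opposite* direction and the rest
    does not change; ``background_sc_rate`` (b) is the per-gene rate of
    spurious changes with uniform direction; ``effect_size`` is the log2
    shift planted for SC genes in the expression matrix.
    """

    n_regulators: int = 50
    n_genes: int = 2000
    mean_out_degree: float = 8.0
    positive_sign_prob: float = 0.5
    active: tuple[tuple[int, str], ...] = ()  # (regulator index, "increase"/"decrease")
    concordance_prob: float = 1.0
    flip_prob: float = 0.5
    background_sc_rate: float = 0.0
    samples_per_group: int = 5
    effect_size: float = 2.0
    noise_sd: float = 0.1
    baseline_log2_range: tuple[float, float] = (7.0, 12.0)
    seed: int = 0

    def __post_init__(self):
        for p in (self.positive_sign_prob, self.concordance_prob, self.flip_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.background_sc_rate < 1:
            raise ValueError("background_sc_rate must lie in [0, 1)")
        if self.samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for idx, d in self.active:
            if not 0 <= idx < self.n_regulators:
                raise ValueError(f"active regulator index {idx} out of range")
            if d not in ("increase", "decrease"):
                raise ValueError(f"bad active direction {d!r}")


@dataclass
class SyntheticExperiment:
    network: NetworkModel
    truth: tuple[tuple[BiologicalTerm, str], ...]
    planted_scs: StateChangeSet
    matrix: ExpressionMatrix
    design: ComparisonDesign
    probe_map: dict[str, str]


def _streams(spec: SyntheticSpec) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(spec.seed).spawn(3)
    names = ("network", "state_changes", "expression")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def regulator_term(i: int) -> BiologicalTerm:
    return BiologicalTerm("transcriptional-activity", f"REG{i:04d}")


def gene_symbol(j: int) -> str:
    return f"G{j:05d}"


def generate_network(spec: SyntheticSpec) -> NetworkModel:
    """Bipartite regulator -> transcript causal network, deterministic given
    the spec seed."""
    rng = _streams(spec)["network"]
    genes = [gene_symbol(j) for j in range(spec.n_genes)]
    model = NetworkModel(name=f"synthetic-{spec.seed}")
    degrees = 1 + rng.poisson(max(spec.mean_out_degree - 1.0, 0.0),
                              size=spec.n_regulators)
    degrees = np.minimum(degrees, spec.n_genes)
    if degrees.max(initial=0) > spec.n_genes:
        raise ValueError("out-degree exceeds number of genes")
    for i in range(spec.n_regulators):
        reg = regulator_term(i)
        targets = rng.choice(spec.n_genes, size=int(degrees[i]), replace=False)
        signs = np.where(rng.random(len(targets)) < spec.positive_sign_prob, 1, -1)
        for j, s in zip(targets, signs):
            model.add_edge(CausalEdge(
                reg, BiologicalTerm("rna-abundance", genes[j]), int(s),
                causal=True, species="unspecified", tissue="synthetic"))
    return model


def choose_active(spec: SyntheticSpec, net: NetworkModel, n_active: int,
                  min_targets: int = 4) -> SyntheticSpec:
    """Pick ``n_active`` regulators uniformly among those with at least
    ``min_targets`` targets, with random directions; returns an updated spec.

    Recovery guarantees only hold for regulators eligible as hypotheses, so
    planted actives are drawn from the eligible pool.
    """
    rng = _streams(spec)["network"]
    rng = np.random.default_rng(rng.integers(2**31))  # decouple from topology draws
    out_deg = {i: 0 for i in range(spec.n_regulators)}
    for e in net.causal_edges:
        if e.source.function == "transcriptional-activity":
            idx = int(e.source.entity[3:])
            out_deg[idx] += 1
    eligible = [i for i, d in out_deg.items() if d >= min_targets]
    if len(eligible) < n_active:
        raise ValueError("not enough eligible regulators")
    chosen = rng.choice(eligible, size=n_active, replace=False)
    dirs = rng.choice(["increase", "decrease"], size=n_active)
    return replace(spec, active=tuple((int(i), str(d))
                                      for i, d in zip(chosen, dirs)))


def simulate_state_changes(net: NetworkModel, spec: SyntheticSpec
                           ) -> tuple[StateChangeSet, tuple[tuple[BiologicalTerm, str], ...]]:
    """Plant State Changes implied by the active regulators.

    Each target of an active regulator becomes an SC in the implied direction
    with probability q, in the opposite direction with probability
    (1 - q) * flip_prob, else no SC; every non-target gene becomes an SC with
    probability b, direction uniform.  A gene targeted with conflicting
    implied signs follows a fair coin.  Population = all genes.
    """
    rng = _streams(spec)["state_changes"]
    truth = tuple((regulator_term(i), d) for i, d in spec.active)
    active_terms = {t: (+1 if d == "increase" else -1) for t, d in truth}
    implied: dict[str, set[int]] = {}
    for e in net.causal_edges:
        if e.source in active_terms and e.target.function == "rna-abundance":
            implied.setdefault(e.target.entity, set()).add(
                e.sign * active_terms[e.source])
    genes = [gene_symbol(j) for j in range(spec.n_genes)]
    directions: dict[str, int] = {}
    for g in genes:
        if g in implied:
            signs = implied[g]
            s = next(iter(signs)) if len(signs) == 1 \
                else (1 if rng.random() < 0.5 else -1)
            u = rng.random()
            if u < spec.concordance_prob:
                directions[g] = s
            elif u < spec.concordance_prob + (1 - spec.concordance_prob) * spec.flip_prob:
                directions[g] = -s
        else:
            if rng.random() < spec.background_sc_rate:
                directions[g] = 1 if rng.random() < 0.5 else -1
    changes = [StateChange(g, "increased" if s > 0 else "decreased",
                           fold_change=float(2 ** spec.effect_size),
                           adjusted_p=0.0)
               for g, s in sorted(directions.items())]
    scs = StateChangeSet(label=f"synthetic-{spec.seed}",
                         population=frozenset(genes), changes=changes)
    return scs, truth


def simulate_expression(scs: StateChangeSet, spec: SyntheticSpec
                        ) -> tuple[ExpressionMatrix, ComparisonDesign, dict[str, str]]:
    """Two-group log-normal expression matrix realizing the planted SCs.

    Control samples are baseline + N(0, noise_sd) in log2 space; treatment
    samples add +/- effect_size for planted SC genes.  Probe ids equal gene
    symbols (identity probe map).  Exported on linear scale.
    """
    rng = _streams(spec)["expression"]
    genes = sorted(scs.population)
    n = spec.samples_per_group
    lo, hi = spec.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=len(genes))
    shift = np.zeros(len(genes))
    dirs = scs.directions
    for idx, g in enumerate(genes):
        if g in dirs:
            shift[idx] = dirs[g] * spec.effect_size
    noise = rng.normal(0.0, spec.noise_sd, size=(len(genes), 2 * n))
    log2vals = baseline[:, None] + noise
    log2vals[:, :n] += shift[:, None]
    t_ids = [f"treat_{i+1}" for i in range(n)]
    c_ids = [f"ctrl_{i+1}" for i in range(n)]
    matrix = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2vals), index=genes, columns=t_ids + c_ids),
        log2=False)
    design = ComparisonDesign(scs.label, tuple(t_ids), tuple(c_ids))
    probe_map = {g: g for g in genes}
    return matrix, design, probe_map


def generate_experiment(spec: SyntheticSpec) -> SyntheticExperiment:
    """Network + planted SCs + expression matrix in one call."""
    net = generate_network(spec)
    scs, truth = simulate_state_changes(net, spec)
    matrix, design, probe_map = simulate_expression(scs, spec)
    return SyntheticExperiment(net, truth, scs, matrix, design, probe_map)


def recovery_metrics(scores: list[HypothesisScore],
                     truth: tuple[tuple[BiologicalTerm, str], ...]) -> dict:
    """Precision/recall of significant hypotheses against the planted truth.

    Scores are collapsed to best direction per term first.  With no
    significant hypotheses precision is reported as 1.0 (no false claims)
    with ``no_calls=True``; direction accuracy is computed over true
    positives only (nan if there are none).
    """
    sig = {h.term: h.direction for h in best_directions(scores) if h.significant}
    truth_dirs = dict(truth)
    tp = set(sig) & set(truth_dirs)
    no_calls = len(sig) == 0
    precision = 1.0 if no_calls else len(tp) / len(sig)
    recall = len(tp) / len(truth_dirs) if truth_dirs else 1.0
    direction_accuracy = (sum(sig[t] == truth_dirs[t] for t in tp) / len(tp)
                          if tp else float("nan"))
    return {"precision": precision, "recall": recall,
            "direction_accuracy": direction_accuracy, "no_calls": no_calls,
            "n_significant": len(sig), "n_truth": len(truth_dirs)}


# ---------------------------------------------------------------------------
# stand-in reference network

_STANDIN_NODE_COUNTS = {
    "rna-abundance": 84,
    "protein-abundance": 235,
    "phosphoprotein": 43,
    "transcriptional-activity": 100,
    "kinase-activity": 50,
    "gtp-bound-activity": 30,
    "complex": 57,
    "protein-family": 18,
    "biological-process": 48,
    "chemical": 65,
}
_STANDIN_SPECIES = (("human", 545), ("mouse", 175), ("rat", 58))
_STANDIN_TISSUES = (("lung", 0.40), ("cardiovascular", 0.27), ("liver", 0.13),
                    ("kidney", 0.10), ("cell line", 0.10))


def standin_stress_network(seed: int = 0) -> NetworkModel:
    """SYNTHETIC stand-in for a published cellular-stress causal network.

    Deterministically constructs a network carrying the published summary
    statistics of that model — 730 nodes across the standard node
    categories, 1280 edges of which 778 are causal (545 human, 175 mouse, 58
    rat), 428 unique PMIDs — with random wiring.  It is *not* the published
    network: entities and topology are invented, only the summary-level
    counts are matched, so it exercises serialization and counting
    machinery, not biology.
    """
    rng = np.random.default_rng(seed)
    nodes: list[BiologicalTerm] = []
    for fn, count in _STANDIN_NODE_COUNTS.items():
        nodes.extend(BiologicalTerm(fn, f"E{len(nodes) + i:04d}")
                     for i in range(count))
    n_causal = sum(c for _, c in _STANDIN_SPECIES)
    n_noncausal = 1280 - n_causal
    species_seq = [sp for sp, c in _STANDIN_SPECIES for _ in range(c)]
    t_labels, t_probs = zip(*_STANDIN_TISSUES)
    tissues = rng.choice(t_labels, size=n_causal, p=t_probs)
    pmid_pool = [str(10000000 + i) for i in range(428)]

    model = NetworkModel(name=f"standin-stress-{seed}")
    seen: set[tuple] = set()

    def draw_pair(force_src: int | None = None) -> tuple[BiologicalTerm, BiologicalTerm, int]:
        while True:
            i = force_src if force_src is not None else int(rng.integers(len(nodes)))
            j = int(rng.integers(len(nodes)))
            if i == j:
                continue
            sign = 1 if rng.random() < 0.7 else -1
            key = (nodes[i], nodes[j], sign, True)
            if key not in seen:
                seen.add(key)
                return nodes[i], nodes[j], sign

    causal_edges = []
    # first sweep touches every node so the edge list preserves all 730
    for idx in range(len(nodes)):
        causal_edges.append(draw_pair(force_src=idx))
    while len(causal_edges) < n_causal:
        causal_edges.append(draw_pair())
    blocks = ("xenobiotic", "ER", "shear", "hypoxic", "osmotic", "oxidative")
    for e_idx, (src, tgt, sign) in enumerate(causal_edges):
        model.add_edge(CausalEdge(
            src, tgt, sign, causal=True, species=species_seq[e_idx],
            tissue=str(tissues[e_idx]),
            pmids=(pmid_pool[e_idx % len(pmid_pool)],),
            blocks=frozenset({blocks[e_idx % len(blocks)]})))
    n_added = 0
    while n_added < n_noncausal:
        i, j = rng.integers(len(nodes)), rng.integers(len(nodes))
        if i == j:
            continue
        key = (nodes[i], nodes[j], 1, False)
        if key in seen or (nodes[i], nodes[j], 1, True) in seen:
            continue
        seen.add(key)
        model.add_edge(CausalEdge(nodes[int(i)], nodes[int(j)], 1, causal=False,
                                  species="unspecified", tissue=""))
        n_added += 1
    return model
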