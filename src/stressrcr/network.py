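"""Signed causal biological networks.

A network is a set of *biological terms* (functionalized entities such as
``taof(Nfe2l2)``, the transcriptional activity of Nfe2l2) connected by signed
causal assertions mined from the literature.  Each causal edge states that an
increase in the source term increases (``+1``) or decreases (``-1``) the
target term, and carries its provenance: species, tissue context and PubMed
identifiers.  Non-causal edges merely connect alternative forms of the same
entity (e.g. an mRNA and its protein) and are excluded from inference.

The canonical on-disk form is a tab-separated edge list with the header
``source  relation  target  causal_flag  species  tissue  pmids  blocks``.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx

__all__ = [
    "BiologicalTerm",
    "CausalEdge",
    "NetworkModel",
    "NetworkParseError",
    "parse_term",
    "format_term",
    "parse_network_tsv",
    "write_network_tsv",
    "network_statistics",
    "tissue_context_summary",
    "merge_models",
    "export_graph",
]

#: term-grammar tag -> node function
TAG_TO_FUNCTION = {
    "r": "rna-abundance",
    "p": "protein-abundance",
    "pp": "phosphoprotein",
    "taof": "transcriptional-activity",
    "kaof": "kinase-activity",
    "gtpof": "gtp-bound-activity",
    "complex": "complex",
    "fam": "protein-family",
    "bp": "biological-process",
    "chem": "chemical",
}
FUNCTION_TO_TAG = {v: k for k, v in TAG_TO_FUNCTION.items()}

VALID_SPECIES = ("human", "mouse", "rat", "unspecified")
BLOCK_LABELS = ("xenobiotic", "ER", "shear", "hypoxic", "osmotic", "oxidative")


class NetworkParseError(ValueError):
    """Raised for malformed term strings or network files."""


@dataclass(frozen=True)
class BiologicalTerm:
    """A functionalized biological entity, the node currency of the network.

    Two terms are equal iff their function tag (case-insensitive) and entity
    name (case-sensitive) are equal.
    """

    function: str
    entity: str
    species_qualifier: str | None = None

    def __post_init__(self):
        fn = self.function.lower()
        if fn not in FUNCTION_TO_TAG:
            raise NetworkParseError(f"unknown node function: {self.function!r}")
        object.__setattr__(self, "function", fn)
        if not self.entity:
            raise NetworkParseError("term entity must be non-empty")

    def __eq__(self, other):
        if not isinstance(other, BiologicalTerm):
            return NotImplemented
        return self.function == other.function and self.entity == other.entity

    def __hash__(self):
        return hash((self.function, self.entity))

    def __str__(self) -> str:
        return format_term(self)


def parse_term(text: str) -> BiologicalTerm:
    """Parse ``tag(entity)`` notation, e.g. ``taof(Nfe2l2)``.

    Raises :class:`NetworkParseError` on an unknown tag, unbalanced
    parentheses or an empty entity, naming the offending text.
    """
    text = text.strip()
    open_idx = text.find("(")
    if open_idx <= 0 or not text.endswith(")"):
        raise NetworkParseError(f"malformed term: {text!r}")
    tag = text[:open_idx].strip().lower()
    entity = text[open_idx + 1 : -1].strip()
    if tag not in TAG_TO_FUNCTION:
        raise NetworkParseError(f"unknown term tag {tag!r} in {text!r}")
    if not entity:
        raise NetworkParseError(f"empty entity in term {text!r}")
    if entity.count("(") != entity.count(")"):
        raise NetworkParseError(f"unbalanced parentheses in term {text!r}")
    return BiologicalTerm(TAG_TO_FUNCTION[tag], entity)


def format_term(term: BiologicalTerm) -> str:
    return f"{FUNCTION_TO_TAG[term.function]}({term.entity})"


@dataclass
class CausalEdge:
    """A signed, evidence-annotated cause-effect assertion.

    ``sign`` is +1 (source increases target) or -1; non-causal edges carry
    sign +1 by convention and never enter inference.  Identity for merging is
    ``(source, target, sign, causal_flag)``; duplicate assertions pool their
    PMID evidence.
    """

    source: BiologicalTerm
    target: BiologicalTerm
    sign: int
    causal: bool = True
    species: str = "unspecified"
    tissue: str = ""
    pmids: tuple[str, ...] = ()
    blocks: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")
        if not self.causal and self.sign != +1:
            raise ValueError("non-causal edges must carry sign +1")
        if self.species not in VALID_SPECIES:
            raise ValueError(f"unknown species: {self.species!r}")
        self.pmids = tuple(str(p) for p in self.pmids)
        self.blocks = frozenset(self.blocks)

    @property
    def key(self) -> tuple:
        return (self.source, self.target, self.sign, self.causal)


class NetworkModel:
    """A named collection of terms and causal edges.

    Node-level building-block membership is derived as the union of block
    labels over a node's incident edges; a node may belong to several blocks.
    """

    def __init__(self, name: str = "network", edges: Iterable[CausalEdge] = (),
                 extra_nodes: Iterable[BiologicalTerm] = ()):
        self.name = name
        self._edges: dict[tuple, CausalEdge] = {}
        self._nodes: set[BiologicalTerm] = set(extra_nodes)
        for e in edges:
            self.add_edge(e)

    def add_edge(self, edge: CausalEdge) -> None:
        prev = self._edges.get(edge.key)
        if prev is None:
            self._edges[edge.key] = edge
        else:
            merged_pmids = tuple(dict.fromkeys(prev.pmids + edge.pmids))
            self._edges[edge.key] = CausalEdge(
                prev.source, prev.target, prev.sign, prev.causal,
                prev.species, prev.tissue, merged_pmids,
                prev.blocks | edge.blocks)
        self._nodes.add(edge.source)
        self._nodes.add(edge.target)

    @property
    def nodes(self) -> set[BiologicalTerm]:
        return set(self._nodes)

    @property
    def edges(self) -> list[CausalEdge]:
        return list(self._edges.values())

    @property
    def causal_edges(self) -> list[CausalEdge]:
        return [e for e in self._edges.values() if e.causal]

    @property
    def building_blocks(self) -> dict[BiologicalTerm, set[str]]:
        blocks: dict[BiologicalTerm, set[str]] = {n: set() for n in self._nodes}
        for e in self._edges.values():
            blocks[e.source] |= e.blocks
            blocks[e.target] |= e.blocks
        return blocks

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other):
        if not isinstance(other, NetworkModel):
            return NotImplemented
        if self._nodes != other._nodes or set(self._edges) != set(other._edges):
            return False
        for k, e in self._edges.items():
            o = other._edges[k]
            if (set(e.pmids) != set(o.pmids) or e.blocks != o.blocks
                    or e.species != o.species or e.tissue != o.tissue):
                return False
        return True


_HEADER = ["source", "relation", "target", "causal_flag", "species",
           "tissue", "pmids", "blocks"]
_RELATION_TO_SIGN = {"increases": +1, "decreases": -1}


def parse_network_tsv(stream: TextIO | str, name: str = "network") -> NetworkModel:
    """Parse the canonical tab-separated edge list into a model.

    Errors (unknown relation word, malformed term, wrong column count) are
    reported with the 1-based line number of the offending row.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    header = stream.readline().rstrip("\n").split("\t")
    if [h.strip().lower() for h in header] != _HEADER:
        raise NetworkParseError(
            f"expected header {_HEADER}, got {header}")
    model = NetworkModel(name=name)
    for lineno, raw in enumerate(stream, start=2):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_HEADER):
            raise NetworkParseError(
                f"line {lineno}: expected {len(_HEADER)} columns, got {len(fields)}")
        src_s, rel, tgt_s, cflag, species, tissue, pmids_s, blocks_s = fields
        if rel not in _RELATION_TO_SIGN:
            raise NetworkParseError(f"line {lineno}: unknown relation {rel!r}")
        try:
            src = parse_term(src_s)
            tgt = parse_term(tgt_s)
        except NetworkParseError as exc:
            raise NetworkParseError(f"line {lineno}: {exc}") from exc
        causal = cflag.strip().lower() == "causal"
        if cflag.strip().lower() not in ("causal", "non-causal"):
            raise NetworkParseError(
                f"line {lineno}: causal_flag must be causal/non-causal, got {cflag!r}")
        pmids = tuple(p for p in pmids_s.split(";") if p)
        blocks = frozenset(b for b in blocks_s.split(";") if b)
        model.add_edge(CausalEdge(src, tgt, _RELATION_TO_SIGN[rel], causal,
                                  species.strip() or "unspecified",
                                  tissue.strip(), pmids, blocks))
    return model


def _edge_row(e: CausalEdge) -> list[str]:
    rel = "increases" if e.sign == +1 else "decreases"
    return [format_term(e.source), rel, format_term(e.target),
            "causal" if e.causal else "non-causal", e.species, e.tissue,
            ";".join(e.pmids), ";".join(sorted(e.blocks))]


def write_network_tsv(model: NetworkModel, stream: TextIO) -> None:
    stream.write("\t".join(_HEADER) + "\n")
    for e in sorted(model.edges, key=lambda e: _edge_row(e)):
        stream.write("\t".join(_edge_row(e)) + "\n")


def network_statistics(model: NetworkModel) -> dict:
    """Distinct node/edge counts of the kind reported in network summaries.

    Returns total nodes, nodes per function tag, total and causal edge
    counts, causal edges per species, and the number of unique PMIDs cited
    by causal edges.  An empty model yields all zeros.
    """
    fn_counts = Counter(n.function for n in model.nodes)
    causal = model.causal_edges
    species_counts = Counter(e.species for e in causal)
    pmids = {p for e in causal for p in e.pmids}
    return {
        "nodes": len(model.nodes),
        "nodes_by_function": {fn: fn_counts.get(fn, 0)
                              for fn in FUNCTION_TO_TAG},
        "edges": len(model.edges),
        "causal_edges": len(causal),
        "causal_edges_by_species": dict(species_counts),
        "unique_pmids": len(pmids),
    }


def tissue_context_summary(model: NetworkModel,
                           category_map: Mapping[str, str]) -> dict[str, float]:
    """Fraction of causal edges per tissue category.

    Tissue labels absent from ``category_map`` fall into ``"other"``.
    Fractions sum to 1 over a non-empty causal edge set; categories are
    returned in sorted order for determinism.
    """
    causal = model.causal_edges
    if not causal:
        return {}
    counts: Counter[str] = Counter(
        category_map.get(e.tissue, "other") for e in causal)
    total = len(causal)
    return {cat: counts[cat] / total for cat in sorted(counts)}


def merge_models(a: NetworkModel, b: NetworkModel,
                 name: str | None = None) -> NetworkModel:
    """Union of two models: nodes unioned, edges merged under the identity
    rule with pooled evidence and block labels."""
    merged = NetworkModel(name=name or a.name,
                          extra_nodes=a.nodes | b.nodes)
    for e in a.edges:
        merged.add_edge(e)
    for e in b.edges:
        merged.add_edge(e)
    return merged


def export_graph(model: NetworkModel, stream: TextIO, dialect: str = "edge-TSV") -> None:
    """Write the model as ``edge-TSV`` (lossless round trip), ``SIF``
    (``source increases|decreases target``) or ``GraphML``."""
    if dialect == "edge-TSV":
        write_network_tsv(model, stream)
    elif dialect == "SIF":
        for e in sorted(model.edges, key=_edge_row):
            rel = "increases" if e.sign == +1 else "decreases"
            stream.write(f"{format_term(e.source)}\t{rel}\t{format_term(e.target)}\n")
    elif dialect == "GraphML":
        g = nx.MultiDiGraph()
        for n in model.nodes:
            g.add_node(format_term(n), function=n.function, entity=n.entity)
        for e in model.edges:
            g.add_edge(format_term(e.source), format_term(e.target),
                       sign=e.sign, causal=e.causal, species=e.species,
                       tissue=e.tissue, pmids=";".join(e.pmids))
        for line in nx.generate_graphml(g):
            stream.write(line + "\n")
    else:
        raise ValueError(f"unknown export dialect: {dialect!r}")
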