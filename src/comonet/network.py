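"""Interactome construction, 1-step seed expansion and network overlap.

Raw interaction records are reduced to a non-redundant physical
interactome for one organism: each unordered pair of interactors counts
once regardless of direction, genetic interactions and self-pairs are
dropped, and non-matching organisms filtered out.  Disease networks are
built by taking every interactome edge incident to a seed gene (the
seeds' direct 1-step interactions, not the induced subgraph on the
neighbourhood), and two disease networks are compared by intersecting
their node and edge sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import InteractionRecord

HUMAN_TAXON = 9606

Edge = tuple[str, str]  # lexicographically ordered unordered pair


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class Interactome:
    """Deduplicated unordered physical interaction pairs for one taxon."""

    edges: set[Edge]
    taxon: int = HUMAN_TAXON
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def neighbors(self, node: str) -> set[str]:
        return {b if a == node else a for a, b in self.edges if node in (a, b)}

    def to_records(self) -> list[InteractionRecord]:
        return [
            InteractionRecord(a, b, self.taxon, self.taxon, "physical")
            for a, b in sorted(self.edges)
        ]


@dataclass
class DiseaseNetwork:
    """1-step expansion of a seed gene list on the interactome.

    Every edge touches at least one seed; nodes are the endpoints of
    those edges.  Seeds absent from the interactome are kept aside in
    ``unmapped_seeds``.
    """

    label: str
    seeds: set[str]
    nodes: set[str]
    edges: set[Edge]
    unmapped_seeds: set[str]

    def degree(self, node: str) -> int:
        return sum(node in e for e in self.edges)


def build_interactome(records: list[InteractionRecord], taxon: int = HUMAN_TAXON) -> Interactome:
    """Filter records to non-redundant physical same-taxon interactions.

    Returns the interactome with a count breakdown: ``kept``,
    ``dropped_genetic``, ``dropped_organism``, ``dropped_duplicate``
    and ``dropped_self``.
    """
    counts = {
        "kept": 0,
        "dropped_genetic": 0,
        "dropped_organism": 0,
        "dropped_duplicate": 0,
        "dropped_self": 0,
    }
    edges: set[Edge] = set()
    for r in records:
        if r.system_type != "physical":
            counts["dropped_genetic"] += 1
            continue
        if r.organism_a != taxon or r.organism_b != taxon:
            counts["dropped_organism"] += 1
            continue
        if r.symbol_a == r.symbol_b:
            counts["dropped_self"] += 1
            continue
        edge = _edge(r.symbol_a, r.symbol_b)
        if edge in edges:
            counts["dropped_duplicate"] += 1
            continue
        edges.add(edge)
        counts["kept"] += 1
    return Interactome(edges, taxon, counts)


def expand_seed_network(inter: Interactome, seeds: list[str], label: str = "") -> DiseaseNetwork:
    """Collect the seeds' direct interactions into a disease network."""
    if not seeds:
        raise ValueError("seed list is empty")
    seed_set = {s.upper() for s in seeds}
    edges = {e for e in inter.edges if e[0] in seed_set or e[1] in seed_set}
    nodes = {n for e in edges for n in e}
    unmapped = seed_set - inter.nodes
    return DiseaseNetwork(label=label, seeds=seed_set, nodes=nodes, edges=edges, unmapped_seeds=unmapped)


def overlap_network(net_a: DiseaseNetwork, net_b: DiseaseNetwork) -> tuple[set[str], set[Edge]]:
    """Shared nodes and shared edges of two disease networks."""
    return net_a.nodes & net_b.nodes, net_a.edges & net_b.edges
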