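"""Tandem-cluster detection, conserved adjacencies and ancestral gene orders.

A gene *adjacency* is an unordered pair of symbols immediately next to each
other on a scaffold (strand and orientation are ignored).  Each adjacency
is treated as a binary character on the species tree and reconstructed by
Dollo parsimony (one gain, any number of losses): it is inferred present
at an ancestral node exactly when that node lies on the spanning subtree
connecting the carrier species.  Ancestral adjacency sets are then greedily
assembled into linear orders; symbols touching more than two inferred
neighbours are reported as conflicts rather than forced into a path.

The family cluster (all family-flagged genes in a run) may be collapsed to
a single token so that flanking adjacencies are comparable across species
whose clusters differ in content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .trees import Node, Tree

CLUSTER_TOKEN = "FAMILY_CLUSTER"


@dataclass
class GeneOrder:
    """Coordinate-sorted gene symbols on one scaffold of one species."""

    species: str
    scaffold: str
    genes: list[tuple[str, str, bool]]  # (symbol, strand, is_family_member)

    def __post_init__(self) -> None:
        symbols = [g[0] for g in self.genes]
        if len(symbols) != len(set(symbols)):
            raise ValueError(f"duplicate symbols on scaffold {self.scaffold!r}")

    @property
    def symbols(self) -> list[str]:
        return [g[0] for g in self.genes]

    def collapsed_symbols(self, token: str = CLUSTER_TOKEN) -> list[str]:
        """Symbol sequence with each maximal family run replaced by ``token``."""
        out: list[str] = []
        for symbol, _strand, is_family in self.genes:
            if is_family:
                if not out or out[-1] != token:
                    out.append(token)
            else:
                out.append(symbol)
        return out


def read_gene_orders(tsv: str) -> dict[str, list[GeneOrder]]:
    """BED-like TSV: scaffold, start, end, strand, symbol, family(0/1), species."""
    rows: dict[tuple[str, str], list[tuple[int, str, str, bool]]] = {}
    for line in tsv.strip().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        scaffold, start, _end, strand, symbol, fam, species = line.split("\t")
        rows.setdefault((species, scaffold), []).append(
            (int(start), symbol, strand, fam == "1"))
    orders: dict[str, list[GeneOrder]] = {}
    for (species, scaffold), genes in sorted(rows.items()):
        genes.sort()
        orders.setdefault(species, []).append(GeneOrder(
            species=species, scaffold=scaffold,
            genes=[(sym, strand, fam) for _pos, sym, strand, fam in genes]))
    return orders


def write_gene_orders(orders: Mapping[str, list[GeneOrder]]) -> str:
    lines = []
    for species in sorted(orders):
        for order in orders[species]:
            for i, (symbol, strand, fam) in enumerate(order.genes):
                start, end = i * 10_000, i * 10_000 + 5_000
                lines.append("\t".join([order.scaffold, str(start), str(end),
                                        strand, symbol, "1" if fam else "0",
                                        species]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Clusters and adjacencies
# ---------------------------------------------------------------------------

def detect_clusters(order: GeneOrder, max_intervening: int = 0) -> list[list[str]]:
    """Maximal runs of family members separated by <= ``max_intervening``
    non-family genes.  Singleton family genes form singleton clusters."""
    clusters: list[list[str]] = []
    current: list[str] = []
    gap = 0
    for symbol, _strand, is_family in order.genes:
        if is_family:
            current.append(symbol)
            gap = 0
        elif current:
            gap += 1
            if gap > max_intervening:
                clusters.append(current)
                current = []
                gap = 0
    if current:
        clusters.append(current)
    return clusters


def scaffold_adjacencies(order: GeneOrder, collapse_family: bool = False,
                         token: str = CLUSTER_TOKEN) -> set[frozenset[str]]:
    symbols = order.collapsed_symbols(token) if collapse_family else order.symbols
    return {frozenset((a, b)) for a, b in zip(symbols, symbols[1:])}


def species_adjacencies(orders: Mapping[str, Sequence[GeneOrder]],
                        collapse_family: bool = False,
                        token: str = CLUSTER_TOKEN) -> dict[str, set[frozenset[str]]]:
    return {
        species: set().union(*(scaffold_adjacencies(o, collapse_family, token)
                               for o in species_orders)) if species_orders else set()
        for species, species_orders in orders.items()
    }


def adjacency_presence(orders: Mapping[str, Sequence[GeneOrder]],
                       pair: tuple[str, str],
                       collapse_family: bool = False,
                       token: str = CLUSTER_TOKEN) -> dict[str, bool]:
    """Which species have the two symbols immediately adjacent.

    With ``collapse_family`` the family cluster counts as a single unit:
    two flanking genes separated only by family members (the run collapses
    to one token) are adjacent across the cluster.
    """
    key = frozenset(pair)
    if len(key) != 2:
        raise ValueError("pair must contain two distinct symbols")
    result: dict[str, bool] = {}
    for species, species_orders in orders.items():
        found = False
        for order in species_orders:
            symbols = (order.collapsed_symbols(token) if collapse_family
                       else order.symbols)
            adjacent = {frozenset(p) for p in zip(symbols, symbols[1:])}
            if collapse_family:
                bridged = {frozenset((a, c))
                           for a, b, c in zip(symbols, symbols[1:], symbols[2:])
                           if b == token and a != c}
                adjacent |= bridged
            if key in adjacent:
                found = True
                break
        result[species] = found
    return result


# ---------------------------------------------------------------------------
# Ancestral adjacencies (Dollo, one gain per adjacency)
# ---------------------------------------------------------------------------

def ancestral_adjacencies(species_tree: Tree,
                          per_species: Mapping[str, Iterable[frozenset[str]]]
                          ) -> dict[str, set[frozenset[str]]]:
    """Dollo reconstruction of every adjacency as a binary character.

    An adjacency is present at a node iff the node lies on the spanning
    subtree connecting its carrier species (gain at the carrier MRCA,
    minimal losses below).  Adding a carrier can only enlarge spanning
    subtrees, so inference is monotone in the carrier sets.
    """
    carriers: dict[frozenset[str], list[str]] = {}
    leaf_ids = set(species_tree.leaf_ids())
    for species, adjacencies in per_species.items():
        if species not in leaf_ids:
            continue
        for adjacency in adjacencies:
            carriers.setdefault(adjacency, []).append(species)

    result: dict[str, set[frozenset[str]]] = {n.id: set()
                                              for n in species_tree.preorder()}
    for adjacency, species_list in carriers.items():
        origin = species_tree.mrca(species_list)
        present: set[str] = {origin.id}
        for sp in species_list:
            node: Optional[Node] = species_tree.node(sp)
            while node is not None and node.id not in present:
                present.add(node.id)
                node = node.parent
        for node_id in present:
            result[node_id].add(adjacency)
    return result


# ---------------------------------------------------------------------------
# Order assembly
# ---------------------------------------------------------------------------

@dataclass
class AssembledOrder:
    """Linear paths implied by an adjacency set, with degree conflicts."""

    paths: list[list[str]] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)   # symbols with degree > 2


def assemble_order(adjacencies: Iterable[frozenset[str]]) -> AssembledOrder:
    """Assemble maximal simple paths from unordered adjacencies.

    Symbols with more than two neighbours are conflicts; each of their
    incident adjacencies terminates a path there.  Output is deterministic:
    paths start from lexicographically smallest endpoints, each path is
    oriented to its lexicographically smaller reading, and the path list is
    sorted.  Cycles are cut at their smallest symbol.
    """
    neighbours: dict[str, set[str]] = {}
    for adjacency in adjacencies:
        pair = sorted(adjacency)
        if len(pair) != 2:
            raise ValueError(f"self-adjacency or malformed pair: {set(adjacency)}")
        a, b = pair
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)

    conflicts = sorted(s for s, nb in neighbours.items() if len(nb) > 2)
    conflict_set = set(conflicts)
    visited_edges: set[frozenset[str]] = set()
    paths: list[list[str]] = []

    def walk(start: str, first: str) -> list[str]:
        path = [start, first]
        visited_edges.add(frozenset((start, first)))
        while True:
            tail = path[-1]
            if tail in conflict_set:
                break
            options = [n for n in sorted(neighbours[tail])
                       if frozenset((tail, n)) not in visited_edges]
            if not options:
                break
            nxt = options[0]
            visited_edges.add(frozenset((tail, nxt)))
            path.append(nxt)
        return path

    # endpoints: degree-1 symbols and conflict symbols
    endpoints = sorted(s for s, nb in neighbours.items()
                       if len(nb) != 2 or s in conflict_set)
    for start in endpoints:
        for first in sorted(neighbours[start]):
            if frozenset((start, first)) in visited_edges:
                continue
            paths.append(walk(start, first))
    # remaining edges belong to cycles: cut at smallest symbol
    remaining = sorted(s for s in neighbours
                       if any(frozenset((s, n)) not in visited_edges
                              for n in neighbours[s]))
    for start in remaining:
        for first in sorted(neighbours[start]):
            if frozenset((start, first)) in visited_edges:
                continue
            paths.append(walk(start, first))

    oriented = [min(p, p[::-1]) for p in paths]
    return AssembledOrder(paths=sorted(oriented), conflicts=conflicts)
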