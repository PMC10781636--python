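"""Placing gene-family origins, duplications and losses on a species tree.

Two reconstructions are provided:

``dollo_reconstruct``
    Matrix-only Dollo parsimony: each clade is gained exactly once, at the
    most recent common ancestor of its carrier species (pseudogenes count
    as carriers), and losses are placed on the minimal set of branches
    below the origin so that exactly the carriers retain the clade.

``reconcile``
    LCA reconciliation of a clade tree (gene-family tree whose leaves are
    ortholog clade labels) against the species tree.  Each clade-tree node
    maps to the species-tree LCA of its descendant carriers; a node whose
    children overlap that mapping is a duplication placed on the branch
    leading to the mapped species node.  Clade origins are thereby pushed
    rootward relative to matrix-only Dollo, and losses are then placed as
    in Dollo parsimony below each origin.

Branches are identified by the id of their child node; an event on branch
``b`` happened between ``parent(b)`` and ``b``.  Copy number above one
within a species is ignored: reconstruction is clade-level presence only,
and species-specific duplications are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .trees import (ABSENT, INTACT, PSEUDOGENE, GeneModel, Node,
                    PresenceMatrix, Tree, TreeError)
from .orthology import DUPLICATION, SPECIATION

ORIGIN = "origin"
LOSS = "loss"
PSEUDOGENIZATION = "pseudogenization"


@dataclass(frozen=True)
class Event:
    branch: str            # child-node id of the species-tree branch
    kind: str              # origin | duplication | loss | pseudogenization
    clade: str
    parent_clade: Optional[str] = None


class EventMap:
    """Per-branch event lists plus the speciation handoffs needed to replay.

    ``divergences`` record where an ancestral lineage's identity splits at
    a speciation into differently named descendant clades (e.g. the
    cartilaginous-fish TAS1R6 versus the bony-vertebrate ancestor of
    TAS1R1/TAS1R2A/TAS1R2B/TAS1R5); they are bookkeeping, not events.
    """

    def __init__(self) -> None:
        self.events: dict[str, list[Event]] = {}
        self.divergences: dict[str, list[tuple[str, str]]] = {}
        #: reconciliation detail: clade-tree node id -> (species node id,
        #: "duplication" | "speciation" | "leaf"); filled by ``reconcile``
        self.node_mapping: dict[str, tuple[str, str]] = {}

    def add(self, event: Event) -> None:
        self.events.setdefault(event.branch, []).append(event)

    def add_divergence(self, branch: str, parent_label: str, child_label: str) -> None:
        self.divergences.setdefault(branch, []).append((parent_label, child_label))

    def on_branch(self, branch: str) -> list[Event]:
        return list(self.events.get(branch, []))

    def all_events(self) -> Iterable[Event]:
        for events in self.events.values():
            yield from events

    def losses_on_branch(self, species_tree: Tree, branch: str) -> list[str]:
        """Sorted clade labels lost on the branch above node ``branch``."""
        species_tree.node(branch)  # raises on unknown branch
        return sorted(e.clade for e in self.events.get(branch, [])
                      if e.kind == LOSS)

    def origin_branch(self, clade: str) -> Optional[str]:
        for event in self.all_events():
            if event.clade == clade and event.kind in (ORIGIN, DUPLICATION):
                return event.branch
        return None

    def first_appearance(self, clade: str) -> Optional[str]:
        """Branch where the clade's identity first appears: its creating
        origin/duplication, or the speciation handoff that named it."""
        branch = self.origin_branch(clade)
        if branch is not None:
            return branch
        for divergence_branch, pairs in self.divergences.items():
            if any(child == clade for _parent, child in pairs):
                return divergence_branch
        return None

    # -- replay ------------------------------------------------------------

    def replay(self, species_tree: Tree) -> dict[str, dict[str, str]]:
        """Walk root-to-tips applying events; return node -> {clade: state}.

        States are ``intact``/``pseudogene``; absent clades are simply
        missing from the per-node dict.
        """
        result: dict[str, dict[str, str]] = {}

        def apply(node: Node, inherited: dict[str, str]) -> None:
            state = dict(inherited)
            branch = node.id
            for parent_label, child_label in self.divergences.get(branch, []):
                if parent_label in state:
                    flag = state.pop(parent_label)
                    state[child_label] = flag
            removed_parents: set[str] = set()
            for event in self.events.get(branch, []):
                if event.kind == ORIGIN:
                    state[event.clade] = INTACT
                elif event.kind == DUPLICATION:
                    state[event.clade] = INTACT
                    if event.parent_clade is not None:
                        removed_parents.add(event.parent_clade)
                elif event.kind == LOSS:
                    state.pop(event.clade, None)
                elif event.kind == PSEUDOGENIZATION:
                    if event.clade in state:
                        state[event.clade] = PSEUDOGENE
            for label in removed_parents:
                state.pop(label, None)
            result[node.id] = state
            for child in node.children:
                apply(child, state)

        apply(species_tree.root, {})
        return result


class AncestralRepertoire:
    """Species-tree node -> set of clade labels present at that node."""

    def __init__(self, present: dict[str, dict[str, str]]):
        self._present = present

    def at(self, node_id: str) -> dict[str, str]:
        if node_id not in self._present:
            raise TreeError(f"unknown node: {node_id!r}")
        return dict(self._present[node_id])

    def labels_at(self, node_id: str) -> frozenset[str]:
        return frozenset(self.at(node_id))

    def size(self, node_id: str, count_pseudogenes: bool = False) -> int:
        states = self.at(node_id)
        if count_pseudogenes:
            return len(states)
        return sum(1 for s in states.values() if s == INTACT)


def ancestral_repertoire_size(repertoire: AncestralRepertoire, node_id: str,
                              count_pseudogenes: bool = False) -> int:
    return repertoire.size(node_id, count_pseudogenes=count_pseudogenes)


def losses_on_branch(event_map: EventMap, species_tree: Tree, branch: str) -> list[str]:
    return event_map.losses_on_branch(species_tree, branch)


# ---------------------------------------------------------------------------
# Matrix-only Dollo parsimony
# ---------------------------------------------------------------------------

def _spanning_presence(tree: Tree, origin: Node, carriers: list[str]) -> set[str]:
    """Node ids on a path from ``origin`` to at least one carrier tip."""
    present: set[str] = {origin.id}
    for sp in carriers:
        node: Optional[Node] = tree.node(sp)
        while node is not None and node.id not in present:
            present.add(node.id)
            node = node.parent
        # carriers are guaranteed to descend from origin, so the walk
        # always meets the present set
    return present


def _dollo_single_clade(tree: Tree, clade: str, carriers: list[str],
                        pseudo_tips: set[str], event_map: EventMap,
                        origin: Optional[Node] = None) -> set[str]:
    if not carriers:
        raise TreeError(f"clade {clade!r} has zero carriers")
    mrca = tree.mrca(carriers)
    if origin is None:
        origin = mrca
        event_map.add(Event(branch=origin.id, kind=ORIGIN, clade=clade))
    elif not tree.is_ancestor(origin, mrca):
        raise TreeError(f"forced origin {origin.id!r} below carrier MRCA for {clade!r}")
    present = _spanning_presence(tree, origin, carriers)
    for node_id in sorted(present):
        node = tree.node(node_id)
        for child in node.children:
            if child.id not in present:
                event_map.add(Event(branch=child.id, kind=LOSS, clade=clade))
    for sp in pseudo_tips:
        event_map.add(Event(branch=sp, kind=PSEUDOGENIZATION, clade=clade))
    return present


def dollo_reconstruct(species_tree: Tree, matrix: PresenceMatrix
                      ) -> tuple[EventMap, AncestralRepertoire]:
    """Single-gain / minimal-loss reconstruction from the matrix alone.

    Every clade originates at the MRCA of its carriers; each maximal
    carrier-free subtree below the origin receives one loss on its stem,
    which is provably the minimal loss set for a single-origin history.
    """
    matrix.validate_against(species_tree)
    event_map = EventMap()
    presence: dict[str, set[str]] = {}
    for clade in matrix.clades:
        carriers = matrix.carriers(clade)
        pseudo = {sp for sp in carriers if matrix.state(sp, clade) == PSEUDOGENE}
        presence[clade] = _dollo_single_clade(species_tree, clade, carriers,
                                              pseudo, event_map)
    repertoire = _repertoire_from_presence(species_tree, presence, matrix)
    return event_map, repertoire


def _repertoire_from_presence(tree: Tree, presence: Mapping[str, set[str]],
                              matrix: Optional[PresenceMatrix]) -> AncestralRepertoire:
    per_node: dict[str, dict[str, str]] = {n.id: {} for n in tree.preorder()}
    leaf_ids = set(tree.leaf_ids())
    for clade, nodes in presence.items():
        for node_id in nodes:
            state = INTACT
            if matrix is not None and node_id in leaf_ids \
                    and node_id in matrix.species and clade in matrix.clades:
                cell = matrix.state(node_id, clade)
                state = cell if cell != ABSENT else INTACT
            per_node[node_id][clade] = state
    return AncestralRepertoire(per_node)


# ---------------------------------------------------------------------------
# LCA reconciliation of the clade tree
# ---------------------------------------------------------------------------

def _lineage_label(clade_node: Node) -> str:
    if clade_node.is_leaf:
        return clade_node.id
    leaves = sorted(n.id for n in _leaves_under(clade_node))
    return "anc(" + "+".join(leaves) + ")"


def _leaves_under(node: Node) -> Iterable[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _child_towards(tree: Tree, ancestor: Node, descendant: Node) -> Node:
    """Child of ``ancestor`` on the path to ``descendant``."""
    walker = descendant
    while walker.parent is not ancestor:
        walker = walker.parent
        if walker is None:
            raise TreeError("descendant does not descend from ancestor")
    return walker


def reconcile(clade_tree: Tree, species_tree: Tree, matrix: PresenceMatrix
              ) -> tuple[EventMap, AncestralRepertoire]:
    """Duplication-loss reconciliation of the clade tree with the species tree.

    Returns the event map (origin of the family, per-branch duplications,
    losses and terminal pseudogenizations) and the ancestral repertoire at
    every species-tree node, in which ancestral lineages that later split
    at speciations are named ``anc(<member>+...)``.
    """
    matrix.validate_against(species_tree)
    for leaf in clade_tree.leaves():
        if leaf.id not in matrix.clades:
            raise TreeError(f"clade in tree but absent from matrix: {leaf.id!r}")

    smap: dict[str, Node] = {}
    event_kind: dict[str, str] = {}
    for node in clade_tree.postorder():
        if node.is_leaf:
            smap[node.id] = species_tree.mrca(matrix.carriers(node.id))
        else:
            child_maps = [smap[c.id] for c in node.children]
            # LCA over species nodes: lift pairwise
            current = child_maps[0]
            for other in child_maps[1:]:
                current = _species_lca(species_tree, current, other)
            smap[node.id] = current
            dup = any(smap[c.id] is smap[node.id] for c in node.children)
            event_kind[node.id] = DUPLICATION if dup else SPECIATION

    labels = {node.id: _lineage_label(node) for node in clade_tree.preorder()}

    event_map = EventMap()
    for node in clade_tree.preorder():
        kind = "leaf" if node.is_leaf else event_kind[node.id]
        event_map.node_mapping[node.id] = (smap[node.id].id, kind)
    presence: dict[str, set[str]] = {}

    root = clade_tree.root
    event_map.add(Event(branch=smap[root.id].id, kind=ORIGIN,
                        clade=labels[root.id]))

    def process(cnode: Node, start: Node) -> None:
        label = labels[cnode.id]
        mapped = smap[cnode.id]
        if cnode.is_leaf:
            carriers = matrix.carriers(cnode.id)
            pseudo = {sp for sp in carriers
                      if matrix.state(sp, cnode.id) == PSEUDOGENE}
            presence[label] = _dollo_single_clade(
                species_tree, label, carriers, pseudo, event_map, origin=start)
            return

        kind = event_kind[cnode.id]
        path = _species_path(species_tree, start, mapped)
        if kind == DUPLICATION:
            alive = set(path) - {mapped.id}
            # losses on side branches strictly above the duplication point
            for node_id in path:
                if node_id == mapped.id:
                    continue
                node = species_tree.node(node_id)
                for child in node.children:
                    if child.id not in path:
                        event_map.add(Event(branch=child.id, kind=LOSS, clade=label))
            for child in cnode.children:
                event_map.add(Event(branch=mapped.id, kind=DUPLICATION,
                                    clade=labels[child.id], parent_clade=label))
                process(child, mapped)
        else:  # speciation: lineage survives to `mapped`, splits below it
            alive = set(path)
            covered_children: set[str] = set()
            for child in cnode.children:
                child_start = _child_towards(species_tree, mapped, smap[child.id])
                covered_children.add(child_start.id)
                event_map.add_divergence(child_start.id, label, labels[child.id])
                process(child, child_start)
            for node_id in path:
                node = species_tree.node(node_id)
                for child in node.children:
                    if child.id in path:
                        continue
                    if node is mapped and child.id in covered_children:
                        continue
                    event_map.add(Event(branch=child.id, kind=LOSS, clade=label))
        if alive:
            presence[label] = alive

    process(root, smap[root.id])
    repertoire = _repertoire_from_presence(species_tree, presence, matrix)
    return event_map, repertoire


def _species_lca(tree: Tree, a: Node, b: Node) -> Node:
    ancestors = {n.id for n in tree.path_to_root(a)}
    walker: Optional[Node] = b
    while walker is not None and walker.id not in ancestors:
        walker = walker.parent
    if walker is None:
        raise TreeError("nodes share no common ancestor")
    return walker


def _species_path(tree: Tree, top: Node, bottom: Node) -> list[str]:
    """Node ids from ``top`` down to ``bottom`` (inclusive)."""
    path = [bottom.id]
    walker = bottom
    while walker is not top:
        walker = walker.parent
        if walker is None:
            raise TreeError("path endpoints are not nested")
        path.append(walker.id)
    return path[::-1]


# ---------------------------------------------------------------------------
# Exon-structure comparison
# ---------------------------------------------------------------------------

@dataclass
class StructureDiff:
    """Intron gains/losses between two gene models of one family."""

    intron_gains: list[int] = field(default_factory=list)   # coding offsets
    intron_losses: list[int] = field(default_factory=list)
    exon_count_delta: int = 0

    @property
    def is_identical(self) -> bool:
        return not self.intron_gains and not self.intron_losses


def compare_gene_models(reference: GeneModel, derived: GeneModel,
                        tolerance: int = 0) -> StructureDiff:
    """Diff exon structures aligned by cumulative coding length.

    An intron gain appears as one reference exon corresponding to two
    derived exons whose junction falls at a coding offset absent from the
    reference (e.g. the extra introns in exons 3 and 6 of ray-finned-fish
    TAS1R3B, turning the canonical six-exon gene into eight exons).
    """
    if abs(reference.coding_length - derived.coding_length) > tolerance:
        raise ValueError(
            "coding lengths differ beyond tolerance: "
            f"{reference.coding_length} vs {derived.coding_length}")
    ref_bounds = set(reference.exon_boundaries())
    der_bounds = set(derived.exon_boundaries())
    return StructureDiff(
        intron_gains=sorted(der_bounds - ref_bounds),
        intron_losses=sorted(ref_bounds - der_bounds),
        exon_count_delta=derived.exon_count - reference.exon_count,
    )
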