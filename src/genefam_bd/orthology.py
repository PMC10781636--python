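"""Speciation/duplication labelling of gene trees and ortholog-clade cutting.

Internal nodes of a rooted gene tree are labelled by the species-overlap
rule: a node is a duplication if the species sets of at least two of its
children intersect, otherwise a speciation.  Ortholog clades are then the
maximal connected pieces of the tree that contain no *clade-separating*
duplication.  Which duplications separate clades is controlled by a
taxon-group map (species -> named group, e.g. "Amphibia"): a duplication
confined to one group produces subclades (e.g. the three TAS1R6 subclades
of cartilaginous fishes), not new clades; a duplication confined to a
single species (e.g. the two zebrafish TAS1R2B copies) never separates
anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .trees import Node, Tree, TreeError

DUPLICATION = "duplication"
SPECIATION = "speciation"
CLADE_LEVEL = "clade"
SUBCLADE_LEVEL = "subclade"


def species_sets(gene_tree: Tree, species_map: Mapping[str, str]) -> dict[str, frozenset[str]]:
    """Species set subtended by every node, keyed by node id."""
    sets: dict[str, frozenset[str]] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            if node.id not in species_map:
                raise TreeError(f"gene leaf with no species mapping: {node.id!r}")
            sets[node.id] = frozenset((species_map[node.id],))
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= sets[child.id]
            sets[node.id] = frozenset(acc)
    return sets


def label_duplications(gene_tree: Tree, species_map: Mapping[str, str]) -> dict[str, str]:
    """Label each internal node duplication/speciation by species overlap.

    Under a polytomy the node is a duplication if *any* pair of children
    overlaps in species content (pairwise, conservative rule).
    """
    sets = species_sets(gene_tree, species_map)
    events: dict[str, str] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            continue
        seen: set[str] = set()
        event = SPECIATION
        for child in node.children:
            child_set = sets[child.id]
            if seen & child_set:
                event = DUPLICATION
                break
            seen |= child_set
        events[node.id] = event
    return events


@dataclass
class CladeAssignment:
    """Gene -> clade label (and optionally gene -> subclade label)."""

    clade_of: dict[str, str]
    subclade_of: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.clade_of.values()))

    def genes_in(self, label: str) -> list[str]:
        return sorted(g for g, c in self.clade_of.items() if c == label)

    def n_clades(self) -> int:
        return len(set(self.clade_of.values()))


def _group_of(species: str, taxon_groups: Optional[Mapping[str, str]]) -> str:
    if taxon_groups and species in taxon_groups:
        return taxon_groups[species]
    return species  # ungrouped species form their own singleton group


def _separates(node: Node, level: str,
               sets: Mapping[str, frozenset[str]],
               taxon_groups: Optional[Mapping[str, str]]) -> bool:
    spp = sets[node.id]
    if len(spp) == 1:
        return False  # within-species duplication never separates
    if level == SUBCLADE_LEVEL:
        return True  # any multi-species duplication forms subclades
    groups = {_group_of(sp, taxon_groups) for sp in spp}
    return len(groups) > 1


def extract_clades(gene_tree: Tree, events: Mapping[str, str],
                   species_map: Mapping[str, str],
                   level: str = CLADE_LEVEL,
                   taxon_groups: Optional[Mapping[str, str]] = None,
                   label_names: Optional[Mapping[str, str]] = None) -> CladeAssignment:
    """Cut a duplication-labelled gene tree into ortholog clades.

    Clades are the connected components obtained after removing every
    duplication node that separates lineages at the requested level.
    Component labels are deterministic (``clade_01`` ... in order of the
    lexicographically smallest member gene); ``label_names`` may remap the
    smallest member gene id to a display label.
    """
    if level not in (CLADE_LEVEL, SUBCLADE_LEVEL):
        raise ValueError(f"unknown level: {level!r}")
    for node in gene_tree.preorder():
        if not node.is_leaf and node.id not in events:
            raise TreeError(f"internal node without event label: {node.id!r}")
    sets = species_sets(gene_tree, species_map)

    # Union-find over nodes; separating duplication nodes keep their
    # children's components apart (the node itself joins no component).
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    for node in gene_tree.postorder():
        if node.is_leaf:
            find(node.id)
            continue
        if events[node.id] == DUPLICATION and _separates(node, level, sets, taxon_groups):
            continue
        for child in node.children:
            union(child.id, node.id)

    components: dict[str, list[str]] = {}
    for leaf in gene_tree.leaves():
        components.setdefault(find(leaf.id), []).append(leaf.id)

    ordered = sorted(components.values(), key=lambda genes: min(genes))
    width = max(2, len(str(len(ordered))))
    clade_of: dict[str, str] = {}
    for k, genes in enumerate(ordered, start=1):
        rep = min(genes)
        if label_names and rep in label_names:
            label = label_names[rep]
        else:
            label = f"clade_{k:0{width}d}"
        for gene in genes:
            clade_of[gene] = label
    return CladeAssignment(clade_of=clade_of)


def separating_duplications(gene_tree: Tree, events: Mapping[str, str],
                            species_map: Mapping[str, str],
                            level: str = CLADE_LEVEL,
                            taxon_groups: Optional[Mapping[str, str]] = None
                            ) -> set[str]:
    """Ids of duplication nodes that separate clades at the given level."""
    sets = species_sets(gene_tree, species_map)
    return {
        node.id for node in gene_tree.preorder()
        if not node.is_leaf and events[node.id] == DUPLICATION
        and _separates(node, level, sets, taxon_groups)
    }


def collapse_to_clade_tree(gene_tree: Tree, events: Mapping[str, str],
                           species_map: Mapping[str, str],
                           assignment: CladeAssignment,
                           level: str = CLADE_LEVEL,
                           taxon_groups: Optional[Mapping[str, str]] = None,
                           with_cut_map: bool = False):
    """Contract each ortholog clade to a single leaf named by its label.

    The gene tree is cut at the clade-separating duplication nodes (the
    same rule used by :func:`extract_clades`); each resulting component
    becomes one leaf, and the between-clade duplications and speciations
    are retained as the internal structure of the clade tree.

    With ``with_cut_map`` also returns {gene-tree cut node id -> clade-tree
    node id} so callers can trace inferred events back to gene-tree nodes.
    """
    cut = separating_duplications(gene_tree, events, species_map,
                                  level, taxon_groups)
    counter = [0]
    cut_map: dict[str, str] = {}

    def internal(kids: list[Node]) -> Node:
        if len(kids) == 1:
            return kids[0]
        node = Node(f"n{counter[0]}")
        counter[0] += 1
        for k in kids:
            node.add_child(k)
        return node

    def component(top: Node) -> Node:
        """Collapse the component rooted at a non-cut node to one leaf,
        keeping the cut subtrees branching off inside it as siblings.

        The component's own gene content becomes a single leaf hoisted to
        the top of the component; nested separating duplications retain
        their relative nesting.
        """
        label: Optional[str] = None
        has_tips = False

        def walk(node: Node) -> list[Node]:
            nonlocal label, has_tips
            if node.is_leaf:
                has_tips = True
                found = assignment.clade_of[node.id]
                if label is not None and found != label:
                    raise TreeError("inconsistent assignment within a component")
                label = found
                return []
            parts: list[Node] = []
            for child in node.children:
                if not child.is_leaf and child.id in cut:
                    parts.append(build_cut(child))
                else:
                    sub = walk(child)
                    if sub:
                        parts.append(internal(sub) if len(sub) > 1 else sub[0])
            return parts

        parts = walk(top)
        if label is None:
            # no gene tips of its own: pure structure between cut nodes
            if not parts:
                raise TreeError("component without leaves or structure")
            return internal(parts)
        leaf = Node(label)
        if not parts:
            return leaf
        return internal([leaf] + parts)

    def build_cut(node: Node) -> Node:
        kids = []
        for child in node.children:
            if not child.is_leaf and child.id in cut:
                kids.append(build_cut(child))
            else:
                kids.append(component(child))
        built = internal(kids)
        cut_map[node.id] = built.id
        return built

    root_node = gene_tree.root
    if not root_node.is_leaf and root_node.id in cut:
        root = build_cut(root_node)
    else:
        root = component(root_node)
    tree = Tree(root)
    if with_cut_map:
        return tree, cut_map
    return tree


def collapse_pure_subtrees(gene_tree: Tree, assignment: CladeAssignment
                           ) -> tuple[Tree, CladeAssignment, dict[str, str]]:
    """Faithful reduction: contract each maximal single-clade subtree.

    Unlike :func:`collapse_to_clade_tree` this keeps one leaf per
    *contiguous chunk* of a clade, so the reduced tree preserves the exact
    branching structure of the gene tree (a clade whose copies are
    interleaved with nested duplications yields several chunk leaves).
    Chunk leaves are labelled ``<clade>.<k>``; the returned assignment maps
    genes to chunk labels and the dict maps chunk label -> clade label.
    """
    pure: dict[str, Optional[str]] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            pure[node.id] = assignment.clade_of[node.id]
        else:
            child_labels = {pure[c.id] for c in node.children}
            pure[node.id] = (child_labels.pop()
                             if len(child_labels) == 1 and None not in child_labels
                             else None)

    counters: dict[str, int] = {}
    chunk_of: dict[str, str] = {}
    chunk_clade: dict[str, str] = {}
    counter = [0]

    def chunk_leaf(node: Node) -> Node:
        clade = pure[node.id]
        counters[clade] = counters.get(clade, 0) + 1
        label = f"{clade}.{counters[clade]}"
        chunk_clade[label] = clade
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                chunk_of[n.id] = label
            stack.extend(n.children)
        return Node(label)

    def build(node: Node) -> Node:
        if pure[node.id] is not None:
            return chunk_leaf(node)
        new = Node(f"n{counter[0]}")
        counter[0] += 1
        for child in node.children:
            new.add_child(build(child))
        return new

    root = build(gene_tree.root)
    return Tree(root), CladeAssignment(clade_of=chunk_of), chunk_clade


def matrix_from_assignment(assignment: CladeAssignment,
                           species_map: Mapping[str, str],
                           species_tree: Tree,
                           pseudogenes: Optional[set[str]] = None):
    """Presence matrix (species x extracted clade) implied by an assignment."""
    from .trees import PresenceMatrix

    pseudogenes = pseudogenes or set()
    per_cell: dict[tuple[str, str], list[bool]] = {}
    for gene, clade in assignment.clade_of.items():
        sp = species_map[gene]
        per_cell.setdefault((sp, clade), []).append(gene in pseudogenes)
    cells = {}
    for (sp, clade), flags in per_cell.items():
        token = "1" if any(not f for f in flags) else "P"
        if len(flags) > 1:
            token += f":{len(flags)}"
        cells[(sp, clade)] = token
    species = sorted(set(species_tree.leaf_ids()) & set(species_map.values()))
    return PresenceMatrix.from_cells(species, assignment.labels, cells)


def clades_per_species(source, species_map: Optional[Mapping[str, str]] = None,
                       pseudogenes: Optional[set[str]] = None,
                       count_pseudogenes: bool = False) -> dict[str, int]:
    """Number of distinct clades with members in each species.

    ``source`` is either a :class:`~genefam_bd.trees.PresenceMatrix` or a
    :class:`CladeAssignment` (the latter needs ``species_map`` and, to
    exclude pseudogene copies, the set of pseudogene gene ids).
    Pseudogene-only presence does not count unless ``count_pseudogenes``.
    """
    from .trees import PresenceMatrix, ABSENT, INTACT

    if isinstance(source, PresenceMatrix):
        counts: dict[str, int] = {}
        for sp in source.species:
            row = source.states.loc[sp]
            if count_pseudogenes:
                counts[sp] = int((row != ABSENT).sum())
            else:
                counts[sp] = int((row == INTACT).sum())
        return counts

    if species_map is None:
        raise ValueError("species_map required for a CladeAssignment source")
    pseudogenes = pseudogenes or set()
    per_species: dict[str, set[str]] = {}
    for gene, clade in source.clade_of.items():
        if gene in pseudogenes and not count_pseudogenes:
            continue
        per_species.setdefault(species_map[gene], set()).add(clade)
    return {sp: len(clades) for sp, clades in per_species.items()}
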