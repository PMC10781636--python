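"""Rooted-tree and presence-matrix data model shared by every analysis stage.

Trees are kept deliberately small: labelled rooted trees with parent/child
links, optional branch lengths, support values and node ages (Ma).  Newick
parsing is delegated to :mod:`dendropy`; this module only converts into the
lightweight structure used throughout the package.  Trees are treated as
rooted exactly as given -- no automatic rerooting is performed (rooting,
e.g. with an outgroup, is the caller's job).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy
import pandas as pd


_AUTO_ID = re.compile(r"n\d+")


class TreeError(ValueError):
    """Invalid tree structure or query."""


class NewickParseError(TreeError):
    """Malformed Newick input; the message names the offending token."""


class MatrixError(ValueError):
    """Invalid presence/absence matrix."""


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

class Node:
    __slots__ = ("id", "name", "parent", "children", "length", "support", "age")

    def __init__(self, id: str, name: Optional[str] = None,
                 length: Optional[float] = None,
                 support: Optional[float] = None,
                 age: Optional[float] = None):
        self.id = id
        self.name = name if name is not None else id
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.length = length
        self.support = support
        self.age = age

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id!r})"


class Tree:
    """Rooted tree with unique node identifiers; polytomies permitted."""

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] = {}
        for node in self.preorder():
            if node.id in self._index:
                raise TreeError(f"duplicate node identifier: {node.id!r}")
            self._index[node.id] = node

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def node(self, node_id: str) -> Node:
        try:
            return self._index[node_id]
        except KeyError:
            raise TreeError(f"unknown node identifier: {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def nodes(self) -> Iterable[Node]:
        return self._index.values()

    # -- queries -----------------------------------------------------------

    def path_to_root(self, node: Node) -> list[Node]:
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    def depth(self, node: Node) -> int:
        return len(self.path_to_root(node)) - 1

    def mrca(self, leaf_ids: Iterable[str]) -> Node:
        """Least node whose leaf descendants contain all of ``leaf_ids``."""
        ids = list(leaf_ids)
        if not ids:
            raise TreeError("mrca of an empty set is undefined")
        nodes = [self.node(i) for i in ids]
        current = nodes[0]
        ancestors = {n.id for n in self.path_to_root(current)}
        for other in nodes[1:]:
            walker: Optional[Node] = other
            while walker is not None and walker.id not in ancestors:
                walker = walker.parent
            if walker is None:  # different trees -- cannot happen post-index
                raise TreeError("nodes share no common ancestor")
            current = walker
            ancestors = {n.id for n in self.path_to_root(current)}
        return current

    def is_ancestor(self, ancestor: Node, node: Node) -> bool:
        """True if ``ancestor`` is ``node`` or lies on its root path."""
        walker: Optional[Node] = node
        while walker is not None:
            if walker is ancestor:
                return True
            walker = walker.parent
        return False

    def leaf_set(self, node: Node) -> frozenset[str]:
        return frozenset(n.id for n in self._subtree(node) if n.is_leaf)

    def _subtree(self, node: Node) -> Iterator[Node]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def subtree_nodes(self, node: Node) -> Iterator[Node]:
        return self._subtree(node)

    def branch_duration(self, node: Node) -> Optional[float]:
        """Branch time above ``node`` in Ma, from node ages if present."""
        if node.parent is None:
            return None
        if node.parent.age is not None and node.age is not None:
            return node.parent.age - node.age
        return node.length

    def set_ages(self, ages: dict[str, float], leaf_age: float = 0.0) -> None:
        for node in self.preorder():
            if node.id in ages:
                node.age = ages[node.id]
            elif node.is_leaf:
                node.age = leaf_age

    # -- serialisation -----------------------------------------------------

    def write_newick(self, with_lengths: bool = True,
                     with_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.id
            else:
                inner = ",".join(fmt(c) for c in node.children)
                if node.support is not None and with_support:
                    label = f"({inner}){node.support:g}"
                elif not _AUTO_ID.fullmatch(node.id):
                    label = f"({inner}){node.id}"
                else:
                    label = f"({inner})"
            if with_lengths and node.length is not None:
                label += f":{node.length:g}"
            return label

        return fmt(self.root) + ";"


def _from_dendropy(dtree: "dendropy.Tree") -> Tree:
    counter = [0]

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if label is None:
                raise NewickParseError("unlabelled leaf in Newick input")
            node = Node(str(label), length=dnode.edge.length)
        else:
            label = dnode.label
            support = None
            name = None
            if label is not None:
                try:
                    support = float(label)
                except (TypeError, ValueError):
                    name = str(label)
            node_id = name if name is not None else f"n{counter[0]}"
            counter[0] += 1
            node = Node(node_id, name=name, length=dnode.edge.length,
                        support=support)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
        return node

    return Tree(convert(dtree.seed_node))


def read_newick(text: str) -> Tree:
    """Parse one rooted Newick tree.

    Internal-node labels that parse as numbers are stored as support
    values; any other internal label becomes the node's identifier.
    Unnamed internal nodes receive deterministic ``n<k>`` identifiers in
    preorder.  Duplicate leaf labels are rejected.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()
              if leaf.taxon is not None]
    seen: set[str] = set()
    for label in labels:
        if label in seen:
            raise NewickParseError(f"duplicate leaf label: {label!r}")
        seen.add(label)
    return _from_dendropy(dtree)


# ---------------------------------------------------------------------------
# Presence/absence/pseudogene matrix
# ---------------------------------------------------------------------------

ABSENT = "absent"
INTACT = "intact"
PSEUDOGENE = "pseudogene"
STATES = (ABSENT, INTACT, PSEUDOGENE)


class PresenceMatrix:
    """Species x clade states in {absent, intact, pseudogene}.

    Cells optionally carry an integer copy number (>= 1 when not absent).
    The TSV dialect uses ``0`` (absent), ``1`` (intact), ``P`` (pseudogene)
    and ``1:n`` / ``P:n`` for copy number ``n``.
    """

    def __init__(self, states: pd.DataFrame, copies: Optional[pd.DataFrame] = None):
        bad = set(states.values.ravel()) - set(STATES)
        if bad:
            raise MatrixError(f"unknown state token(s): {sorted(bad)}")
        self.states = states
        if copies is None:
            copies = (states != ABSENT).astype(int)
        self.copies = copies
        if ((self.copies.values < 1) & (states.values != ABSENT)).any():
            raise MatrixError("copy number must be >= 1 for non-absent cells")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_cells(cls, species: list[str], clades: list[str],
                   cells: dict[tuple[str, str], str]) -> "PresenceMatrix":
        """Build from sparse {(species, clade): token} cells; default absent."""
        states = pd.DataFrame(ABSENT, index=list(species), columns=list(clades))
        copies = pd.DataFrame(0, index=list(species), columns=list(clades))
        for (sp, cl), token in cells.items():
            state, n = _parse_cell(token)
            states.loc[sp, cl] = state
            copies.loc[sp, cl] = n
        return cls(states, copies)

    @classmethod
    def read_tsv(cls, source) -> "PresenceMatrix":
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        raw = pd.read_csv(source, sep="\t", index_col=0, dtype=str)
        states = raw.copy()
        copies = raw.copy()
        for sp in raw.index:
            for cl in raw.columns:
                state, n = _parse_cell(str(raw.loc[sp, cl]))
                states.loc[sp, cl] = state
                copies.loc[sp, cl] = n
        return cls(states, copies.astype(int))

    def write_tsv(self) -> str:
        out = pd.DataFrame("0", index=self.states.index, columns=self.states.columns)
        for sp in self.states.index:
            for cl in self.states.columns:
                state = self.states.loc[sp, cl]
                n = int(self.copies.loc[sp, cl])
                if state == ABSENT:
                    token = "0"
                else:
                    token = "1" if state == INTACT else "P"
                    if n > 1:
                        token += f":{n}"
                out.loc[sp, cl] = token
        buf = io.StringIO()
        out.to_csv(buf, sep="\t", index_label="species")
        return buf.getvalue()

    # -- queries -----------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return list(self.states.index)

    @property
    def clades(self) -> list[str]:
        return list(self.states.columns)

    def state(self, species: str, clade: str) -> str:
        return self.states.loc[species, clade]

    def copy_number(self, species: str, clade: str) -> int:
        return int(self.copies.loc[species, clade])

    def carriers(self, clade: str, include_pseudogenes: bool = True) -> list[str]:
        col = self.states[clade]
        if include_pseudogenes:
            mask = col != ABSENT
        else:
            mask = col == INTACT
        return list(col.index[mask])

    def validate_against(self, species_tree: Tree) -> None:
        leaf_ids = set(species_tree.leaf_ids())
        unknown = [sp for sp in self.species if sp not in leaf_ids]
        if unknown:
            raise MatrixError(f"species not in tree: {unknown}")
        empty = [cl for cl in self.clades if not self.carriers(cl)]
        if empty:
            raise MatrixError(f"clade(s) with zero carriers: {empty}")


def _parse_cell(token: str) -> tuple[str, int]:
    token = token.strip()
    base, _, count = token.partition(":")
    n = 1
    if count:
        try:
            n = int(count)
        except ValueError:
            raise MatrixError(f"bad copy number in cell {token!r}") from None
        if n < 1:
            raise MatrixError(f"copy number must be >= 1: {token!r}")
    if base == "0":
        if count:
            raise MatrixError(f"absent cell cannot carry copies: {token!r}")
        return ABSENT, 0
    if base == "1":
        return INTACT, n
    if base.upper() == "P":
        return PSEUDOGENE, n
    raise MatrixError(f"unknown state token: {token!r}")


def read_presence_matrix(tsv, species_tree: Optional[Tree] = None) -> PresenceMatrix:
    """Read the TSV matrix dialect, optionally validating against a tree."""
    matrix = PresenceMatrix.read_tsv(tsv)
    if species_tree is not None:
        matrix.validate_against(species_tree)
    return matrix


# ---------------------------------------------------------------------------
# Gene models (exon/intron structure)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Exon structure of one gene; coordinates 0-based half-open.

    ``exons`` are listed in transcription order: ascending genomic
    coordinates on "+", descending on "-".
    """

    gene_id: str
    species_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model requires at least one exon")
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"bad exon interval ({start}, {end})")
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")
        genomic = self.exons if self.strand == "+" else self.exons[::-1]
        if genomic != sorted(genomic):
            raise ValueError("exons not in transcription order")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def coding_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def start_codon_position(self) -> int:
        """Genomic coordinate of the first transcribed base (A of ATG)."""
        first = self.exons[0]
        return first[0] if self.strand == "+" else first[1] - 1

    def exon_boundaries(self) -> list[int]:
        """Cumulative coding offsets of internal exon junctions."""
        offsets, total = [], 0
        for start, end in self.exons[:-1]:
            total += end - start
            offsets.append(total)
        return offsets


def read_gene_models(tsv: str) -> list[GeneModel]:
    """Read 6-column BED-like TSV: scaffold, start, end, strand, gene, species.

    Rows sharing a gene id are exons of one model; intervals are sorted
    into transcription order per strand.
    """
    rows: dict[str, dict] = {}
    for line in tsv.strip().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        scaffold, start, end, strand, gene, species = line.split("\t")
        rec = rows.setdefault(gene, {"scaffold": scaffold, "strand": strand,
                                     "species": species, "exons": []})
        rec["exons"].append((int(start), int(end)))
    models = []
    for gene, rec in rows.items():
        exons = sorted(rec["exons"], reverse=(rec["strand"] == "-"))
        models.append(GeneModel(gene_id=gene, species_id=rec["species"],
                                scaffold=rec["scaffold"], strand=rec["strand"],
                                exons=exons))
    return models
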