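"""Synthetic-data generators with recorded ground truth.

Three generators cover the three inference stages:

* ``simulate_family`` -- gene birth and death along a dated species tree
  (Gillespie per branch; duplication rate lambda, loss rate mu and
  pseudogenization rate psi in events per lineage per Ma).  Every
  duplication spawns a new clade label, so the truth records each clade's
  true origin branch, the per-branch events, the true gene tree and the
  tip presence matrix.
* ``simulate_upstream`` -- i.i.d. background sequence at a given GC content
  with a motif word planted in carrier species at recorded offsets.
* ``simulate_assay`` -- replicate AUC plates (independent experiments x
  duplicate wells) with planted responder ligands.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assay import CONTROL_LIGAND
from .trees import Node, PresenceMatrix, Tree

ROOT_CLADE = "g0"


@dataclass
class SimulationConfig:
    seed: int                         # mandatory: no wall-clock seeding
    duplication_rate: float = 0.002   # events / lineage / Ma
    loss_rate: float = 0.001
    pseudogenization_rate: float = 0.0
    root_copies: int = 1
    max_retries: int = 100            # resampling cap for all-extinct families

    def __post_init__(self) -> None:
        for name in ("duplication_rate", "loss_rate", "pseudogenization_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.root_copies < 1:
            raise ValueError("root_copies must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated family."""

    origin_branch: dict[str, str] = field(default_factory=dict)
    presence: dict[str, dict[str, int]] = field(default_factory=dict)
    events: list[tuple[str, str, str]] = field(default_factory=list)
    #: gene-tree duplication nodes that survived on both sides -> branch
    dup_node_branch: dict[str, str] = field(default_factory=dict)
    n_duplications: int = 0
    n_losses: int = 0

    def carriers(self, clade: str, tree: Tree) -> list[str]:
        leaves = set(tree.leaf_ids())
        return sorted(sp for sp, state in self.presence.items()
                      if sp in leaves and state.get(clade, 0) > 0)


@dataclass
class FamilySimulation:
    gene_tree: Tree
    species_map: dict[str, str]
    pseudogenes: set[str]
    matrix: PresenceMatrix
    clade_tree: Tree
    truth: SimTruth


def simulate_family(species_tree: Tree, config: SimulationConfig
                    ) -> FamilySimulation:
    """Gillespie duplication/loss simulation along a dated species tree.

    The species tree must carry node ages (Ma) or branch lengths; branch
    duration is taken from ages where both ends have one.  Families whose
    every copy goes extinct before reaching a tip are resampled (fresh
    draws from the same stream) up to ``max_retries`` times.
    """
    rng = np.random.default_rng(config.seed)
    for _attempt in range(config.max_retries):
        result = _simulate_once(species_tree, config, rng)
        if result is not None:
            return result
    raise RuntimeError("family went extinct in every resampling attempt")


def _simulate_once(species_tree: Tree, config: SimulationConfig,
                   rng: np.random.Generator) -> Optional[FamilySimulation]:
    lam, mu, psi = (config.duplication_rate, config.loss_rate,
                    config.pseudogenization_rate)
    truth = SimTruth()
    clade_parent: dict[str, str] = {ROOT_CLADE: ""}
    clade_counter = [0]
    node_counter = [0]
    tip_counter: dict[str, int] = {}
    leaf_records: list[tuple[str, str, str, bool]] = []

    def new_clade(parent: str) -> str:
        clade_counter[0] += 1
        label = f"g{clade_counter[0]}"
        clade_parent[label] = parent
        return label

    def join(children: list[Node]) -> Optional[Node]:
        kids = [c for c in children if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node_counter[0] += 1
        node = Node(f"gn{node_counter[0]}")
        for k in kids:
            node.add_child(k)
        return node

    def at_node(clade: str, pseudo: bool, snode: Node) -> Optional[Node]:
        truth.presence.setdefault(snode.id, {})
        truth.presence[snode.id][clade] = \
            truth.presence[snode.id].get(clade, 0) + 1
        if snode.is_leaf:
            k = tip_counter.get(snode.id, 0) + 1
            tip_counter[snode.id] = k
            gene_id = f"{snode.id}__{k}"
            leaf_records.append((gene_id, snode.id, clade, pseudo))
            return Node(gene_id)
        return join([on_branch(clade, pseudo, child) for child in snode.children])

    def on_branch(clade: str, pseudo: bool, child_snode: Node,
                  remaining: Optional[float] = None) -> Optional[Node]:
        if remaining is None:
            remaining = species_tree.branch_duration(child_snode) or 0.0
        branch = child_snode.id
        while True:
            rate = mu + (lam + psi if not pseudo else 0.0)
            if rate == 0.0:
                return at_node(clade, pseudo, child_snode)
            wait = rng.exponential(1.0 / rate)
            if wait >= remaining:
                return at_node(clade, pseudo, child_snode)
            remaining -= wait
            u = rng.random() * rate
            if not pseudo and u < lam:
                label = new_clade(clade)
                truth.origin_branch[label] = branch
                truth.events.append((branch, "duplication", label))
                truth.n_duplications += 1
                left = on_branch(clade, pseudo, child_snode, remaining)
                right = on_branch(label, False, child_snode, remaining)
                node = join([left, right])
                if node is not None and len(node.children) == 2:
                    truth.dup_node_branch[node.id] = branch
                return node
            if not pseudo and u < lam + psi:
                truth.events.append((branch, "pseudogenization", clade))
                pseudo = True
                continue
            truth.events.append((branch, "loss", clade))
            truth.n_losses += 1
            return None

    truth.origin_branch[ROOT_CLADE] = species_tree.root.id
    roots = [at_node(ROOT_CLADE, False, species_tree.root)
             for _ in range(config.root_copies)]
    gene_root = join(roots)
    if gene_root is None or not leaf_records:
        return None
    gene_tree = Tree(gene_root)

    species_map = {g: sp for g, sp, _cl, _ps in leaf_records}
    pseudogenes = {g for g, _sp, _cl, ps in leaf_records if ps}

    surviving = sorted({cl for _g, _sp, cl, _ps in leaf_records},
                       key=lambda c: int(c[1:]))
    cells: dict[tuple[str, str], str] = {}
    leaves = sorted(species_tree.leaf_ids())
    for sp in leaves:
        per_clade: dict[str, list[bool]] = {}
        for g, gsp, cl, ps in leaf_records:
            if gsp == sp:
                per_clade.setdefault(cl, []).append(ps)
        for cl, flags in per_clade.items():
            intact = any(not f for f in flags)
            token = "1" if intact else "P"
            if len(flags) > 1:
                token += f":{len(flags)}"
            cells[(sp, cl)] = token
    matrix = PresenceMatrix.from_cells(leaves, surviving, cells)
    clade_tree = _clade_tree_from_parents(surviving, clade_parent)
    return FamilySimulation(gene_tree=gene_tree, species_map=species_map,
                            pseudogenes=pseudogenes, matrix=matrix,
                            clade_tree=clade_tree, truth=truth)


def _clade_tree_from_parents(surviving: Sequence[str],
                             clade_parent: dict[str, str]) -> Tree:
    """Duplication tree over surviving clade labels.

    Each duplication splits its parent lineage into (parent-continued, new
    label); successive duplications of one lineage therefore nest with the
    earliest duplication outermost.  Extinct intermediate labels are kept
    only where needed to connect survivors, then suppressed.
    """
    children: dict[str, list[str]] = {}
    keep = set(surviving)

    def lineage(label: str) -> list[str]:
        path = [label]
        while clade_parent.get(path[-1]):
            path.append(clade_parent[path[-1]])
        return path

    needed: set[str] = set()
    for label in surviving:
        needed.update(lineage(label))
    for label in sorted(needed, key=lambda c: int(c[1:])):
        parent = clade_parent.get(label)
        if parent:
            children.setdefault(parent, []).append(label)

    def build(label: str) -> Optional[Node]:
        kids = sorted(children.get(label, []), key=lambda c: int(c[1:]))
        current = Node(label) if label in keep else None
        # later duplications are nested deeper: fold from the latest kid
        for kid in reversed(kids):
            kid_node = build(kid)
            if kid_node is None:
                continue
            if current is None:
                current = kid_node
                continue
            joint = Node(f"d_{label}_{kid}")
            joint.add_child(current)
            joint.add_child(kid_node)
            current = joint
        return current

    root_label = ROOT_CLADE if ROOT_CLADE in needed else surviving[0]
    root = build(root_label)
    if root is None:
        raise RuntimeError("no surviving clades")
    return Tree(root)


# ---------------------------------------------------------------------------
# Upstream sequences with planted words
# ---------------------------------------------------------------------------

@dataclass
class UpstreamTruth:
    planted: dict[str, tuple[int, str]]    # species -> (offset, strand)


def simulate_upstream(species: Sequence[str], word: str,
                      carrier_species: Sequence[str], L: int, gc: float,
                      seed: int, strand: str = "+",
                      avoid_chance_hits: bool = True
                      ) -> tuple[dict[str, str], UpstreamTruth]:
    """I.i.d. background windows with ``word`` planted in the carriers.

    Background base probabilities follow the GC content; the word is
    planted at a uniformly drawn offset.  With ``avoid_chance_hits`` the
    background is resampled until it contains no chance occurrence of the
    word on either strand (useful when exact hit recovery is asserted).
    """
    if L < len(word):
        raise ValueError("window shorter than the word")
    carriers = set(carrier_species)
    unknown = carriers - set(species)
    if unknown:
        raise ValueError(f"carriers not among species: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    from .motif import reverse_complement

    rc = reverse_complement(word)

    def count_occurrences(seq: str) -> int:
        return sum(seq[i:i + len(word)] in (word, rc)
                   for i in range(len(seq) - len(word) + 1))

    windows: dict[str, str] = {}
    truth = UpstreamTruth(planted={})
    for sp in species:
        while True:
            seq = "".join(rng.choice(list("ACGT"), size=L, p=p))
            if avoid_chance_hits and count_occurrences(seq) > 0:
                continue
            if sp in carriers:
                pos = int(rng.integers(0, L - len(word) + 1))
                planted = word if strand == "+" else rc
                seq = seq[:pos] + planted + seq[pos + len(word):]
                # splicing the word in can create a second, overlapping
                # occurrence; resample until the planted hit is unique
                if avoid_chance_hits and count_occurrences(seq) != 1:
                    continue
                truth.planted[sp] = (pos - L, strand)
            windows[sp] = seq
            break
    return windows, truth


# ---------------------------------------------------------------------------
# Assay plates with planted responders
# ---------------------------------------------------------------------------

@dataclass
class AssayTruth:
    responders: set[str]
    delta: float
    sigma: float


def simulate_assay(ligands: Sequence[str], effect_ligands: Sequence[str],
                   delta: float, sigma: float, n_experiments: int = 6,
                   n_wells: int = 2, receptor_pair: str = "pair",
                   concentration: float = 50.0, seed: int = 0,
                   control_mean: float = 0.0
                   ) -> tuple[pd.DataFrame, AssayTruth]:
    """Replicate AUC table with planted responder ligands.

    Per-well AUCs are normal around ``control_mean`` (+``delta`` for effect
    ligands) with s.d. ``sigma``; the replicate structure is
    ``n_experiments`` independent experiments each with ``n_wells``
    duplicate wells, plus matched buffer controls.
    """
    effect = set(effect_ligands)
    unknown = effect - set(ligands)
    if unknown:
        raise ValueError(f"effect ligands not in panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for ligand in list(ligands) + [CONTROL_LIGAND]:
        mean = control_mean + (delta if ligand in effect else 0.0)
        for experiment in range(1, n_experiments + 1):
            for well in range(1, n_wells + 1):
                rows.append({
                    "receptor_pair": receptor_pair,
                    "ligand": ligand,
                    "concentration": (0.0 if ligand == CONTROL_LIGAND
                                      else concentration),
                    "experiment": experiment,
                    "well": well,
                    "auc": float(rng.normal(mean, sigma)),
                })
    table = pd.DataFrame(rows)
    return table, AssayTruth(responders=effect, delta=delta, sigma=sigma)
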