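"""Shared fixtures and random-tree helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from genefam_bd import fixture as fx
from genefam_bd.trees import Node, Tree


def random_tree(rng: np.random.Generator, n_leaves: int,
                prefix: str = "L") -> Tree:
    """Random rooted binary-ish tree built by sequential leaf attachment."""
    nodes = [Node(f"{prefix}{i}") for i in range(n_leaves)]
    counter = [0]
    while len(nodes) > 1:
        k = 2 if len(nodes) == 2 else int(rng.integers(2, min(3, len(nodes)) + 1))
        picks = rng.choice(len(nodes), size=k, replace=False)
        parent = Node(f"{prefix}int{counter[0]}")
        counter[0] += 1
        for i in sorted(picks, reverse=True):
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    return Tree(nodes[0])


def brute_force_mrca(tree: Tree, leaf_ids: list[str]) -> str:
    """Oracle: intersect full root paths and take the deepest shared node."""
    paths = []
    for lid in leaf_ids:
        path = [n.id for n in tree.path_to_root(tree.node(lid))]
        paths.append(path)
    shared = set(paths[0])
    for path in paths[1:]:
        shared &= set(path)
    # deepest = first along any root path
    for node_id in paths[0]:
        if node_id in shared:
            return node_id
    raise AssertionError("no shared ancestor")


def dollo_oracle(tree: Tree, carriers: set[str]) -> int:
    """Exhaustive minimum loss count over all single-origin histories.

    Enumerates every presence assignment on the nodes that (i) matches the
    carrier tips exactly and (ii) has exactly one node whose parent is
    absent (the single gain); returns the minimum number of present->absent
    edges (losses).
    """
    nodes = list(tree.preorder())
    index = {n.id: i for i, n in enumerate(nodes)}
    best = None
    for mask in range(1, 1 << len(nodes)):
        present = [(mask >> i) & 1 for i in range(len(nodes))]
        ok = True
        gains = losses = 0
        for n in nodes:
            i = index[n.id]
            if n.is_leaf and present[i] != (n.id in carriers):
                ok = False
                break
            if n.parent is None:
                gains += present[i]
            else:
                pi = index[n.parent.id]
                if present[i] and not present[pi]:
                    gains += 1
                elif present[pi] and not present[i]:
                    losses += 1
        if not ok or gains != 1:
            continue
        if best is None or losses < best:
            best = losses
    assert best is not None, "no valid single-origin history"
    return best


@pytest.fixture(scope="session")
def bundle():
    return fx.paper_fixture()


@pytest.fixture(scope="session")
def species_tree():
    return fx.species_tree()


@pytest.fixture(scope="session")
def fixture_matrix():
    return fx.presence_matrix()


@pytest.fixture(scope="session")
def labelled_fixture(bundle):
    """Fixture gene tree with duplication labels and clade assignment."""
    from genefam_bd import orthology

    events = orthology.label_duplications(bundle.gene_tree, bundle.species_map)
    assignment = orthology.extract_clades(
        bundle.gene_tree, events, bundle.species_map, level="clade",
        taxon_groups=bundle.taxon_groups,
        label_names=fx.CLADE_DISPLAY_NAMES)
    return events, assignment
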