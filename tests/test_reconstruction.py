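"""Dollo parsimony, LCA reconciliation, event replay and exon-structure diff."""

import numpy as np
import pytest

from genefam_bd import fixture as fx, orthology
from genefam_bd.reconstruction import (compare_gene_models, dollo_reconstruct,
                                       reconcile)
from genefam_bd.simulate import SimulationConfig, simulate_family
from genefam_bd.trees import GeneModel, PresenceMatrix, TreeError, read_newick

from conftest import dollo_oracle, random_tree


def matrix_from_carriers(tree, carriers, clade="c1"):
    cells = {(sp, clade): "1" for sp in carriers}
    return PresenceMatrix.from_cells(sorted(tree.leaf_ids()), [clade], cells)


def replay_matches_matrix(event_map, tree, matrix):
    replayed = event_map.replay(tree)
    for sp in matrix.species:
        want = {c: matrix.state(sp, c) for c in matrix.clades
                if matrix.state(sp, c) != "absent"}
        if replayed[sp] != want:
            return False
    return True


class TestDollo:
    def test_clade_in_all_tips_originates_at_root(self, species_tree,
                                                  fixture_matrix):
        matrix = matrix_from_carriers(species_tree, species_tree.leaf_ids())
        event_map, repertoire = dollo_reconstruct(species_tree, matrix)
        assert event_map.origin_branch("c1") == species_tree.root.id
        assert not any(e.kind == "loss" for e in event_map.all_events())
        assert repertoire.size(species_tree.root.id) == 1

    def test_fixture_tas1r7_origin_at_tetrapod_ancestor(self, species_tree,
                                                        fixture_matrix):
        event_map, _ = dollo_reconstruct(species_tree, fixture_matrix)
        assert event_map.origin_branch("TAS1R7") == "tetrapod_ancestor"

    def test_zero_carrier_clade_rejected(self, species_tree):
        import pandas as pd

        empty = PresenceMatrix(pd.DataFrame(
            "absent", index=species_tree.leaf_ids(), columns=["c1"]))
        with pytest.raises(Exception):
            dollo_reconstruct(species_tree, empty)

    def test_loss_count_equals_exhaustive_minimum(self):
        rng = np.random.default_rng(99)
        for case in range(200):
            n = int(rng.integers(2, 7))
            tree = random_tree(rng, n)
            leaves = tree.leaf_ids()
            k = int(rng.integers(1, n + 1))
            carriers = set(rng.choice(leaves, size=k, replace=False))
            matrix = matrix_from_carriers(tree, carriers)
            event_map, _ = dollo_reconstruct(tree, matrix)
            losses = sum(1 for e in event_map.all_events() if e.kind == "loss")
            assert losses == dollo_oracle(tree, carriers), f"case {case}"

    def test_replay_reproduces_fixture_matrix(self, species_tree,
                                              fixture_matrix):
        event_map, _ = dollo_reconstruct(species_tree, fixture_matrix)
        assert replay_matches_matrix(event_map, species_tree, fixture_matrix)


@pytest.fixture(scope="module")
def result(species_tree, fixture_matrix):
    return reconcile(fx.clade_tree(), species_tree, fixture_matrix)


class TestReconcile:
    def test_jawed_ancestor_has_five_lineages(self, result):
        _em, repertoire = result
        assert repertoire.size("jawed_vertebrate_ancestor",
                               count_pseudogenes=True) == 5

    def test_jawed_ancestor_lineage_identities(self, result):
        _em, repertoire = result
        labels = repertoire.labels_at("jawed_vertebrate_ancestor")
        assert {"TAS1R4", "TAS1R7", "TAS1R8"} <= labels
        assert any("TAS1R3A" in l and "TAS1R3C" in l for l in labels)
        assert any("TAS1R6" in l and "TAS1R5" in l for l in labels)

    def test_bony_ancestor_has_nine(self, result):
        _em, repertoire = result
        assert repertoire.size("bony_vertebrate_ancestor",
                               count_pseudogenes=True) == 9

    def test_tas1r2b_origin_and_sarcopterygian_loss(self, result, species_tree):
        em, _ = result
        assert em.origin_branch("TAS1R2B") == "bony_vertebrate_ancestor"
        assert "TAS1R2B" in em.losses_on_branch(species_tree,
                                                "sarcopterygian_ancestor")

    @pytest.mark.parametrize("branch,expected", [
        ("tetrapod_ancestor", ["TAS1R8"]),
        ("amniote_ancestor", ["TAS1R3B", "TAS1R5"]),
        ("human", ["TAS1R4", "TAS1R7"]),   # the sampled mammalian stem
    ])
    def test_losses_on_named_stems(self, result, species_tree, branch, expected):
        em, _ = result
        assert em.losses_on_branch(species_tree, branch) == expected

    def test_unknown_branch_raises(self, result, species_tree):
        em, _ = result
        with pytest.raises(TreeError):
            em.losses_on_branch(species_tree, "no_such_branch")

    def test_clade_missing_from_matrix_rejected(self, species_tree,
                                                fixture_matrix):
        bad_tree = read_newick("(TAS1R1,TAS1R99);")
        with pytest.raises(TreeError):
            reconcile(bad_tree, species_tree, fixture_matrix)

    def test_replay_reproduces_fixture_matrix(self, result, species_tree,
                                              fixture_matrix):
        em, _ = result
        assert replay_matches_matrix(em, species_tree, fixture_matrix)

    def test_pseudogenization_on_terminal_branches(self, result):
        em, _ = result
        pseudo = [(e.branch, e.clade) for e in em.all_events()
                  if e.kind == "pseudogenization"]
        assert ("australian_lungfish", "TAS1R3B") in pseudo
        assert ("whale_shark", "TAS1R3C") in pseudo

    def test_dollo_origin_never_above_reconcile_origin(self, result,
                                                       species_tree,
                                                       fixture_matrix):
        em, _ = result
        dollo_em, _ = dollo_reconstruct(species_tree, fixture_matrix)
        for clade in fixture_matrix.clades:
            dollo_node = species_tree.node(dollo_em.origin_branch(clade))
            rec_node = species_tree.node(em.first_appearance(clade))
            assert species_tree.is_ancestor(rec_node, dollo_node)

    def test_one_creating_event_per_duplication_born_clade(self, result,
                                                           fixture_matrix):
        em, _ = result
        for clade in fixture_matrix.clades:
            creating = [e for e in em.all_events() if e.clade == clade
                        and e.kind in ("origin", "duplication")]
            diverging = [1 for pairs in em.divergences.values()
                         for _p, c in pairs if c == clade]
            assert len(creating) + len(diverging) == 1


class TestSimulationRecovery:
    def test_origin_branches_recovered_at_low_rates(self, species_tree):
        ok = tot = 0
        for seed in range(100):
            sim = simulate_family(species_tree, SimulationConfig(
                seed=seed, duplication_rate=0.002, loss_rate=0.001))
            events = orthology.label_duplications(sim.gene_tree,
                                                  sim.species_map)
            assignment = orthology.extract_clades(
                sim.gene_tree, events, sim.species_map, level="subclade")
            ctree, cut_map = orthology.collapse_to_clade_tree(
                sim.gene_tree, events, sim.species_map, assignment,
                level="subclade", with_cut_map=True)
            matrix = orthology.matrix_from_assignment(
                assignment, sim.species_map, species_tree, sim.pseudogenes)
            em, _ = reconcile(ctree, species_tree, matrix)
            for gene_node, clade_node in cut_map.items():
                mapped, kind = em.node_mapping[clade_node]
                tot += 1
                ok += int(kind == "duplication"
                          and mapped == sim.truth.dup_node_branch[gene_node])
        assert ok / tot >= 0.95

    def test_event_count_never_exceeds_truth(self, species_tree):
        for seed in range(100):
            sim = simulate_family(species_tree, SimulationConfig(
                seed=seed, duplication_rate=0.002, loss_rate=0.001))
            events = orthology.label_duplications(sim.gene_tree,
                                                  sim.species_map)
            assignment = orthology.extract_clades(
                sim.gene_tree, events, sim.species_map, level="subclade")
            ctree, chunk_assign, _names = orthology.collapse_pure_subtrees(
                sim.gene_tree, assignment)
            matrix = orthology.matrix_from_assignment(
                chunk_assign, sim.species_map, species_tree, sim.pseudogenes)
            em, _ = reconcile(ctree, species_tree, matrix)
            inferred = (sum(1 for _n, (_m, k) in em.node_mapping.items()
                            if k == "duplication")
                        + sum(1 for e in em.all_events() if e.kind == "loss"))
            assert inferred <= sim.truth.n_duplications + sim.truth.n_losses

    def test_event_count_exact_without_hidden_events(self, species_tree):
        for seed in range(50):
            sim = simulate_family(species_tree, SimulationConfig(
                seed=seed, duplication_rate=0.001, loss_rate=0.0))
            events = orthology.label_duplications(sim.gene_tree,
                                                  sim.species_map)
            sets = orthology.species_sets(sim.gene_tree, sim.species_map)
            assignment = orthology.extract_clades(
                sim.gene_tree, events, sim.species_map, level="subclade")
            ctree, chunk_assign, _names = orthology.collapse_pure_subtrees(
                sim.gene_tree, assignment)
            matrix = orthology.matrix_from_assignment(
                chunk_assign, sim.species_map, species_tree, sim.pseudogenes)
            em, _ = reconcile(ctree, species_tree, matrix)
            inferred_dups = sum(1 for _n, (_m, k) in em.node_mapping.items()
                                if k == "duplication")
            inferred_losses = sum(1 for e in em.all_events()
                                  if e.kind == "loss")
            # species-specific duplications are out of scope by design
            visible = sum(1 for nid in sim.truth.dup_node_branch
                          if len(sets[nid]) > 1)
            assert inferred_losses == 0
            assert inferred_dups == visible

    def test_replay_reproduces_simulated_matrices(self, species_tree):
        for seed in range(50):
            sim = simulate_family(species_tree, SimulationConfig(
                seed=seed, duplication_rate=0.002, loss_rate=0.001,
                pseudogenization_rate=0.0003))
            em, _ = dollo_reconstruct(species_tree, sim.matrix)
            assert replay_matches_matrix(em, species_tree, sim.matrix)


class TestCompareGeneModels:
    @staticmethod
    def canonical_model(boundaries=(300, 700, 1100, 1600, 2000), total=2400):
        """Six-exon model from internal junction offsets (coding coords)."""
        edges = [0, *boundaries, total]
        exons = []
        pos = 0
        for a, b in zip(edges, edges[1:]):
            exons.append((pos, pos + (b - a)))
            pos += (b - a) + 500   # arbitrary intron of 500 bp
        return GeneModel("g", "sp", "scf", "+", exons)

    def test_two_intron_gains_make_eight_exons(self):
        reference = self.canonical_model()
        derived = self.canonical_model(
            boundaries=(300, 550, 700, 1100, 1600, 2000, 2200))
        diff = compare_gene_models(reference, derived)
        assert diff.intron_gains == [550, 2200]
        assert diff.intron_losses == []
        assert diff.exon_count_delta == 2
        assert derived.exon_count == 8

    def test_identical_models_give_empty_diff(self):
        diff = compare_gene_models(self.canonical_model(),
                                   self.canonical_model())
        assert diff.is_identical and diff.exon_count_delta == 0

    def test_random_intron_insertions_recovered(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            total = 2400
            base = sorted(rng.choice(np.arange(100, total - 100, 10),
                                     size=5, replace=False))
            reference = self.canonical_model(boundaries=tuple(base), total=total)
            k = int(rng.integers(1, 4))
            candidates = [x for x in range(100, total - 100, 10)
                          if x not in base]
            gains = sorted(rng.choice(candidates, size=k, replace=False))
            derived = self.canonical_model(
                boundaries=tuple(sorted([*base, *gains])), total=total)
            diff = compare_gene_models(reference, derived)
            assert diff.intron_gains == [int(x) for x in gains]
            assert diff.exon_count_delta == k

    def test_length_mismatch_rejected(self):
        reference = self.canonical_model(total=2400)
        derived = self.canonical_model(total=2500)
        with pytest.raises(ValueError):
            compare_gene_models(reference, derived)
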