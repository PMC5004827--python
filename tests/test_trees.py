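"""Neighbor joining, monophyly tests and swap detection."""

import dendropy
import numpy as np
import pytest

from conftest import make_alignment, make_meta
from matriline import (
    DistanceMatrix,
    collapse_haplotypes,
    detect_swaps,
    distance_matrix,
    median_join,
    nj_tree,
    test_monophyly as assess_monophyly,
    simulate_dataset,
    SimulationConfig,
)


def tree_distances(tree: dendropy.Tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


def additive_matrix():
    # known 4-taxon tree: ((a:2,b:3):1,(c:4,d:5)) -> additive distances
    ids = ("a", "b", "c", "d")
    m = np.array([
        [0, 5, 7, 8],
        [5, 0, 8, 9],
        [7, 8, 0, 9],
        [8, 9, 9, 0],
    ], dtype=float)
    return DistanceMatrix(ids=ids, matrix=m, model="p")


class TestNJ:
    def test_three_taxa_additive_lengths(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=("a", "b", "c"), matrix=m))
        d = tree_distances(tree)
        assert d("a", "b") == pytest.approx(3)
        assert d("a", "c") == pytest.approx(4)
        assert d("b", "c") == pytest.approx(5)

    def test_four_taxa_recovers_generating_tree(self):
        tree = nj_tree(additive_matrix())
        d = tree_distances(tree)
        dm = additive_matrix()
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1:]:
                assert d(a, b) == pytest.approx(dm.get(a, b))
        # topology: (a,b) form a cherry
        mrca = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(x) for x in "ab"])
        assert {lf.taxon.label for lf in mrca.leaf_iter()} <= {"a", "b", "c", "d"}
        assert len(list(mrca.leaf_iter())) == 2

    def test_input_order_does_not_change_topology(self, two_species):
        alignment, _, _ = two_species
        table = collapse_haplotypes(alignment)
        dm = distance_matrix(table.to_alignment())
        perm = list(reversed(dm.ids))
        idx = [dm.ids.index(i) for i in perm]
        dm2 = DistanceMatrix(
            ids=tuple(perm), matrix=dm.matrix[np.ix_(idx, idx)], model=dm.model
        )
        bip = lambda t: {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in t.preorder_internal_node_iter()
        }
        assert bip(nj_tree(dm)) == bip(nj_tree(dm2))

    def test_matches_reference_nj_on_random_additive_trees(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(8)
        for _ in range(5):
            n = int(rng.integers(6, 11))
            # random additive tree distances: random caterpillar topology
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                rng=__import__("random").Random(int(rng.integers(1 << 30))),
            )
            for t, lab in zip(tree.taxon_namespace, "abcdefghijklm"):
                t.label = lab
            pdm = tree.phylogenetic_distance_matrix()
            ids = sorted(t.label for t in tree.taxon_namespace)
            taxa = {t.label: t for t in tree.taxon_namespace}
            m = np.array([
                [pdm.distance(taxa[a], taxa[b]) for b in ids] for a in ids
            ])
            ours = nj_tree(DistanceMatrix(ids=tuple(ids), matrix=m))
            ref = skbio_nj(SkbioDM(m, ids))
            # both must reproduce the additive distances exactly
            d_ours = tree_distances(ours)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    assert d_ours(a, b) == pytest.approx(m[ids.index(a), ids.index(b)], abs=1e-8)
                    assert ref.find(a).distance(ref.find(b)) == pytest.approx(
                        m[ids.index(a), ids.index(b)], abs=1e-8
                    )

    def test_outgroup_rooting(self):
        tree = nj_tree(additive_matrix(), outgroup_ids=["d"])
        assert tree.is_rooted
        kids = tree.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in k.leaf_iter()} for k in kids]
        assert {"d"} in sides


class TestMonophyly:
    def build(self, seqs, species):
        aln = make_alignment(seqs)
        meta = make_meta(species)
        table = collapse_haplotypes(aln)
        tree = nj_tree(distance_matrix(table.to_alignment()))
        net = median_join(table, metadata=meta)
        return table, meta, tree, net

    def test_two_clean_species_both_monophyletic(self):
        table, meta, tree, net = self.build(
            {"a1": "AAAAAAAAAAAA", "a2": "AAAAAAAAAAAG",
             "b1": "AAAACCCAAAAA", "b2": "AAAACCCAAAAG"},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        for target in (tree, net):
            assert assess_monophyly(target, table, meta, "A").is_monophyletic
            assert assess_monophyly(target, table, meta, "B").is_monophyletic

    def test_intruding_leaf_defeats_monophyly_and_is_reported(self):
        table, meta, tree, net = self.build(
            {"a1": "AAAAAAAAAAAA", "a2": "AAAAAAAAAAAG", "x": "GAAACCCAAAAA",
             "b1": "AAAACCCAAAAA", "b2": "AAAACCCAAAAG"},
            {"a1": "A", "a2": "A", "x": "A", "b1": "B", "b2": "B"},
        )
        res_a = assess_monophyly(tree, table, meta, "A")
        res_b = assess_monophyly(tree, table, meta, "B")
        assert not res_a.is_monophyletic
        assert not res_b.is_monophyletic
        x_hap = table.haplotype_of("x")
        assert x_hap in res_b.offending

    def test_unknown_species_rejected(self, introgression_analysis, introgression):
        table, network, _ = introgression_analysis
        _, metadata, _ = introgression
        with pytest.raises(ValueError, match="absent"):
            assess_monophyly(network, table, metadata, "nosuch")

    def test_simulated_introgression_breaks_recipient_and_donor(
        self, introgression_analysis, introgression
    ):
        table, network, tree = introgression_analysis
        _, metadata, _ = introgression
        for target in (tree, network):
            assert not assess_monophyly(target, table, metadata, "gymnocercus").is_monophyletic
            assert not assess_monophyly(target, table, metadata, "griseus").is_monophyletic
            assert assess_monophyly(target, table, metadata, "vetulus").is_monophyletic

    def test_verdicts_stable_under_leaf_reordering(self):
        seqs = {"a1": "AAAAAAAAAAAA", "a2": "AAAAAAAAAAAG",
                "b1": "AAAACCCAAAAA", "b2": "AAAACCCAAAAG"}
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        t1 = self.build(seqs, species)
        t2 = self.build(dict(reversed(list(seqs.items()))), species)
        for sp in ("A", "B"):
            assert (
                assess_monophyly(t1[2], t1[0], t1[1], sp).is_monophyletic
                == assess_monophyly(t2[2], t2[0], t2[1], sp).is_monophyletic
            )


class TestSwapDetection:
    def test_consistent_labels_give_empty_report(self, two_species):
        alignment, metadata, _ = two_species
        table = collapse_haplotypes(alignment)
        net = median_join(table, metadata=metadata)
        tree = nj_tree(distance_matrix(table.to_alignment()))
        assert detect_swaps(tree, net, table, metadata) == []

    def test_relabeled_individuals_are_recovered(self):
        cfg = SimulationConfig(
            species_tree="(north:800000,south:800000);",
            sample_sizes={"north": 8, "south": 8}, seed=13,
        )
        aln, meta, _ = simulate_dataset(cfg)
        # field mislabels two southern individuals as northern
        relabeled = {"south_07", "south_08"}
        wrong = make_meta({
            i: ("north" if i in relabeled else meta.species_of(i)) for i in aln.ids
        })
        table = collapse_haplotypes(aln)
        net = median_join(table, metadata=wrong)
        tree = nj_tree(distance_matrix(table.to_alignment()))
        report = detect_swaps(tree, net, table, wrong)
        assert {r.individual_id for r in report} == relabeled
        assert all(r.assigned_species == "south" for r in report)

    def test_singleton_species_never_flagged(self):
        # one individual of species "lone" placed inside species "big"
        aln = make_alignment({
            "b1": "AAAAAA", "b2": "AAAAAG", "b3": "AAAAGG", "lone": "AAAAAA"[:5] + "G",
        })
        meta = make_meta({"b1": "big", "b2": "big", "b3": "big", "lone": "lone"})
        table = collapse_haplotypes(aln)
        net = median_join(table, metadata=meta)
        tree = nj_tree(distance_matrix(table.to_alignment()))
        report = detect_swaps(tree, net, table, meta)
        assert all(r.individual_id != "lone" for r in report)

    def test_planted_introgression_fully_recovered(
        self, introgression_analysis, introgression
    ):
        table, network, tree = introgression_analysis
        _, metadata, truth = introgression
        report = detect_swaps(tree, network, table, metadata)
        assert {(r.individual_id, r.assigned_species) for r in report} == set(
            truth.introgressed
        )

    def test_requires_some_evidence_source(self, two_species):
        alignment, metadata, _ = two_species
        table = collapse_haplotypes(alignment)
        with pytest.raises(ValueError):
            detect_swaps(None, None, table, metadata)
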