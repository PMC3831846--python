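"""Neighbour joining, rooting, Fitch parsimony, clock LRT, divergence."""

import numpy as np
import pytest

from alutrack import phylo
from alutrack.align import AlignParams, anchor_to_consensus
from alutrack.phylo import _Pruner, _jc_p
from alutrack.simulate import evolve_jc, random_additive_matrix, random_clock_tree
from alutrack.verification import brute_force_parsimony


class TestNJ:
    def test_three_taxon_branch_lengths(self):
        # three-point formulas: d(A,B)=2, d(A,C)=d(B,C)=4 -> A=1, B=1, C=3
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = phylo.build_nj_tree(D, ["A", "B", "C"])
        lengths = {tree.labels[n]: tree.lengths[n] for n in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_topology_recovered(self, rng):
        # additive matrix from ((A,B),(C,D)) with known branch lengths
        D = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 5],
                [10, 11, 5, 0],
            ],
            float,
        )
        tree = phylo.build_nj_tree(D, ["A", "B", "C", "D"])
        assert tree.bipartitions() == {frozenset({"A", "B"})}

    def test_additive_recovery_up_to_12_leaves(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            D, labels, true_tree = random_additive_matrix(n, rng)
            nj = phylo.build_nj_tree(D, labels)
            assert nj.bipartitions() == true_tree.bipartitions()
            # and path lengths are reproduced (additivity)
            la, Da = true_tree.leaf_distances()
            lb, Db = nj.leaf_distances()
            oa, ob = np.argsort(la), np.argsort(lb)
            np.testing.assert_allclose(
                Da[np.ix_(oa, oa)], Db[np.ix_(ob, ob)], atol=1e-9
            )

    def test_agrees_with_skbio_on_additive_matrix(self, rng):
        # independent cross-check against scikit-bio's NJ
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        D, labels, _tree = random_additive_matrix(9, rng)
        ours = phylo.build_nj_tree(D, labels)
        theirs = skbio_nj(DistanceMatrix(D, ids=labels))
        their_parts = set()
        all_leaves = frozenset(labels)
        for node in theirs.non_tips():
            part = frozenset(t.name for t in node.tips())
            side = min(part, all_leaves - part, key=lambda s: (len(s), sorted(s)))
            if 2 <= len(side) <= len(all_leaves) - 2:
                their_parts.add(side)
        assert ours.bipartitions() == their_parts

    def test_zero_matrix_star_with_zero_lengths(self):
        D = np.zeros((4, 4))
        tree = phylo.build_nj_tree(D, list("ABCD"))
        assert all(tree.lengths[n] == 0.0 for n in tree.leaves())

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0, 1], [2, 0]], float),          # asymmetric
            np.array([[0, -1], [-1, 0]], float),        # negative
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            phylo.build_nj_tree(bad, ["A", "B"])


class TestRooting:
    def test_root_between_outgroup_and_rest(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = phylo.build_nj_tree(D, ["A", "B", "C"])
        rooted = phylo.root_with_outgroup(tree, "C")
        assert rooted.rooted and rooted.is_binary()
        kids = rooted.children[rooted.root]
        labels = {rooted.labels.get(k) for k in kids}
        assert "C" in labels

    def test_path_lengths_preserved(self, rng):
        D, labels, _t = random_additive_matrix(8, rng)
        tree = phylo.build_nj_tree(D, labels)
        rooted = phylo.root_with_outgroup(tree, labels[0])
        la, Da = tree.leaf_distances()
        lb, Db = rooted.leaf_distances()
        oa, ob = np.argsort(la), np.argsort(lb)
        np.testing.assert_allclose(Da[np.ix_(oa, oa)], Db[np.ix_(ob, ob)], atol=1e-9)

    def test_unknown_outgroup(self, rng):
        D, labels, _t = random_additive_matrix(5, rng)
        tree = phylo.build_nj_tree(D, labels)
        with pytest.raises(KeyError):
            phylo.root_with_outgroup(tree, "nope")


class TestFitch:
    def _tree(self, newick_like):
        # ((A,B),(C,D)) with unit branch lengths
        t = phylo.LineageTree()
        root = t.add_node(None)
        left = t.add_node(root, 1.0)
        right = t.add_node(root, 1.0)
        t.add_node(left, 1.0, "A")
        t.add_node(left, 1.0, "B")
        t.add_node(right, 1.0, "C")
        t.add_node(right, 1.0, "D")
        t.root, t.rooted = root, True
        return t

    def test_single_change(self):
        t = self._tree(None)
        states, length = phylo.fitch_ancestral(
            t, {"A": "G", "B": "G", "C": "T", "D": "T"}
        )
        assert length == 1

    def test_identical_leaves_zero_length(self):
        t = self._tree(None)
        states, length = phylo.fitch_ancestral(
            t, {lab: "ACGT" for lab in "ABCD"}
        )
        assert length == 0
        assert all(s == "ACGT" for n, s in states.items())

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(15):
            tree = random_clock_tree(6, rng, height=0.5)
            states = evolve_jc(tree, 40, rng)
            _anc, plen = phylo.fitch_ancestral(tree, states)
            assert plen == brute_force_parsimony(tree, states)

    def test_length_invariant_to_rerooting(self, rng):
        D, labels, _t = random_additive_matrix(7, rng)
        unrooted = phylo.build_nj_tree(D, labels)
        states = {lab: "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
                  for lab in labels}
        lengths = set()
        for lab in labels:
            rooted = phylo.root_with_outgroup(unrooted, lab)
            _anc, plen = phylo.fitch_ancestral(rooted, states)
            lengths.add(plen)
        assert len(lengths) == 1

    def test_missing_leaf_states_rejected(self):
        t = self._tree(None)
        with pytest.raises(ValueError, match="missing"):
            phylo.fitch_ancestral(t, {"A": "G", "B": "G", "C": "T"})


class TestLikelihoodAndClock:
    def test_two_leaf_pruning_equals_closed_form(self):
        t = phylo.LineageTree()
        root = t.add_node(None)
        t.add_node(root, 0.07, "A")
        t.add_node(root, 0.05, "B")
        t.root, t.rooted = root, True
        aln = {"A": "ACGTACGTAC", "B": "ACGTACGTAA"}
        pruner = _Pruner(t, aln)
        got = pruner.loglik(
            np.array([0.07 if t.labels[n] == "A" else 0.05 for n in pruner.edge_nodes])
        )
        p0, p1 = _jc_p(0.12)  # JC distance is additive over the two edges
        expected = 9 * np.log(0.25 * p0) + 1 * np.log(0.25 * p1)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_identical_sequences_do_not_reject(self, rng):
        tree = random_clock_tree(5, rng, height=0.05)
        aln = {lab: "ACGTACGTACGTACGTACGT" for lab in tree.leaf_labels()}
        res = phylo.clock_lrt(tree, aln)
        assert res.statistic == pytest.approx(0.0, abs=1e-4)
        assert res.p_value > 0.99

    def test_noclock_likelihood_dominates(self, rng):
        for _ in range(5):
            tree = random_clock_tree(6, rng, height=0.08)
            aln = evolve_jc(tree, 200, rng)
            res = phylo.clock_lrt(tree, aln)
            assert res.lnL_noclock >= res.lnL_clock - 1e-6
            assert res.df == 4
            assert 0 <= res.p_value <= 1

    def test_accelerated_branch_usually_rejected(self, rng):
        # strong violation: one tip 15x faster
        rejections = 0
        for _ in range(10):
            tree = random_clock_tree(8, rng, height=0.06)
            leaf = tree.leaves()[0]
            tree.lengths[leaf] *= 15
            aln = evolve_jc(tree, 400, rng)
            res = phylo.clock_lrt(tree, aln)
            rejections += res.p_value < 0.05
        assert rejections >= 6

    def test_requires_rooted_tree(self, rng):
        D, labels, _t = random_additive_matrix(5, rng)
        tree = phylo.build_nj_tree(D, labels)
        with pytest.raises(ValueError, match="rooted"):
            phylo.clock_lrt(tree, {lab: "ACGT" for lab in labels})


class TestGroupDivergence:
    def _els(self, toy_reg, muts_by_id):
        model = toy_reg.models["Tb8"]
        out = []
        for eid, muts in muts_by_id.items():
            seq = list(model.sequence)
            for pos, base in muts:
                seq[pos - 1] = base
            out.append(
                anchor_to_consensus("".join(seq), model, AlignParams(), eid)
            )
        return out, len(model)

    def test_identical_groups_all_zero(self, toy_reg):
        els, L = self._els(toy_reg, {"a1": [], "a2": [], "b1": [], "b2": []})
        table = phylo.mean_group_divergence(
            {"A": els[:2], "B": els[2:]}, L, model="p"
        )
        assert (table.fillna(0) == 0).all().all()

    def test_within_is_mean_of_pairs(self, toy_reg):
        # distances designed so pairwise p-dists within the group are known
        model = toy_reg.models["Tb8"].sequence
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        els, L = self._els(
            toy_reg,
            {
                "a": [],
                "b": [(5, flip[model[4]])],
                "c": [(10, flip[model[9]]), (15, flip[model[14]])],
            },
        )
        table = phylo.mean_group_divergence({"G": els}, L, model="p")
        d_ab, d_ac, d_bc = 1 / L, 2 / L, 3 / L
        assert table.loc["G", "G"] == pytest.approx((d_ab + d_ac + d_bc) / 3)

    def test_singleton_within_missing(self, toy_reg):
        els, L = self._els(toy_reg, {"a": [], "b": []})
        table = phylo.mean_group_divergence({"A": [els[0]], "B": els}, L, "p")
        assert np.isnan(table.loc["A", "A"])
        assert table.loc["B", "B"] == 0.0

    def test_young_group_less_divergent_than_old(self, toy_reg, rng):
        from alutrack.align import anchor_identity
        from alutrack.simulate import SimParams, simulate_amplification

        model = toy_reg.models["Tb8"]
        groups = {}
        for name, T in (("young", 0.5), ("old", 8.0)):
            params = SimParams(
                founder=model, timeline_my=T, n_founders=12,
                seed=int(rng.integers(2**31)),
            )
            seqs, _truth = simulate_amplification(params)
            groups[name] = [
                anchor_identity(s, model, f"{name}{c}") for c, s in seqs.items()
            ]
        table = phylo.mean_group_divergence(groups, len(model), model="k2p")
        assert table.loc["young", "young"] < table.loc["old", "old"]
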