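"""K2P distances, sliding windows, distance matrices, NJ/BIONJ and bootstrap."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from tyland import divergence as dv
from tyland import simulate as sim
from tyland import trees


class TestK2PDistance:
    def test_identical_sequences(self):
        r = dv.k2p_distance("ACGT" * 13, "ACGT" * 13)
        assert (r.distance, r.P, r.Q) == (0.0, 0.0, 0.0)

    def test_hand_value_one_transition_in_50(self):
        # P = 0.02, Q = 0: d = -0.5 ln(0.96) = 0.020410997...
        r = dv.k2p_from_counts(1, 0, 50)
        assert r.distance == pytest.approx(-0.5 * math.log(0.96), abs=1e-12)
        assert r.distance == pytest.approx(0.020411, abs=1e-6)

    def test_hand_value_with_transversions(self):
        # P = 0.1, Q = 0.05: d = -0.5 ln(0.75) - 0.25 ln(0.9)
        r = dv.k2p_from_counts(10, 5, 100)
        expected = -0.5 * math.log(1 - 0.2 - 0.05) - 0.25 * math.log(1 - 0.1)
        assert r.distance == pytest.approx(expected, abs=1e-12)

    def test_saturation_returns_na(self):
        r = dv.k2p_from_counts(5, 3, 10)  # 1 - 2P - Q = -0.3
        assert math.isnan(r.distance)
        assert "saturated" in r.reason

    def test_no_usable_sites(self):
        r = dv.k2p_distance("----", "ACGT")
        assert math.isnan(r.distance) and r.usable_sites == 0

    def test_pairwise_deletion_of_gaps_and_n(self):
        r = dv.k2p_distance("ACG-TN", "ACGATA")
        assert r.usable_sites == 4

    def test_small_distance_approximates_p_plus_q(self):
        """For small P+Q the K2P correction is nearly additive."""
        rng = np.random.default_rng(4)
        anc = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        child = sim.evolve_sequence(anc, sim.EvolutionParams(0.04, seed=1))
        r = dv.k2p_distance(anc, child)
        assert r.P + r.Q <= 0.05
        assert r.distance == pytest.approx(r.P + r.Q, abs=0.01)


class TestSlidingWindow:
    def test_identical_all_zero(self):
        track = dv.sliding_window_divergence("A" * 100, "A" * 100)
        assert all(w.result.distance == 0 for w in track.windows)

    def test_window_start_grid(self):
        track = dv.sliding_window_divergence("A" * 100, "A" * 100, window=50, step=10)
        assert [w.start for w in track.windows] == [0, 10, 20, 30, 40, 50]

    def test_oversized_window_truncates(self):
        track = dv.sliding_window_divergence("A" * 30, "A" * 30, window=50, step=10)
        assert len(track.windows) == 1
        assert (track.windows[0].start, track.windows[0].end) == (0, 30)

    def test_min_usable_gives_na(self):
        a = "A" * 10 + "-" * 40
        b = "A" * 50
        track = dv.sliding_window_divergence(a, b, window=50, step=10, min_usable=25)
        assert math.isnan(track.windows[0].result.distance)

    def test_recombinant_step_change(self, refs):
        """Windows left of a breakpoint are ~0, right of it near the
        reference divergence."""
        a, b = refs["Ty1"].internal, refs["ty1prime_internal"]
        p = 2000
        q, _ = sim.build_recombinant(a, b, [p])
        track = dv.sliding_window_divergence(q, a)
        for w in track.windows:
            if w.end <= p - 10:
                assert w.result.distance == 0.0
        right = [w.result.distance for w in track.windows if w.start >= p + 10]
        assert np.nanmean(right) == pytest.approx(0.10, abs=0.02)

    def test_per_window_matches_direct_k2p(self, refs):
        a = refs["Ty1"].internal[:500]
        b = refs["ty1prime_internal"][:500]
        track = dv.sliding_window_divergence(a, b, window=50, step=10)
        for w in track.windows:
            direct = dv.k2p_distance(a[w.start : w.end], b[w.start : w.end])
            assert w.result.distance == pytest.approx(direct.distance, nan_ok=True)


class TestDistanceMatrix:
    def test_identical_rows(self):
        dm = dv.distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert dm.d.tolist() == [[0, 0], [0, 0]]

    def test_matches_per_pair_k2p(self):
        msa = {"a": "ACGTACGTAC", "b": "ACATACGTAC", "c": "GCGTACATAC"}
        dm = dv.distance_matrix(msa)
        for i, x in enumerate(msa):
            for j, y in enumerate(msa):
                if i < j:
                    assert dm.d[i, j] == pytest.approx(
                        dv.k2p_distance(msa[x], msa[y]).distance
                    )

    def test_symmetry_random(self):
        rng = np.random.default_rng(6)
        anc = "".join("ACGT"[j] for j in rng.integers(0, 4, 300))
        msa = {
            f"r{i}": sim.evolve_sequence(anc, sim.EvolutionParams(0.1, seed=60 + i))
            for i in range(5)
        }
        dm = dv.distance_matrix(msa)
        assert np.allclose(dm.d, dm.d.T)

    def test_undefined_pair_raises_naming_pair(self):
        msa = {"a": "A" * 12, "b": "G" * 12, "c": "ACGTACGTACGT"}
        with pytest.raises(ValueError, match="a~b"):
            dv.distance_matrix(msa)


def random_additive_tree(rng, n):
    """Random binary topology with positive branch lengths; returns
    (skbio TreeNode, path-length DistanceMatrix)."""
    nodes = [trees.TreeNode(name=f"T{i}") for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        nodes.append(trees.TreeNode(children=[a, b]))
    tree = nodes[0]
    labels = [t.name for t in tree.tips()]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.find(labels[i]).distance(tree.find(labels[j]))
    return tree, dv.DistanceMatrix(labels, d)


class TestBuildTree:
    def test_four_taxon_additive_recovery_with_lengths(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): d(A,B)=3, d(A,C)=5, d(A,D)=6, ...
        labels = list("ABCD")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        dm = dv.DistanceMatrix(labels, d)
        for method in ("nj", "bionj"):
            t = trees.build_tree(dm, method)
            assert trees.bipartitions(t) == {frozenset({"C", "D"})} or trees.bipartitions(
                t
            ) == {frozenset({"A", "B"})}
            # leaf branch lengths recovered exactly on an additive matrix
            lengths = {tip.name: tip.length for tip in t.tips()}
            assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        t = trees.build_tree(dv.DistanceMatrix(list("ABC"), d), "nj")
        lengths = {tip.name: tip.length for tip in t.tips()}
        # a = (dAB + dAC - dBC)/2 = 0, b = 2, c = 3
        assert lengths == pytest.approx({"A": 0, "B": 2, "C": 3})

    def test_nj_matches_skbio_on_random_matrices(self):
        """Independent cross-check: same topology as scikit-bio's NJ."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            _, dm = random_additive_tree(rng, 7)
            noisy = dm.d + rng.uniform(0, 0.01, dm.d.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0)
            dm_n = dv.DistanceMatrix(dm.labels, noisy)
            mine = trees.build_tree(dm_n, "nj")
            ref = skbio_nj(SkbioDM(noisy, dm.labels))
            assert trees.bipartitions(mine) == trees.bipartitions(ref)

    def test_tree_metric_recovery_property(self):
        """NJ and BIONJ recover the true bipartitions from exact path-length
        matrices of random binary trees (up to 8 taxa)."""
        rng = np.random.default_rng(12)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            true_tree, dm = random_additive_tree(rng, n)
            want = trees.bipartitions(true_tree)
            for method in ("nj", "bionj"):
                got = trees.bipartitions(trees.build_tree(dm, method))
                assert got == want

    def test_na_entries_rejected(self):
        d = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            trees.build_tree(dv.DistanceMatrix(list("ABC"), d), "nj")

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            trees.build_tree(dv.DistanceMatrix(["a", "b"], np.zeros((2, 2))), "nj")


class TestBootstrap:
    @staticmethod
    def congruent_msa(refs):
        """Two clean clades: zero within-clade divergence, distinct between."""
        a = refs["Ty1"].internal[:600]
        b = refs["ty1prime_internal"][:600]
        return {"A1": a, "A2": a, "A3": a, "B1": b, "B2": b, "B3": b}

    def test_perfect_signal_gives_all_100(self, refs):
        t, _, kept = trees.bootstrap_supports(self.congruent_msa(refs), "bionj", 30, seed=1)
        assert kept == 30
        supports = [int(n.name) for n in t.non_tips() if n.name is not None]
        assert supports and all(s == 100 for s in supports)

    def test_zero_replicates_returns_point_tree(self, refs):
        t, cons, kept = trees.bootstrap_supports(self.congruent_msa(refs), "nj", 0, seed=1)
        assert kept == 0 and cons is None
        assert {x.name for x in t.tips()} == {"A1", "A2", "A3", "B1", "B2", "B3"}

    def test_seed_determinism(self, refs):
        msa = self.congruent_msa(refs)
        t1, _, _ = trees.bootstrap_supports(msa, "bionj", 20, seed=7)
        t2, _, _ = trees.bootstrap_supports(msa, "bionj", 20, seed=7)
        assert str(t1) == str(t2)


class TestNewick:
    def test_roundtrip(self, tmp_path):
        t = trees.parse_newick("(A:1,B:2,(C:3,D:4):1);")
        p = tmp_path / "t.nwk"
        trees.write_newick(t, p)
        t2 = trees.read_newick(p)
        assert trees.same_topology(t, t2)
        assert {x.name: x.length for x in t2.tips()} == {"A": 1, "B": 2, "C": 3, "D": 4}

    def test_supports_roundtrip_as_internal_labels(self, tmp_path):
        t = trees.parse_newick("(A:1,B:2,(C:3,D:4)87:1);")
        p = tmp_path / "t.nwk"
        trees.write_newick(t, p)
        t2 = trees.read_newick(p)
        internal = [n for n in t2.non_tips(include_self=False)]
        assert internal[0].name == "87"

    def test_rotation_invariant_equality(self):
        t1 = trees.parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = trees.parse_newick("((D:1,C:1):1,E:1,(B:1,A:1):1);")
        assert trees.same_topology(t1, t2)
        t3 = trees.parse_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        assert not trees.same_topology(t1, t3)

    def test_malformed_raises(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:2;")
        with pytest.raises(ValueError):
            trees.read_newick(p)
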