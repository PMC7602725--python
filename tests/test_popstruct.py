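"""IBS distances, classical MDS, F_ST estimators, and neighbor joining."""

from __future__ import annotations

import numpy as np
import pytest

import dendropy
import rohscan as rs
from rohscan.genotypes import MISSING
from rohscan.popstruct import DistanceMatrix

from conftest import make_matrix


class TestIBS:
    def test_identical_homozygous_samples_distance_zero(self):
        calls = np.tile(np.array([0, 2, 0, 2]), (2, 1))
        d = rs.ibs_distance_matrix(make_matrix(calls))
        assert d.d[0, 1] == pytest.approx(0.0)

    def test_opposite_homozygotes_distance_one(self):
        calls = np.vstack([np.zeros(5), np.full(5, 2)]).astype(int)
        d = rs.ibs_distance_matrix(make_matrix(calls))
        assert d.d[0, 1] == pytest.approx(1.0)

    def test_hand_counted_sharing(self):
        # dosages (0,1,2) vs (2,1,0): shared alleles 0 + 1 + 0 of 6
        calls = np.array([[0, 1, 2], [2, 1, 0]])
        d = rs.ibs_distance_matrix(make_matrix(calls))
        assert d.d[0, 1] == pytest.approx(5 / 6)

    def test_missing_restricts_to_joint_calls(self):
        calls = np.array([[0, 0, MISSING], [0, 2, 2]])
        d = rs.ibs_distance_matrix(make_matrix(calls))
        # two joint SNPs: shares 2 + 0 of 4
        assert d.d[0, 1] == pytest.approx(0.5)

    def test_no_joint_snps_is_an_error(self):
        calls = np.array([[0, MISSING], [MISSING, 0]])
        with pytest.raises(ValueError, match="share no called SNP"):
            rs.ibs_distance_matrix(make_matrix(calls))


class TestClassicalMDS:
    def test_two_points_at_distance_one(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        res = rs.classical_mds(d, k=1)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-0.5, 0.5])

    def test_equilateral_triangle_reproduces_distances(self):
        d = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        res = rs.classical_mds(d, k=2)
        for i in range(3):
            for j in range(i + 1, 3):
                emb = np.linalg.norm(res.coordinates[i] - res.coordinates[j])
                assert emb == pytest.approx(1.0, abs=1e-9)

    def test_planar_point_set_embeds_exactly(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        diff = pts[:, None, :] - pts[None, :, :]
        d = DistanceMatrix([f"p{i}" for i in range(12)],
                           np.sqrt((diff**2).sum(-1)))
        res = rs.classical_mds(d, k=2)
        emb = res.coordinates
        dd = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
        assert np.max(np.abs(dd - d.d)) < 1e-9

    def test_axes_ordered_by_eigenvalue_and_sign_fixed(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3)) * [5.0, 2.0, 0.5]
        diff = pts[:, None, :] - pts[None, :, :]
        d = DistanceMatrix([f"p{i}" for i in range(10)],
                           np.sqrt((diff**2).sum(-1)))
        res = rs.classical_mds(d, k=3)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        for axis in range(res.coordinates.shape[1]):
            col = res.coordinates[:, axis]
            assert col[np.argmax(np.abs(col))] > 0


class TestFst:
    def _panel(self, p1, p2, n=50, m=200, seed=0):
        rng = np.random.default_rng(seed)
        g1 = (rng.random((n, m)) < p1).astype(int) + (rng.random((n, m)) < p1).astype(int)
        g2 = (rng.random((n, m)) < p2).astype(int) + (rng.random((n, m)) < p2).astype(int)
        return make_matrix(
            np.vstack([g1, g2]), populations=["P1"] * n + ["P2"] * n
        )

    def test_identical_populations_near_zero(self):
        # duplicated tables leave a small negative bias term of order
        # -1/(2n-1), so n must be large enough for |F_ST| < 0.01
        rng = np.random.default_rng(1)
        base = rng.choice([0, 1, 2], size=(100, 150), p=[0.25, 0.5, 0.25])
        g = make_matrix(
            np.vstack([base, base]), populations=["P1"] * 100 + ["P2"] * 100
        )
        for estimator in ("hudson", "wc"):
            f = rs.hudson_fst_matrix(g, estimator=estimator)
            assert abs(f.values[0, 1]) < 0.01

    def test_fixed_opposite_alleles_give_one(self):
        n, m = 10, 50
        g = make_matrix(
            np.vstack([np.zeros((n, m)), np.full((n, m), 2)]).astype(int),
            populations=["P1"] * n + ["P2"] * n,
        )
        f = rs.hudson_fst_matrix(g)
        assert f.values[0, 1] == pytest.approx(1.0)

    def test_closed_form_limit(self):
        # p1 = 0.2, p2 = 0.8 at many SNPs: Hudson ratio tends to
        # 0.36/0.68 ~= 0.529 as sample sizes grow
        g = self._panel(0.2, 0.8, n=400, m=400, seed=2)
        f = rs.hudson_fst_matrix(g)
        assert f.values[0, 1] == pytest.approx(0.36 / 0.68, abs=0.02)

    def test_small_population_rejected(self):
        g = make_matrix(
            np.array([[0, 1], [1, 2], [2, 0]]),
            populations=["P1", "P1", "P2"],
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            rs.hudson_fst_matrix(g)


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        f = rs.FstMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = rs.neighbor_joining_tree(f)
        assert tree.newick == "(A:1,B:1,C:3);"

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 0.0, 0.0],
            ]
        )
        d[3, 2] = d[2, 3] = 7.0
        d[3, 3] = 0.0
        tree = rs.neighbor_joining_tree(rs.FstMatrix(labels, d))
        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j])

    def test_invariant_under_taxon_input_order(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 4))
        diff = pts[:, None, :] - pts[None, :, :]
        dmat = np.sqrt((diff**2).sum(-1))
        labels = [f"T{i}" for i in range(6)]
        t1 = rs.neighbor_joining_tree(rs.FstMatrix(labels, dmat))
        perm = rng.permutation(6)
        t2 = rs.neighbor_joining_tree(
            rs.FstMatrix([labels[i] for i in perm], dmat[np.ix_(perm, perm)])
        )
        assert t1.newick == t2.newick

    def test_tie_break_is_deterministic(self):
        # ultrametric with exact ties
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        labels = ["a", "b", "c", "d"]
        outs = {
            rs.neighbor_joining_tree(rs.FstMatrix(labels, d)).newick
            for _ in range(5)
        }
        assert len(outs) == 1

    def test_matches_reference_nj_topology(self):
        # independent oracle: scikit-bio's NJ on the same random matrix
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(7, 5))
        diff = pts[:, None, :] - pts[None, :, :]
        dmat = np.sqrt((diff**2).sum(-1))
        labels = [f"T{i}" for i in range(7)]
        mine = rs.neighbor_joining_tree(rs.FstMatrix(labels, dmat))
        ref = skbio.tree.nj(skbio.DistanceMatrix(dmat, ids=labels))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=mine.newick, schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=str(ref), schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0

    def test_too_few_taxa_rejected(self):
        f = rs.FstMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            rs.neighbor_joining_tree(f)
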