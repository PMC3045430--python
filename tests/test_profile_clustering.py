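"""Profile construction, SOTA tree clustering, per-cluster summary curves."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mrnaturnover.kinetics_core import (
    GeneKinetics,
    IntervalSolveResult,
    DecayProfile,
    TimeGrid,
    decay_profile,
    theoretical_ra,
)
from mrnaturnover.profile_clustering import (
    ProfileMatrix,
    SotaParams,
    build_profiles,
    cluster_mean_kd,
    cluster_mean_ra,
    sota_cluster,
)

GRID = TimeGrid((0, 4, 11, 16, 26, 40))


class TestBuildProfiles:
    def test_constant_gene_is_zero_row(self):
        g = GeneKinetics("g", GRID, np.ones(6), np.full(6, 10.0))
        m = build_profiles([g])
        assert m.values.tolist() == [[0.0] * 10]

    def test_tr_doubling_ra_constant(self):
        tr = np.array([1.0, 2, 2, 2, 2, 2])
        g = GeneKinetics("g", GRID, tr, np.full(6, 10.0))
        m = build_profiles([g])
        assert m.values.tolist() == [[1.0] * 5 + [0.0] * 5]

    def test_zero_t0_excluded_with_reason(self):
        g = GeneKinetics("g", GRID, np.array([0.0, 1, 1, 1, 1, 1]), np.full(6, 10.0))
        m = build_profiles([g])
        assert m.gene_ids == []
        assert "TR(t0)" in m.excluded["g"]


def _two_group_matrix():
    a = np.array([1.0, 2, 2, 1, 0, -1, 0, 1, 1, 0])
    b = np.array([-1.0, -2, -1, 0, 1, 1, 0, -1, -2, -1])
    rows = [a + 0.01 * i for i in range(5)] + [b + 0.01 * i for i in range(5)]
    ids = [f"g{i}" for i in range(10)]
    return ProfileMatrix(ids, np.array(rows)), ["A"] * 5 + ["B"] * 5


class TestSotaCluster:
    def test_identical_rows_stay_one_leaf(self):
        m = ProfileMatrix(["a", "b", "c"], np.tile([1.0, 0, 1, 0, 1, 0, 1, 0, 1, 0], (3, 1)))
        tree = sota_cluster(m, SotaParams(max_clusters=4))
        assert len([l for l in tree.leaves() if l.members]) == 1

    def test_two_group_partition_matches_exhaustive_optimum(self):
        """SOTA's 2-way split equals the best of all 2-partitions by
        within-cluster distance (brute force over assignments)."""
        m, labels = _two_group_matrix()
        tree = sota_cluster(m, SotaParams(max_clusters=2, distance="euclidean"))
        got = tree.assignments()

        x = m.values
        best, best_cost = None, np.inf
        for assign in itertools.product([0, 1], repeat=len(x) - 1):
            assign = np.array((0,) + assign)
            if len(set(assign)) < 2:
                continue
            cost = sum(
                ((x[assign == k] - x[assign == k].mean(axis=0)) ** 2).sum()
                for k in (0, 1)
            )
            if cost < best_cost:
                best, best_cost = assign, cost
        assert adjusted_rand_score(best, got[m.gene_ids].values) == 1.0
        assert adjusted_rand_score(labels, got[m.gene_ids].values) == 1.0

    def test_four_gaussian_groups_recovered(self):
        rng = np.random.default_rng(42)
        centroids = rng.normal(0, 1.5, size=(4, 10))
        rows, labels = [], []
        for k in range(4):
            for _ in range(40):
                rows.append(centroids[k] + rng.normal(0, 0.1, 10))
                labels.append(k)
        m = ProfileMatrix([f"g{i}" for i in range(len(rows))], np.array(rows))
        tree = sota_cluster(m, SotaParams(max_clusters=4))
        ari = adjusted_rand_score(labels, tree.assignments()[m.gene_ids].values)
        assert ari >= 0.95

    def test_deterministic_given_input_order(self):
        m, _ = _two_group_matrix()
        a1 = sota_cluster(m, SotaParams(max_clusters=3)).assignments()
        a2 = sota_cluster(m, SotaParams(max_clusters=3)).assignments()
        assert a1.tolist() == a2.tolist()

    def test_affine_row_transform_invariance_in_correlation_mode(self):
        m, _ = _two_group_matrix()
        rng = np.random.default_rng(0)
        scales = rng.uniform(0.5, 3.0, size=(len(m.gene_ids), 1))
        offsets = rng.uniform(-2, 2, size=(len(m.gene_ids), 1))
        m2 = ProfileMatrix(m.gene_ids, m.values * scales + offsets)
        a1 = sota_cluster(m, SotaParams(max_clusters=2)).assignments()
        a2 = sota_cluster(m2, SotaParams(max_clusters=2)).assignments()
        assert adjusted_rand_score(a1.values, a2.values) == 1.0

    def test_partition_property(self):
        m, _ = _two_group_matrix()
        tree = sota_cluster(m, SotaParams(max_clusters=3))
        member_rows = sorted(i for l in tree.leaves() for i in l.members)
        assert member_rows == list(range(len(m.gene_ids)))

    def test_leaf_centroid_is_member_mean(self):
        m, _ = _two_group_matrix()
        tree = sota_cluster(m, SotaParams(max_clusters=2))
        for leaf in tree.leaves():
            if leaf.members:
                assert leaf.centroid == pytest.approx(
                    tree.values[leaf.members].mean(axis=0)
                )

    def test_newick_export(self):
        m, _ = _two_group_matrix()
        tree = sota_cluster(m, SotaParams(max_clusters=2))
        nwk = tree.newick()
        assert nwk.endswith(";") and "c01" in nwk

    def test_invalid_max_clusters(self):
        m, _ = _two_group_matrix()
        with pytest.raises(ValueError):
            sota_cluster(m, SotaParams(max_clusters=0))


def _profile(gene_id, kd0, kd_rels):
    mids = GRID.midpoints
    return DecayProfile(
        gene_id,
        kd0,
        [IntervalSolveResult(m, kd0 * r, r, "ok") for m, r in zip(mids, kd_rels)],
    )


class TestClusterMeans:
    def _steady_tree(self):
        g1 = GeneKinetics("a", GRID, np.ones(6), np.full(6, 10.0))
        g2 = GeneKinetics("b", GRID, np.ones(6), np.full(6, 12.0))
        m = build_profiles([g1, g2])
        tree = sota_cluster(m, SotaParams(max_clusters=1))
        return tree, {"a": g1, "b": g2}

    def test_flat_kd_curves(self):
        tree, _ = self._steady_tree()
        profiles = {g: _profile(g, 0.1, [1.0] * 5) for g in ("a", "b")}
        df = cluster_mean_kd(tree, profiles)
        assert df["mean_kd_relative"].tolist() == [1.0] * 5

    def test_mean_and_se_by_hand(self):
        tree, _ = self._steady_tree()
        profiles = {"a": _profile("a", 0.1, [0.5] * 5), "b": _profile("b", 0.1, [1.5] * 5)}
        df = cluster_mean_kd(tree, profiles)
        assert df["mean_kd_relative"].tolist() == [1.0] * 5
        # SE of {0.5, 1.5}: sd = 1/sqrt(2) over sqrt(2) = 0.5
        assert df["se"].tolist() == pytest.approx([0.5] * 5)

    def test_steady_cluster_ra_curves_flat(self):
        tree, genes = self._steady_tree()
        theo = {g: theoretical_ra(genes[g]) for g in genes}
        df = cluster_mean_ra(tree, genes, theo)
        assert df["mean_ra_relative"].tolist() == pytest.approx([1.0] * 6)
        assert df["mean_ra_theoretical_relative"].tolist() == pytest.approx([1.0] * 6)

    def test_single_gene_cluster_equals_gene_curve(self):
        g = GeneKinetics("a", GRID, np.ones(6), np.array([10.0, 12, 14, 15, 15, 15]))
        other = GeneKinetics("b", GRID, 2 * np.ones(6), np.full(6, 5.0))
        m = build_profiles([g, other])
        tree = sota_cluster(m, SotaParams(max_clusters=2, distance="euclidean"))
        theo = {x.gene_id: theoretical_ra(x) for x in (g, other)}
        df = cluster_mean_ra(tree, {"a": g, "b": other}, theo)
        cl = tree.assignments()["a"]
        sub = df[df["cluster"] == cl]
        assert sub["mean_ra_relative"].tolist() == pytest.approx((g.ra / g.ra[0]).tolist())
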