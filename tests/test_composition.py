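import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from microsurv import composition as comp
from microsurv import tables_io as tio
from conftest import toy_table


class TestAgglomerate:
    def test_shared_order_sums(self):
        t = toy_table()
        out = comp.agglomerate(t, "order")
        clo = [f for f in out.feature_ids if "Clostridiales" in f]
        assert len(clo) == 1
        assert (out.counts[clo[0]] == t.counts[["F1", "F2"]].sum(axis=1)).all()

    def test_asv_rank_is_identity(self):
        t = toy_table()
        assert comp.agglomerate(t, "asv") is t

    def test_counts_conserved_without_drop(self, cohort):
        for rank in ("phylum", "genus"):
            out = comp.agglomerate(cohort.table, rank, drop_unclassified=False)
            assert (out.counts.sum(axis=1)
                    == cohort.table.counts.sum(axis=1)).all()

    def test_drop_unclassified_removes_counts(self):
        t = toy_table()
        # none of the toy features carry genus labels
        with pytest.raises(tio.TableError):
            comp.agglomerate(t, "genus", drop_unclassified=True)
        kept = comp.agglomerate(t, "genus", drop_unclassified=False)
        assert (kept.counts.sum(axis=1) == t.counts.sum(axis=1)).all()

    def test_unknown_rank_rejected(self):
        with pytest.raises(tio.TableError):
            comp.agglomerate(toy_table(), "domain")


class TestClr:
    def test_uniform_row_maps_to_zero(self):
        t = tio.FeatureTable(pd.DataFrame([[5, 5, 5]], index=["s"],
                                          columns=list("abc")))
        assert np.allclose(comp.clr_transform(t, 1.0).values, 0)

    def test_hand_value(self):
        df = pd.DataFrame([[1.0, 2.0, 4.0]], index=["s"], columns=list("abc"))
        vals = comp.clr_transform(df, pseudocount=0).values.to_numpy()[0]
        assert vals == pytest.approx([-0.693, 0.0, 0.693], abs=1e-3)

    def test_rows_sum_to_zero(self, cohort):
        clr = comp.clr_transform(cohort.table, 0.5)
        assert np.allclose(clr.values.sum(axis=1), 0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 5.0, size=(4, 8))
        a = comp.clr_transform(pd.DataFrame(x), pseudocount=0).values
        b = comp.clr_transform(pd.DataFrame(3.7 * x), pseudocount=0).values
        assert np.allclose(a, b, atol=1e-12)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(tio.TableError):
            comp.clr_transform(pd.DataFrame(index=["s"]), 0.5)


class TestRarefiedAlpha:
    def test_full_depth_is_deterministic(self):
        counts = pd.DataFrame([[5, 3, 2]], index=["s"], columns=list("abc"))
        a = comp.rarefied_alpha(tio.FeatureTable(counts), depth=10,
                                iterations=5, seed=0)
        assert a.table.loc["s", "richness"] == 3
        p = np.array([0.5, 0.3, 0.2])
        assert a.table.loc["s", "shannon"] == pytest.approx(
            -(p * np.log2(p)).sum())

    def test_single_feature_sample(self):
        counts = pd.DataFrame([[4000]], index=["s"], columns=["a"])
        a = comp.rarefied_alpha(tio.FeatureTable(counts), depth=100,
                                iterations=10, seed=0)
        assert a.table.loc["s", "richness"] == 1
        assert a.table.loc["s", "shannon"] == 0

    def test_even_two_feature_sample_near_one_bit(self):
        counts = pd.DataFrame([[5000, 5000]], index=["s"], columns=["a", "b"])
        a = comp.rarefied_alpha(tio.FeatureTable(counts), depth=2468,
                                iterations=100, seed=1)
        assert a.table.loc["s", "shannon"] == pytest.approx(1.0, abs=0.02)

    def test_matches_independent_high_iteration_oracle(self):
        """Mean over 100 iterations agrees with a 10x longer independent
        rarefaction run within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(0, 400, size=(5, 12)),
                              index=[f"s{i}" for i in range(5)],
                              columns=[f"f{i}" for i in range(12)])
        counts += 30  # keep totals comfortably above depth
        table = tio.FeatureTable(counts)
        depth = 200
        a = comp.rarefied_alpha(table, depth, iterations=100, seed=2)

        oracle_rng = np.random.default_rng(12345)
        for sid in table.sample_ids:
            row = table.counts.loc[sid].to_numpy()
            sh = np.empty(1000)
            for k in range(1000):
                sub = oracle_rng.multivariate_hypergeometric(row, depth)
                p = sub[sub > 0] / depth
                sh[k] = -(p * np.log2(p)).sum()
            se = sh.std(ddof=1) / np.sqrt(100)
            assert abs(a.table.loc[sid, "shannon"] - sh.mean()) < 3 * se + 1e-9

    def test_nonpositive_depth_rejected(self, cohort):
        with pytest.raises(tio.TableError):
            comp.rarefied_alpha(cohort.table, 0)

    def test_shannon_bounded_by_log_richness(self, cohort):
        a = comp.rarefied_alpha(cohort.table, 500, iterations=10, seed=3)
        assert (a.table["shannon"]
                <= np.log2(np.maximum(a.table["richness"], 1)) + 1e-9).all()


class TestJsd:
    def test_identical_rows_zero(self):
        df = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert comp.jsd_matrix(df).values.loc["a", "b"] == pytest.approx(0, abs=1e-12)

    def test_disjoint_supports_one(self):
        df = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert comp.jsd_matrix(df).values.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_value(self):
        df = pd.DataFrame([[1.0, 0.0], [0.5, 0.5]], index=["a", "b"])
        assert comp.jsd_matrix(df).values.loc["a", "b"] == pytest.approx(
            0.3113, abs=1e-4)

    def test_all_zero_row_rejected(self):
        df = pd.DataFrame([[0, 0], [1, 1]], index=["a", "b"])
        with pytest.raises(tio.TableError):
            comp.jsd_matrix(df)

    def test_sqrt_jsd_triangle_inequality(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(6), size=3000).reshape(1000, 3, 6)
        for triple in p:
            d = comp.jsd_matrix(pd.DataFrame(triple)).values.to_numpy()
            r = np.sqrt(d)
            assert r[0, 1] <= r[0, 2] + r[2, 1] + 1e-10
            assert r[0, 2] <= r[0, 1] + r[1, 2] + 1e-10
            assert r[1, 2] <= r[1, 0] + r[0, 2] + 1e-10


class TestPcoa:
    def test_line_recovers_distances(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        d = squareform(pdist(pts))
        dm = comp.DistanceMatrix(pd.DataFrame(d, index=list("abcd"),
                                              columns=list("abcd")))
        res = comp.pcoa(dm, k=2)
        assert (res.eigenvalues > 1e-8).sum() == 1
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)

    def test_plane_recovers_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 2))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(15)]
        dm = comp.DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))
        res = comp.pcoa(dm, k=2)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(10)]
        dm = comp.DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))
        ours = comp.pcoa(dm, k=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, ids),
                                          method="eigh")
        assert np.allclose(np.sort(ours.eigenvalues)[::-1][:3],
                           ref.eigvals.to_numpy()[:3], atol=1e-8)
        assert np.allclose(np.abs(ours.coordinates.to_numpy()),
                           np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-6)

    def test_centroid_at_origin_and_k_guard(self, cohort):
        dm = comp.jsd_matrix(cohort.table)
        res = comp.pcoa(dm, k=2)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-8)
        with pytest.raises(tio.TableError):
            comp.pcoa(dm, k=len(dm.ids))

    def test_sign_convention_deterministic(self, cohort):
        dm = comp.jsd_matrix(cohort.table)
        a = comp.pcoa(dm, k=2).coordinates
        b = comp.pcoa(dm, k=2).coordinates
        pd.testing.assert_frame_equal(a, b)
        first_nonzero = a.to_numpy()[np.abs(a.to_numpy()[:, 0]) > 1e-12, 0][0]
        assert first_nonzero > 0
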