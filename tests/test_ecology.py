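"""Ecology stage: filtering, diversity closed forms, ordination, ANOSIM,
clustering tree, shared-feature counts.  Independent oracles: hand-derived
formula values, classical MDS eigendecomposition, scikit-bio."""

import math

import numpy as np
import pandas as pd
import pytest

import keloidomics as k
from keloidomics import ecology
from keloidomics.tables import AbundanceTable, SampleMetadata, ValidationError


def _table(arr, samples=None, features=None):
    arr = np.asarray(arr, float)
    samples = samples or [f"s{i+1}" for i in range(arr.shape[0])]
    features = features or [f"f{j+1}" for j in range(arr.shape[1])]
    return AbundanceTable(pd.DataFrame(arr, index=samples, columns=features))


class TestPrevalenceFilter:
    def test_all_zero_feature_removed(self, small_cohort):
        tab, _, _ = small_cohort
        df = tab.data.copy()
        df["dead"] = 0.0
        out = ecology.prevalence_filter(AbundanceTable(df))
        assert "dead" not in out.feature_ids

    def test_boundary_inclusive_one_of_ten(self):
        # 10 samples, feature exactly 1e-4 in exactly 1 sample: ceil(0.1*10)=1
        arr = np.full((10, 2), 0.5)
        arr[:, 1] = 0.0
        arr[0, 1] = 1e-4
        out = ecology.prevalence_filter(_table(arr), 1e-4, 0.10)
        assert out.feature_ids == ["f1", "f2"]

    def test_matches_brute_force_count(self, study_cohort):
        tab, _, _ = study_cohort
        out = ecology.prevalence_filter(tab, 1e-3, 0.25)
        need = math.ceil(0.25 * len(tab.sample_ids))
        expected = [f for f in tab.feature_ids
                    if int((tab.data[f] >= 1e-3).sum()) >= need]
        assert out.feature_ids == expected

    def test_no_renormalization(self):
        arr = np.array([[0.6, 0.4 - 1e-6, 1e-6]])
        arr = np.tile(arr, (10, 1))
        out = ecology.prevalence_filter(_table(arr), 1e-4, 0.10)
        assert out.data.shape[1] == 2
        assert out.data.iloc[0].sum() < 1.0  # original fractions kept


class TestAlphaDiversity:
    def test_closed_forms(self):
        res = ecology.alpha_diversity(_table([[0.5, 0.5]]))
        assert res.table["shannon"].iloc[0] == pytest.approx(math.log(2))
        assert res.table["simpson"].iloc[0] == pytest.approx(0.5)

    def test_chao1_hand_value(self):
        counts = np.array([[1, 1, 2, 5]])
        tab = _table(counts / counts.sum())
        res = ecology.alpha_diversity(tab, counts=counts)
        assert res.table["chao1"].iloc[0] == pytest.approx(4.5)

    def test_uniform_is_maximal_shannon(self):
        kk = 7
        res = ecology.alpha_diversity(_table([np.full(kk, 1 / kk)]))
        assert res.table["shannon"].iloc[0] == pytest.approx(math.log(kk))

    def test_matches_skbio(self, rng):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = rng.integers(0, 20, size=(5, 30))
        counts[:, 0] = 1  # ensure non-empty
        tab = _table(counts / counts.sum(axis=1, keepdims=True))
        res = ecology.alpha_diversity(tab, counts=counts)
        for i in range(5):
            assert res.table["chao1"].iloc[i] == pytest.approx(
                skbio_alpha.chao1(counts[i], bias_corrected=True))
            assert res.table["shannon"].iloc[i] == pytest.approx(
                skbio_alpha.shannon(counts[i], base=math.e))

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValidationError, match="s2"):
            ecology.alpha_diversity(_table([[0.5, 0.5], [0.0, 0.0]]))


class TestBrayCurtis:
    def test_identical_zero_disjoint_one(self):
        d = ecology.bray_curtis(_table([[0.2, 0.8, 0.0], [0.2, 0.8, 0.0],
                                        [0.0, 0.0, 1.0]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] == pytest.approx(1.0)

    def test_hand_value(self):
        d = ecology.bray_curtis(_table([[0.2, 0.8], [0.4, 0.6]]))
        assert d.iloc[0, 1] == pytest.approx(0.2)

    def test_range_and_symmetry(self, small_cohort):
        tab, _, _ = small_cohort
        d = ecology.bray_curtis(tab)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.all((arr >= 0) & (arr <= 1))
        assert np.allclose(np.diag(arr), 0)


class TestPCoA:
    def test_collinear_points_recover_spacing(self):
        pts = np.array([0.0, 1.0, 3.0])
        d = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]))
        res = ecology.pcoa(d, n_axes=1)
        ax = res.coordinates.iloc[:, 0].to_numpy()
        gaps = np.diff(np.sort(ax))
        assert np.allclose(np.sort(gaps), [1.0, 2.0], atol=1e-8)

    def test_equals_classical_mds_on_euclidean(self, rng):
        x = rng.normal(size=(8, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        res = ecology.pcoa(pd.DataFrame(d), n_axes=3)
        # oracle: direct eigendecomposition of the centered Gram matrix
        xc = x - x.mean(axis=0)
        g = xc @ xc.T
        ev = np.sort(np.linalg.eigvalsh(g))[::-1][:3]
        assert np.allclose(np.sort(res.eigenvalues)[::-1], ev, atol=1e-8)
        b = res.coordinates.to_numpy()
        assert np.allclose(b @ b.T, g, atol=1e-8)

    def test_eigenvalue_sum_equals_trace(self, small_cohort):
        tab, _, _ = small_cohort
        d = ecology.bray_curtis(tab)
        dm = d.to_numpy()
        n = dm.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dm**2) @ j
        evals = np.linalg.eigvalsh(b)
        assert np.trace(b) == pytest.approx(evals.sum())

    def test_zero_distance_zero_coords(self):
        d = pd.DataFrame(np.zeros((2, 2)))
        res = ecology.pcoa(d, n_axes=1)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_matches_skbio(self, small_cohort):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        tab, _, _ = small_cohort
        d = ecology.bray_curtis(tab)
        res = ecology.pcoa(d, n_axes=2)
        import skbio
        ref = skbio_ord.pcoa(skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
                             number_of_dimensions=2)
        assert np.allclose(np.abs(res.coordinates.to_numpy()),
                           np.abs(ref.samples.to_numpy()), atol=1e-6)


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        arr = np.vstack([np.tile([1.0, 0.0], (4, 1)) + np.arange(4)[:, None] * 1e-4,
                         np.tile([0.0, 1.0], (4, 1)) + np.arange(4)[:, None] * 1e-4])
        tab = _table(arr / arr.sum(axis=1, keepdims=True))
        d = ecology.bray_curtis(tab)
        r, p = ecology.anosim(d, ["A"] * 4 + ["B"] * 4, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_exchangeable_r_near_zero(self, rng):
        rs = []
        for i in range(30):
            x = rng.normal(size=(12, 4))
            d = pd.DataFrame(np.abs(x[:, None] - x[None, :]).sum(-1))
            r, _ = ecology.anosim(d, ["A"] * 6 + ["B"] * 6, n_perm=99, seed=i)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    def test_matches_skbio_r_statistic(self, small_cohort):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        tab, meta, _ = small_cohort
        d = ecology.bray_curtis(tab)
        r, _ = ecology.anosim(d, meta.group, n_perm=99, seed=0)
        import skbio
        ref = skbio_dist.anosim(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            meta.group.loc[list(d.index)].to_numpy(), permutations=99)
        assert r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_low_perm_rejected(self, small_cohort):
        tab, meta, _ = small_cohort
        d = ecology.bray_curtis(tab)
        with pytest.raises(ValueError):
            ecology.anosim(d, meta.group, n_perm=50)


class TestUpgma:
    def test_three_leaf_topology(self):
        d = pd.DataFrame([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
                         index=list("ABC"), columns=list("ABC"))
        nwk = ecology.upgma_tree(d)
        assert nwk.startswith("((A:0.05,B:0.05):0.4,C:0.45)")

    def test_two_samples_cherry(self):
        d = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=["x", "y"], columns=["x", "y"])
        assert ecology.upgma_tree(d) == "(x:0.15,y:0.15);"

    def test_ties_deterministic(self):
        d = pd.DataFrame(0.5, index=list("ABCD"), columns=list("ABCD"))
        np.fill_diagonal(d.values, 0.0)
        assert ecology.upgma_tree(d) == ecology.upgma_tree(d)
        # lexicographically smallest pair (A,B) merges first
        assert ecology.upgma_tree(d).startswith("(((A:0.25,B:0.25)")

    def test_leaves_match_samples_and_ultrametric(self, small_cohort):
        dendropy = pytest.importorskip("dendropy")
        tab, _, _ = small_cohort
        d = ecology.bray_curtis(tab)
        tree = dendropy.Tree.get(data=ecology.upgma_tree(d), schema="newick")
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        assert leaves == set(tab.sample_ids)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert np.allclose(depths, depths[0], atol=1e-9)


class TestSharedFeatures:
    def test_constructed_venn_counts(self):
        # 3 shared + 2 MK-only + 1 NS-only species
        arr = np.array([
            # f1 f2 f3 shared, f4 f5 MK-only, f6 NS-only
            [1, 1, 1, 1, 1, 0],   # MK sample
            [1, 1, 1, 1, 1, 0],   # MK sample
            [1, 1, 1, 0, 0, 1],   # NS sample
            [1, 1, 1, 0, 0, 1],   # NS sample
        ], dtype=float)
        tab = _table(arr / arr.sum(axis=1, keepdims=True))
        meta = SampleMetadata(pd.Series(["MK", "MK", "NS", "NS"],
                                        index=["s1", "s2", "s3", "s4"]))
        out = ecology.shared_feature_counts(tab, meta)
        row = out.loc["unknown"]
        assert (row["shared"], row["MK_only"], row["NS_only"]) == (3, 2, 1)

    def test_absent_feature_counted_nowhere(self):
        arr = np.array([[1.0, 0.0], [1.0, 0.0]])
        tab = _table(arr)
        meta = SampleMetadata(pd.Series(["MK", "NS"], index=["s1", "s2"]))
        out = ecology.shared_feature_counts(tab, meta)
        assert out["shared"].sum() + out["MK_only"].sum() + out["NS_only"].sum() == 1
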