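"""Mega sites, imputation, simplex deconvolution, and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from labs_cfdna import (
    ParameterError,
    ValidationError,
    aggregate_sample_to_mega_sites,
    build_mega_sites,
    deconvolve,
    group_compare,
    knn_impute,
    marker_region_levels,
    simulate_sample_calls,
)
from labs_cfdna.methylome import CALL_COLUMNS

from _oracles import simplex_grid_search


def _ref(rows, index=None, columns=("t1", "t2")):
    return pd.DataFrame(rows, index=index, columns=list(columns))


class TestMarkerRegionLevels:
    def test_pooling_and_missing(self):
        calls = pd.DataFrame(
            [("chr1", 10, "+", "CpG", 2, 2), ("chr1", 20, "+", "CpG", 1, 3)],
            columns=CALL_COLUMNS,
        )
        markers = pd.DataFrame(
            [("chr1", 0, 100, "m1", "."), ("chr1", 200, 300, "m2", ".")],
            columns=["chrom", "start0", "end0", "name", "strand"],
        )
        levels = marker_region_levels(calls, markers)
        assert levels["m1"] == pytest.approx(3 / 8)
        assert np.isnan(levels["m2"])


class TestMegaSites:
    def test_toy_clusters_drop_singleton(self):
        # two tight 3-site clusters plus one distant outlier; k=3 makes the
        # outlier a singleton which is removed
        rows = [[0.0, 1.0], [0.01, 0.99], [0.02, 1.0],
                [1.0, 0.0], [0.99, 0.02], [1.0, 0.01],
                [0.5, 0.5]]
        ref = _ref(rows, index=[f"s{i}" for i in range(7)])
        mega = build_mega_sites(ref, k=3)
        assert len(mega.groups) == 2
        assert all(len(m) == 3 for m in mega.groups.values())
        for _, members in mega.groups.items():
            np.testing.assert_allclose(
                mega.reference.loc[:, "t1"].sort_values(),
                [0.01, 0.996666666], atol=1e-6,
            )
            break

    def test_all_singletons_empty_with_warning(self):
        ref = _ref([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
        with pytest.warns(UserWarning):
            mega = build_mega_sites(ref, k=3)
        assert len(mega.groups) == 0

    def test_group_sizes_at_least_two(self, small_atlas):
        mega = build_mega_sites(small_atlas.to_frame(), k=32)
        assert (mega.sizes >= 2).all()

    def test_k_exceeding_sites_rejected(self):
        with pytest.raises(ParameterError):
            build_mega_sites(_ref([[0.1, 0.9]]), k=2)


class TestAggregate:
    def test_pooled_counts(self):
        calls = pd.DataFrame(
            [("chr1", 10, "+", "CpG", 1, 1), ("chr1", 20, "+", "CpG", 3, 1)],
            columns=CALL_COLUMNS,
        )
        from labs_cfdna.deconv import MegaSiteSet

        mega = MegaSiteSet(
            groups={"g1": [("chr1", 10), ("chr1", 20)], "g2": [("chr1", 99)]},
            reference=_ref([[0.5, 0.5], [0.1, 0.9]], index=["g1", "g2"]),
        )
        vec = aggregate_sample_to_mega_sites(calls, mega)
        assert vec["g1"] == pytest.approx(4 / 6)
        assert np.isnan(vec["g2"])

    def test_pure_type_matches_reference_column(self, small_atlas):
        mega = build_mega_sites(small_atlas.to_frame(), k=32)
        w = np.zeros(5)
        w[2] = 1.0
        calls = simulate_sample_calls(small_atlas, w, coverage_mean=200, seed=3)
        vec = aggregate_sample_to_mega_sites(calls, mega)
        ref_col = mega.reference.iloc[:, 2]
        # read-pooled aggregation vs site-mean reference: agreement within
        # binomial noise at 200x over >=2-site groups
        assert (vec - ref_col).abs().max() < 0.08

    def test_commutes_with_pooling(self, small_atlas, rng):
        """Aggregating = pooling reads over the union of member sites."""
        mega = build_mega_sites(small_atlas.to_frame(), k=20)
        calls = simulate_sample_calls(small_atlas, np.full(5, 0.2), coverage_mean=30, seed=9)
        vec = aggregate_sample_to_mega_sites(calls, mega)
        indexed = calls.set_index(["chrom", "pos0"])
        for label, members in mega.groups.items():
            sub = indexed.loc[[m for m in members if m in indexed.index]]
            total = sub["n_meth"].sum() + sub["n_unmeth"].sum()
            if total:
                assert vec[label] == pytest.approx(sub["n_meth"].sum() / total)


class TestKnnImpute:
    def test_identity_without_missing(self, rng):
        m = pd.DataFrame(rng.random((8, 4)))
        pd.testing.assert_frame_equal(knn_impute(m, k=3), m)

    def test_k1_copies_nearest_feature(self):
        m = pd.DataFrame(
            {"s1": [0.1, 0.11, 0.9], "s2": [0.2, 0.21, 0.8], "s3": [np.nan, 0.3, 0.7]},
            index=["A", "B", "C"],
        )
        out = knn_impute(m, k=1)
        # feature B is nearest to A on (s1, s2); A[s3] takes B's value
        assert out.loc["A", "s3"] == pytest.approx(0.3)

    def test_imputed_within_donor_range(self, rng):
        m = pd.DataFrame(rng.random((20, 6)))
        mask = rng.random((20, 6)) < 0.2
        m = m.mask(mask)
        out = knn_impute(m, k=5)
        assert out.notna().all().all()
        assert (out.to_numpy() >= np.nanmin(m.to_numpy()) - 1e-12).all()
        assert (out.to_numpy() <= np.nanmax(m.to_numpy()) + 1e-12).all()

    def test_entirely_missing_rejected(self):
        with pytest.raises(ValidationError):
            knn_impute(pd.DataFrame({"a": [np.nan], "b": [np.nan]}))


class TestDeconvolve:
    def test_identity_reference(self):
        est = deconvolve(pd.Series([0.3, 0.7]), _ref([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(est.proportions, [0.3, 0.7], atol=1e-6)

    def test_exact_two_type_solution(self):
        est = deconvolve(pd.Series([0.3, 0.65]), _ref([[0.9, 0.1], [0.2, 0.8]]))
        np.testing.assert_allclose(est.proportions, [0.25, 0.75], atol=1e-6)
        assert est.residual == pytest.approx(0.0, abs=1e-9)

    def test_on_simplex_and_beats_vertices(self, rng):
        for _ in range(10):
            R = rng.random((8, 3))
            y = rng.random(8)
            est = deconvolve(pd.Series(y), pd.DataFrame(R))
            w = est.proportions.to_numpy()
            assert (w >= -1e-9).all() and w.sum() == pytest.approx(1.0, abs=1e-6)
            obj = np.sum((R @ w - y) ** 2)
            for v in range(3):
                e = np.zeros(3)
                e[v] = 1.0
                assert obj <= np.sum((R @ e - y) ** 2) + 1e-9

    @pytest.mark.parametrize("n_types", [2, 3, 4])
    def test_matches_grid_search_oracle(self, n_types, rng):
        for _ in range(3):
            R = rng.random((10, n_types))
            w_true = rng.dirichlet(np.ones(n_types))
            y = R @ w_true + rng.normal(0, 0.02, 10)
            est = deconvolve(pd.Series(y), pd.DataFrame(R))
            w_grid = simplex_grid_search(R, y, step=1e-4 if n_types == 2 else 0.01)
            np.testing.assert_allclose(est.proportions, w_grid, atol=1e-3)

    def test_missing_features_dropped(self):
        y = pd.Series([0.3, np.nan, 0.65])
        R = _ref([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        est = deconvolve(y, R)
        assert est.n_features_used == 2
        np.testing.assert_allclose(est.proportions, [0.25, 0.75], atol=1e-6)

    def test_too_few_features_rejected(self):
        with pytest.raises(ValidationError):
            deconvolve(pd.Series([0.5]), _ref([[0.9, 0.1]]))

    def test_recovery_error_decreases_with_coverage(self, rng):
        R = pd.DataFrame(rng.random((26, 6)))
        errors = {}
        for cov in (10, 50, 200):
            errs = []
            for _ in range(40):
                w = rng.dirichlet(np.ones(6))
                p = np.clip(R.to_numpy() @ w, 0, 1)
                reads = np.maximum(rng.poisson(cov, 26), 1)
                y = rng.binomial(reads, p) / reads
                est = deconvolve(pd.Series(y, index=R.index), R)
                errs.append(np.abs(est.proportions.to_numpy() - w).mean())
            errors[cov] = np.mean(errs)
        assert errors[10] > errors[50] > errors[200]


class TestGroupCompare:
    def test_exact_rank_sum(self):
        assert group_compare([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert group_compare([2, 2, 2], [2, 2, 2]) == 1.0

    def test_label_swap_symmetry(self, rng):
        x, y = rng.random(8), rng.random(10)
        assert group_compare(x, y) == pytest.approx(group_compare(y, x))

    def test_welch_alternative(self):
        p = group_compare([1.0, 1.1, 0.9], [2.0, 2.1, 1.9], test="ttest")
        assert p < 0.01
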