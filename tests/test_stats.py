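"""Count-matrix preparation, diversity, group tests and correlation screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

from straintrace.formats import SampleMeta
from straintrace.stats import (
    CountMatrix,
    FilterParams,
    alpha_diversity,
    benjamini_hochberg,
    bray_curtis,
    group_compare,
    prepare_feature_matrix,
    spearman_bh,
)

from helpers import brute_bh, brute_bray_curtis, brute_simpson


def _matrix(values, features=None, samples=None, kind="reads"):
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=features, columns=samples), kind=kind)


def _meta_for(samples_per_ind):
    mapping = {}
    for ind, cols in samples_per_ind.items():
        for c in cols:
            mapping[c] = ind
    return mapping


class TestPrepareFeatureMatrix:
    def test_median_over_three_visits(self):
        cm = _matrix([[10, 20, 30]], samples=["v1", "v2", "v3"])
        out = prepare_feature_matrix(
            cm, _meta_for({"I1": ["v1", "v2", "v3"]}), FilterParams(min_count=1)
        )
        assert out.data.loc["f0", "I1"] == 20

    def test_even_visit_count_uses_mean_of_central_values(self):
        cm = _matrix([[10, 20, 30, 100]], samples=["v1", "v2", "v3", "v4"])
        out = prepare_feature_matrix(
            cm, _meta_for({"I1": ["v1", "v2", "v3", "v4"]}), FilterParams(min_count=1)
        )
        assert out.data.loc["f0", "I1"] == 25

    def test_reads_prevalence_filter_boundary(self):
        # >= 20 reads in 2/10 individuals -> dropped; in 3/10 -> kept
        vals = np.zeros((2, 10))
        vals[0, :2] = 25
        vals[1, :3] = 25
        cm = _matrix(vals, samples=[f"i{j}" for j in range(10)])
        meta = _meta_for({f"I{j}": [f"i{j}"] for j in range(10)})
        out = prepare_feature_matrix(cm, meta, FilterParams(min_count=20, min_fraction=0.25))
        assert list(out.data.index) == ["f1"]

    def test_spectra_default_threshold_is_ten(self):
        vals = np.zeros((1, 10))
        vals[0, :3] = 12
        cm = _matrix(vals, samples=[f"i{j}" for j in range(10)], kind="spectra")
        meta = _meta_for({f"I{j}": [f"i{j}"] for j in range(10)})
        out = prepare_feature_matrix(cm, meta)
        assert list(out.data.index) == ["f0"]

    def test_median_permutation_invariant_over_visits(self, rng):
        vals = rng.integers(0, 100, size=(5, 6)).astype(float)
        cols = [f"v{j}" for j in range(6)]
        cm1 = _matrix(vals, samples=cols)
        perm = [3, 0, 5, 1, 4, 2]
        cm2 = CountMatrix(cm1.data[[cols[j] for j in perm]])
        meta = _meta_for({"I1": cols[:3], "I2": cols[3:]})
        p = FilterParams(min_count=1, min_fraction=0.25)
        out1 = prepare_feature_matrix(cm1, meta, p)
        out2 = prepare_feature_matrix(cm2, meta, p)
        pd.testing.assert_frame_equal(out1.data[["I1", "I2"]], out2.data[["I1", "I2"]])

    @given(
        min_count=hst.integers(min_value=1, max_value=40),
        min_fraction=hst.floats(min_value=0.05, max_value=1.0),
    )
    def test_filter_monotonicity(self, min_count, min_fraction):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 60, size=(8, 6)).astype(float)
        cm = _matrix(vals, samples=[f"i{j}" for j in range(6)])
        meta = _meta_for({f"I{j}": [f"i{j}"] for j in range(6)})
        base = prepare_feature_matrix(cm, meta, FilterParams(1, 0.05))
        tighter = prepare_feature_matrix(
            cm, meta, FilterParams(min_count, min_fraction)
        )
        assert set(tighter.data.index) <= set(base.data.index)

    def test_sample_without_metadata_is_an_error(self):
        cm = _matrix([[1, 2]], samples=["a", "b"])
        with pytest.raises(ValueError, match="metadata"):
            prepare_feature_matrix(cm, {"a": "I1"}, FilterParams(min_count=1))


class TestAlphaDiversity:
    def test_two_even_species(self):
        rel = pd.DataFrame({"s1": [0.5, 0.5]})
        out = alpha_diversity(rel)
        assert out.loc["s1", "richness"] == 2
        assert out.loc["s1", "simpson"] == pytest.approx(0.5)

    def test_single_species_has_zero_diversity(self):
        rel = pd.DataFrame({"s1": [1.0, 0.0]})
        out = alpha_diversity(rel)
        assert out.loc["s1", "richness"] == 1
        assert out.loc["s1", "simpson"] == pytest.approx(0.0)

    def test_arithmetic_example(self):
        rel = pd.DataFrame({"s1": [0.9, 0.1]})
        assert alpha_diversity(rel).loc["s1", "simpson"] == pytest.approx(0.18)

    def test_all_zero_sample_flagged(self):
        rel = pd.DataFrame({"s1": [0.0, 0.0], "s2": [0.4, 0.6]})
        out = alpha_diversity(rel)
        assert not out.loc["s1", "defined"] and np.isnan(out.loc["s1", "simpson"])
        assert out.loc["s2", "defined"]

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError, match="normalised"):
            alpha_diversity(pd.DataFrame({"s1": [0.7, 0.7]}))

    def test_matches_brute_force_and_skbio(self, rng):
        from skbio.diversity.alpha import simpson as skbio_simpson

        counts = rng.integers(0, 50, size=(10, 10)).astype(float)
        counts[0, 0] += 1  # avoid an all-zero first column
        rel = counts / counts.sum(axis=0)
        out = alpha_diversity(pd.DataFrame(rel))
        for j in range(10):
            assert out.iloc[j]["simpson"] == pytest.approx(brute_simpson(rel[:, j]), abs=1e-12)
            assert out.iloc[j]["simpson"] == pytest.approx(
                skbio_simpson(counts[:, j]), abs=1e-9
            )


class TestBrayCurtis:
    def test_identical_vectors_have_zero_distance(self):
        cm = _matrix([[3, 3], [1, 1]])
        assert bray_curtis(cm).iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_have_distance_one(self):
        cm = _matrix([[5, 0], [0, 7]])
        assert bray_curtis(cm).iloc[0, 1] == pytest.approx(1.0)

    def test_arithmetic_example(self):
        cm = _matrix([[1, 0], [1, 2]])
        assert bray_curtis(cm).iloc[0, 1] == pytest.approx(0.5)

    def test_two_all_zero_samples_flagged_nan(self):
        cm = _matrix([[0, 0, 1], [0, 0, 2]])
        dm = bray_curtis(cm)
        assert np.isnan(dm.iloc[0, 1])
        assert dm.iloc[0, 0] == 0.0

    def test_matches_brute_force_on_random_matrices(self, rng):
        vals = rng.integers(0, 30, size=(10, 10)).astype(float) + 0.5
        dm = bray_curtis(_matrix(vals))
        for i in range(10):
            for j in range(10):
                expect = 0.0 if i == j else brute_bray_curtis(vals[:, i], vals[:, j])
                assert dm.iloc[i, j] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(dm.values, dm.values.T)


class TestGroupCompare:
    def test_identical_multisets_give_p_one(self):
        res = group_compare([1, 2, 3], [1, 2, 3])
        assert res.testable and res.p == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact_p(self):
        res = group_compare([1, 2, 3], [4, 5, 6])
        assert res.U == 0 and res.p == pytest.approx(0.1)  # 2/20 arrangements

    def test_symmetry_under_group_swap(self):
        a, b = [1, 5, 7, 9], [2, 3, 4, 10]
        r1 = group_compare(a, b)
        r2 = group_compare(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert r1.U + r2.U == len(a) * len(b)

    def test_small_group_not_testable(self):
        assert not group_compare([1], [2, 3]).testable

    def test_large_groups_use_tie_corrected_approximation(self, rng):
        a = rng.integers(0, 5, size=30).tolist()
        b = rng.integers(0, 5, size=30).tolist()
        res = group_compare(a, b)
        assert res.testable and 0 <= res.p <= 1


class TestSpearmanBH:
    def test_monotone_transform_gives_rho_one(self):
        x = pd.DataFrame([[1, 2, 3, 4, 5]], index=["a"], columns=list("vwxyz"))
        y = pd.DataFrame([[1, 4, 9, 16, 25]], index=["b"], columns=list("vwxyz"))
        edges, _ = spearman_bh(x, y, rho_min=0.9, alpha=0.05)
        assert len(edges) == 1 and edges[0].rho == pytest.approx(1.0)

    def test_bh_step_up_by_hand(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        ps = [0.001, 0.01, 0.02, 0.8]
        assert benjamini_hochberg(ps) == pytest.approx(brute_bh(ps))

    def test_bh_adjusted_dominates_raw_and_is_bounded(self, rng):
        ps = rng.uniform(0, 1, size=40)
        adj = benjamini_hochberg(ps)
        assert np.all(adj >= ps - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rho_below_threshold_yields_no_edge(self, rng):
        n = 40
        base = rng.normal(size=n)
        x = pd.DataFrame([base], index=["a"], columns=[f"s{i}" for i in range(n)])
        noisy = 0.5 * base + rng.normal(size=n)
        y = pd.DataFrame([noisy], index=["b"], columns=[f"s{i}" for i in range(n)])
        from scipy.stats import spearmanr

        rho, _ = spearmanr(base, noisy)
        assert abs(rho) < 0.7  # seeded instance sits below the threshold
        edges, _ = spearman_bh(x, y, rho_min=0.7, alpha=0.5)
        assert edges == []

    def test_constant_feature_excluded_with_flag(self):
        x = pd.DataFrame([[1, 1, 1, 1]], index=["const"], columns=list("wxyz"))
        y = pd.DataFrame([[1, 2, 3, 4]], index=["b"], columns=list("wxyz"))
        edges, excluded = spearman_bh(x, y, rho_min=0.0, alpha=1.0)
        assert edges == [] and excluded[0][:2] == ("const", "b")

    def test_fewer_than_four_shared_samples_rejected(self):
        x = pd.DataFrame([[1, 2, 3]], index=["a"], columns=list("xyz"))
        y = pd.DataFrame([[1, 2, 3]], index=["b"], columns=list("xyz"))
        with pytest.raises(ValueError, match="4 shared"):
            spearman_bh(x, y)


class TestCountMatrixInvariants:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _matrix([[-1, 2]])

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["f", "f"], columns=["a", "b"])
        with pytest.raises(ValueError, match="unique"):
            CountMatrix(df)

    def test_relative_abundance_sums_to_one(self, rng):
        cm = _matrix(rng.integers(1, 20, size=(4, 3)).astype(float))
        assert cm.relative_abundance().sum(axis=0).values == pytest.approx([1, 1, 1])
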