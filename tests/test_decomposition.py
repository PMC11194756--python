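import numpy as np
import pandas as pd
import pytest

from spotica import (
    NormalizedMatrix,
    component_kurtosis,
    contributor_genes,
    filter_by_kurtosis,
    merge_components,
    run_ica,
    sign_correct,
)
from spotica.decomposition import _plain_kurtosis


def as_normalized(X):
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    return NormalizedMatrix(
        residuals=X,
        gene_ids=np.array([f"g{j}" for j in range(g)], dtype=object),
        spot_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        model_params=pd.DataFrame(index=[f"g{j}" for j in range(g)]),
        clip_bound=np.inf,
    )


def mixture_fixture(seed=0, n_sources=3, n_mix=50, n_obs=2000):
    """Super-Gaussian gene-side sources mixed into spot-side features."""
    rng = np.random.default_rng(seed)
    S = rng.laplace(size=(n_sources, n_obs)) ** 3  # heavy-tailed sources
    S /= S.std(axis=1, keepdims=True)
    A = rng.normal(size=(n_mix, n_sources))
    X = A @ S + 0.01 * rng.normal(size=(n_mix, n_obs))
    return as_normalized(X), S, A


def best_abs_corr(recovered, truth):
    """|r| of the best recovered match per true source (permutation/sign free)."""
    out = []
    for t in truth:
        rs = [abs(np.corrcoef(t, r)[0, 1]) for r in recovered]
        out.append(max(rs))
    return np.array(out)


class TestRunIca:
    def test_blind_source_recovery(self):
        nm, S_true, _ = mixture_fixture()
        d = run_ica(nm, k=3, seed=0)
        r = best_abs_corr(d.sources, S_true)
        assert np.all(r >= 0.95)

    def test_rank_one_data_single_component_reconstructs(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.normal(size=30), rng.laplace(size=400))
        d = run_ica(as_normalized(X), k=1, seed=0)
        rel = np.abs(d.reconstruction() - X).max() / np.abs(X).max()
        assert rel <= 1e-6

    def test_same_seed_reproducible(self):
        nm, _, _ = mixture_fixture()
        d1 = run_ica(nm, k=3, seed=42)
        d2 = run_ica(nm, k=3, seed=42)
        np.testing.assert_allclose(d1.sources, d2.sources, atol=1e-10)
        np.testing.assert_allclose(d1.weights, d2.weights, atol=1e-10)

    def test_k_larger_than_data_errors(self):
        nm, _, _ = mixture_fixture(n_mix=10, n_obs=50)
        with pytest.raises(ValueError, match="smaller k"):
            run_ica(nm, k=20, seed=0)

    @pytest.mark.parametrize("method", ["infomax", "jade"])
    def test_alternative_backends_recover_sources(self, method):
        nm, S_true, _ = mixture_fixture(n_obs=1000)
        d = run_ica(nm, k=3, seed=0, method=method, max_iter=200)
        r = best_abs_corr(d.sources, S_true)
        assert np.all(r >= 0.9)

    def test_overdecomposition_keeps_super_gaussian_sources(self):
        # more components than true sparse sources: kurtosis>3 count >= truth
        nm, S_true, _ = mixture_fixture(n_sources=4, n_mix=40)
        d = run_ica(nm, k=10, seed=0)
        assert int((d.kurtosis > 3).sum()) >= 4


class TestKurtosis:
    def test_two_point_symmetric_distribution(self):
        v = np.array([1.0, -1.0] * 50)
        assert _plain_kurtosis(v) == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_limit(self):
        v = np.random.default_rng(0).normal(size=100_000)
        assert _plain_kurtosis(v) == pytest.approx(3.0, abs=0.1)

    def test_single_spike_vector(self):
        v = np.array([0.0] * 9 + [10.0])
        assert _plain_kurtosis(v) == pytest.approx(657 / 81, abs=1e-12)

    def test_matches_direct_moment_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            v = rng.laplace(size=500)
            c = v - v.mean()
            oracle = np.mean(c**4) / np.mean(c**2) ** 2
            assert abs(_plain_kurtosis(v) - oracle) <= 1e-10

    def test_zero_variance_component_flagged(self):
        nm, _, _ = mixture_fixture(n_obs=300)
        d = run_ica(nm, k=3, seed=0)
        d.sources[1] = 1.0  # constant loadings
        component_kurtosis(d)
        assert np.isnan(d.kurtosis[1]) and not d.kept[1]


class TestFilterByKurtosis:
    def make_with_kurtosis(self, values):
        nm, _, _ = mixture_fixture(n_sources=len(values), n_obs=300)
        d = run_ica(nm, k=len(values), seed=0)
        d.kurtosis = np.asarray(values, dtype=float)
        return d

    def test_boundary_is_strict(self):
        d = self.make_with_kurtosis([2.9, 3.0, 8.1])
        filter_by_kurtosis(d, threshold=3)
        assert d.kept.tolist() == [False, False, True]

    def test_threshold_zero_keeps_all(self):
        d = self.make_with_kurtosis([2.9, 3.0, 8.1])
        filter_by_kurtosis(d, threshold=0)
        assert d.kept.all()

    def test_all_gaussian_like_raises(self):
        d = self.make_with_kurtosis([2.5, 2.9, 3.0])
        with pytest.raises(ValueError, match="no components retained"):
            filter_by_kurtosis(d, threshold=3)


class TestSignCorrect:
    def set_component(self, d, i, loadings):
        pad = np.zeros(d.sources.shape[1])
        pad[: len(loadings)] = loadings
        d.sources[i] = pad

    def test_flip_when_negative_side_heavier(self):
        nm, _, _ = mixture_fixture(n_obs=300)
        d = run_ica(nm, k=3, seed=0)
        self.set_component(d, 0, [-5.0, 1.0, 2.0])
        w_before = d.weights[:, 0].copy()
        rec_before = d.reconstruction()
        sign_correct(d)
        assert d.sources[0, 0] == 5.0 and d.sources[0, 1] == -1.0
        np.testing.assert_allclose(d.weights[:, 0], -w_before)
        assert d.sign_flipped[0]
        np.testing.assert_allclose(d.reconstruction(), rec_before, atol=1e-10)

    def test_no_flip_when_positive_side_heavier(self):
        nm, _, _ = mixture_fixture(n_obs=300)
        d = run_ica(nm, k=3, seed=0)
        self.set_component(d, 0, [-1.0, 4.0])
        sign_correct(d)
        assert d.sources[0, 1] == 4.0 and not d.sign_flipped[0]

    def test_exact_tie_unchanged(self):
        nm, _, _ = mixture_fixture(n_obs=300)
        d = run_ica(nm, k=3, seed=0)
        self.set_component(d, 0, [-3.0, 3.0, 1.0])
        sign_correct(d)
        assert d.sources[0, 1] == 3.0 and not d.sign_flipped[0]

    def test_idempotent(self):
        nm, _, _ = mixture_fixture()
        d = run_ica(nm, k=3, seed=0)
        sign_correct(d)
        S1, W1, f1 = d.sources.copy(), d.weights.copy(), d.sign_flipped.copy()
        sign_correct(d)
        np.testing.assert_array_equal(d.sources, S1)
        np.testing.assert_array_equal(d.weights, W1)
        np.testing.assert_array_equal(d.sign_flipped, f1)


class TestContributorGenes:
    def test_single_spiked_gene_selected(self):
        nm, _, _ = mixture_fixture(n_obs=1000)
        d = run_ica(nm, k=3, seed=0)
        d.sources[0] = 0.0
        d.sources[0, 7] = 10.0
        out = contributor_genes(d, z_threshold=3)
        genes = [g for g, _, _ in out["IC1"]]
        assert genes == ["g7"]
        _, _, z = out["IC1"][0]
        assert z == pytest.approx(31.6, abs=0.1)

    def test_constant_loadings_give_empty_list(self):
        nm, _, _ = mixture_fixture(n_obs=300)
        d = run_ica(nm, k=3, seed=0)
        d.sources[0] = 2.5
        out = contributor_genes(d)
        assert out["IC1"] == []

    def test_threshold_zero_returns_all_genes_ordered(self):
        nm, _, _ = mixture_fixture(n_obs=300)
        d = run_ica(nm, k=3, seed=0)
        out = contributor_genes(d, z_threshold=0)
        zs = [abs(z) for _, _, z in out["IC2"]]
        assert len(zs) == 300
        assert zs == sorted(zs, reverse=True)


class TestMergeComponents:
    def test_merged_weights_are_exact_sums(self):
        nm, _, _ = mixture_fixture()
        d = run_ica(nm, k=3, seed=0)
        wi, wj = d.weights[:, 0].copy(), d.weights[:, 1].copy()
        si, sj = d.sources[0].copy(), d.sources[1].copy()
        merge_components(d, {"merged": ["IC1", "IC2"]})
        m = d.index_of("merged")
        np.testing.assert_array_equal(d.weights[:, m], wi + wj)
        np.testing.assert_array_equal(d.sources[m], si + sj)
        assert d.superseded[0] and d.superseded[1] and not d.superseded[m]

    def test_singleton_merge_is_identity(self):
        nm, _, _ = mixture_fixture()
        d = run_ica(nm, k=3, seed=0)
        s0 = d.sources[0].copy()
        merge_components(d, {"solo": ["IC1"]})
        np.testing.assert_array_equal(d.sources[d.index_of("solo")], s0)

    def test_reconstruction_unchanged_after_merge(self):
        nm, _, _ = mixture_fixture()
        d = run_ica(nm, k=3, seed=0)
        rec = d.reconstruction()
        merge_components(d, {"m": ["IC1", "IC3"]})
        np.testing.assert_allclose(d.reconstruction(), rec, atol=1e-10)

    def test_overlapping_groups_error(self):
        nm, _, _ = mixture_fixture()
        d = run_ica(nm, k=3, seed=0)
        with pytest.raises(ValueError, match="more than one"):
            merge_components(d, {"a": ["IC1", "IC2"], "b": ["IC2", "IC3"]})
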