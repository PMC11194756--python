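import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from spotica import (
    CompositionMatrix,
    GroundTruth,
    aggregate_by_annotation,
    dm_test,
    match_features,
    rmse_ilr,
    signature_correlation,
    uniform_baseline_losses,
)


def composition(values, parts=None):
    values = np.asarray(values, dtype=float)
    parts = parts or [f"p{j}" for j in range(values.shape[1])]
    return CompositionMatrix(values=values, part_ids=parts)


def truth_from_props(props, type_names=None):
    props = np.asarray(props, dtype=float)
    n, k = props.shape
    return GroundTruth(
        cells_per_spot=np.round(props * 10).astype(int),
        proportions=props,
        region_of_spot=np.zeros(n, dtype=int),
        region_priors=np.full((1, k), 1.0 / k),
        type_names=type_names or [f"type{j + 1}" for j in range(k)],
    )


class TestMatchFeatures:
    def test_exact_profile_match_has_r_one(self, small_reference):
        fm = match_features(
            small_reference.profiles[1], small_reference.gene_ids, small_reference
        )
        assert fm.loc[0, "cell_type"] == "type2"
        assert fm.loc[0, "r"] == pytest.approx(1.0)
        assert fm.loc[0, "confident"]

    def test_negated_profile_flagged_low_confidence(self, small_reference):
        fm = match_features(
            -small_reference.profiles[0], small_reference.gene_ids, small_reference
        )
        assert not fm.loc[0, "confident"]

    def test_random_loadings_fall_below_confidence_floor(self, rng, small_reference):
        # Monte-Carlo null: random vectors against marker profiles stay small
        L = rng.normal(size=(30, small_reference.profiles.shape[1]))
        fm = match_features(L, small_reference.gene_ids, small_reference, r_min=0.3)
        assert (~fm["confident"]).mean() > 0.9

    def test_constant_loading_excluded(self, small_reference):
        L = np.vstack([np.ones(small_reference.profiles.shape[1]), small_reference.profiles[0]])
        fm = match_features(L, small_reference.gene_ids, small_reference)
        assert len(fm) == 1

    def test_too_few_shared_genes_errors(self, small_reference):
        with pytest.raises(ValueError, match="shared genes"):
            match_features(np.ones((1, 5)), [f"x{i}" for i in range(5)], small_reference)


class TestAggregateByAnnotation:
    def fm(self, pairs):
        return pd.DataFrame(
            [
                {"component": c, "cell_type": t, "r": 0.9, "confident": True}
                for c, t in pairs
            ]
        )

    def test_same_annotation_summed(self):
        c = composition([[0.3, 0.2, 0.5]])
        fm = self.fm([("p0", "A"), ("p1", "A"), ("p2", "B")])
        agg = aggregate_by_annotation(c, fm, abundance_filter=0.0)
        np.testing.assert_allclose(
            agg.values[0], [0.5, 0.5]
        )

    def test_all_parts_to_one_type_gives_ones(self):
        c = composition([[0.25, 0.25, 0.5], [0.1, 0.4, 0.5]])
        fm = self.fm([("p0", "A"), ("p1", "A"), ("p2", "A")])
        agg = aggregate_by_annotation(c, fm, abundance_filter=0.0)
        np.testing.assert_allclose(agg.values, 1.0)

    def test_abundance_filter_zeroes_and_recloses(self):
        c = composition([[0.08, 0.42, 0.5]])
        fm = self.fm([("p0", "A"), ("p1", "B"), ("p2", "C")])
        agg = aggregate_by_annotation(c, fm, abundance_filter=0.10)
        np.testing.assert_allclose(agg.values[0], [0.0, 0.42 / 0.92, 0.5 / 0.92])

    def test_unconfident_parts_dropped_by_default(self):
        c = composition([[0.5, 0.5]])
        fm = pd.DataFrame(
            [
                {"component": "p0", "cell_type": "A", "r": 0.9, "confident": True},
                {"component": "p1", "cell_type": "B", "r": 0.1, "confident": False},
            ]
        )
        agg = aggregate_by_annotation(c, fm, abundance_filter=0.0)
        assert agg.part_ids == ["A"]
        np.testing.assert_allclose(agg.values[0], [1.0])


class TestRmseIlr:
    def test_perfect_prediction_zero_rmse(self, rng):
        props = rng.dirichlet(np.ones(4), size=50)
        pred = composition(props, parts=[f"type{j + 1}" for j in range(4)])
        rep = rmse_ilr(pred, truth_from_props(props))
        np.testing.assert_allclose(rep.rmse_per_dim, 0.0, atol=1e-10)
        assert rep.rmse_overall == pytest.approx(0.0, abs=1e-10)
        assert rep.n_spots_evaluated == 50

    def test_uniform_prediction_equals_truth_ilr_rms(self, rng):
        props = rng.dirichlet(np.ones(5), size=80)
        uniform = composition(
            np.full((80, 5), 0.2), parts=[f"type{j + 1}" for j in range(5)]
        )
        truth = truth_from_props(props)
        rep = rmse_ilr(uniform, truth)
        from spotica import ilr_transform

        oracle = float(np.sqrt((ilr_transform(props) ** 2).mean()))
        assert rep.rmse_overall == pytest.approx(oracle, abs=1e-10)
        # and the uniform-baseline helper agrees spot by spot
        np.testing.assert_allclose(
            rep.per_spot_loss, uniform_baseline_losses(truth), atol=1e-10
        )

    def test_duplicating_spots_leaves_rmse_unchanged(self, rng):
        props = rng.dirichlet(np.ones(3), size=40)
        predv = rng.dirichlet(np.ones(3), size=40)
        parts = [f"type{j + 1}" for j in range(3)]
        r1 = rmse_ilr(composition(predv, parts), truth_from_props(props))
        r2 = rmse_ilr(
            composition(np.vstack([predv, predv]), parts),
            truth_from_props(np.vstack([props, props])),
        )
        np.testing.assert_allclose(r1.rmse_per_dim, r2.rmse_per_dim, atol=1e-12)

    def test_brute_force_reimplementation_agreement(self, rng):
        # independent path: explicit Helmert contrasts and loop-based RMSE
        D = 6
        props = rng.dirichlet(np.ones(D), size=30)
        predv = rng.dirichlet(np.ones(D), size=30)
        parts = [f"type{j + 1}" for j in range(D)]
        rep = rmse_ilr(composition(predv, parts), truth_from_props(props))

        def brute_ilr(row):
            out = []
            for A in range(1, D):
                g = np.exp(np.mean(np.log(row[:A])))
                out.append(np.sqrt(A / (A + 1.0)) * np.log(g / row[A]))
            return np.array(out)

        Y = np.array([brute_ilr(r) for r in predv])
        Yh = np.array([brute_ilr(r) for r in props])
        per_dim = np.sqrt(((Y - Yh) ** 2).sum(axis=0) / 30)
        overall = np.sqrt(((Y - Yh) ** 2).mean())
        np.testing.assert_allclose(rep.rmse_per_dim, per_dim, atol=1e-10)
        assert rep.rmse_overall == pytest.approx(overall, abs=1e-10)

    def test_zero_rows_excluded_and_reported(self, rng):
        props = rng.dirichlet(np.ones(3), size=5)
        predv = props.copy()
        predv[2] = 0.0
        parts = [f"type{j + 1}" for j in range(3)]
        rep = rmse_ilr(composition(predv, parts), truth_from_props(props))
        assert rep.n_spots_evaluated == 4
        assert rep.spots_excluded == [(2, "no positive prediction")]

    def test_fewer_than_two_types_errors(self):
        pred = composition([[1.0]], parts=["type1"])
        with pytest.raises(ValueError):
            rmse_ilr(pred, truth_from_props([[1.0]], type_names=["type1"]))


class TestDmTest:
    def test_identical_losses_degenerate_half(self):
        l = np.abs(np.random.default_rng(0).normal(size=50))
        stat, p, flag = dm_test(l, l)
        assert (stat, p, flag) == (0.0, 0.5, True)

    def test_constant_improvement_degenerate_zero(self):
        l2 = np.abs(np.random.default_rng(0).normal(size=50)) + 1.0
        stat, p, flag = dm_test(l2 - 0.5, l2)
        assert flag and p == pytest.approx(0.0, abs=1e-300)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dm_test(np.ones(10), np.zeros(10))

    def test_null_calibration_uniform_p(self, rng):
        # exchangeable losses: one-tailed p should be uniform on (0, 1)
        n_rep, n = 10_000, 200
        a = rng.chisquare(3, size=(n_rep, n))
        b = rng.chisquare(3, size=(n_rep, n))
        ps = np.array([dm_test(a[i], b[i])[1] for i in range(n_rep)])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_detects_genuinely_better_method(self, rng):
        base = rng.chisquare(3, size=300)
        noisy = base + np.abs(rng.normal(0.5, 0.2, size=300))
        stat, p, flag = dm_test(base, noisy)
        assert not flag and p < 1e-6 and stat < 0


class TestSignatureCorrelation:
    def test_self_correlation_diagonal_one(self, rng):
        F = rng.normal(size=(4, 60))
        genes = [f"g{i}" for i in range(60)]
        R = signature_correlation(F, genes, F, genes)
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)

    def test_orthogonal_indicators_anticorrelated_off_diagonal(self):
        # disjoint indicator signatures share no support; mean removal forces r < 0
        F = np.kron(np.eye(3), np.ones(10))
        genes = [f"g{i}" for i in range(30)]
        R = signature_correlation(F, genes, F, genes)
        oracle = -0.5  # corr of two disjoint 1/3-indicators: -f/(1-f) with f=1/3
        off = R[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, oracle, atol=1e-12)

    def test_constant_feature_reported_missing(self, rng):
        F = rng.normal(size=(2, 40))
        F[0] = 3.0
        genes = [f"g{i}" for i in range(40)]
        R = signature_correlation(F, genes, F, genes)
        assert np.isnan(R[0]).all() and np.isnan(R[:, 0]).all()
        assert R[1, 1] == pytest.approx(1.0)
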