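import numpy as np
import pytest

from skelfuse.data_model import CohortDataset, SkeletonMask
from skelfuse.mcca import (
    CCAModel,
    MultiViewCCA,
    ViewSet,
    bh_adjust,
    component_group_test,
    cv_select_hyperparams,
    fit_mcca,
    mannwhitney_u,
    prepare_views,
    spatial_maps,
)
from skelfuse.simulate import SimConfig, generate_cohort

from _oracles import bh_stepup_oracle, mannwhitney_exact_oracle, rank_auc


def _latent_views(seed=0, n=60, v=30, k=2, eff=0.0, noise=1.0):
    """k views sharing a 1-D latent plus iid noise."""
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)
    t[: n // 2] -= eff
    views = {}
    for i in range(k):
        load = np.abs(rng.normal(size=v)) + 0.3
        x = np.outer(t, load) + noise * rng.standard_normal((n, v))
        x = (x - x.mean(0)) / x.std(0)
        views[f"v{i + 1}"] = x
    return ViewSet(views), t


class TestPrepareViews:
    def test_zscore_contract(self, tiny_cohort):
        vs = prepare_views(tiny_cohort)
        for x in vs.views.values():
            assert np.abs(x.mean(axis=0)).max() < 1e-10
            assert np.abs(x.std(axis=0) - 1).max() < 1e-10

    def test_constant_column_dropped(self, tiny_cohort, caplog):
        tiny_cohort.metrics["m"][:, 3] = 2.5
        with caplog.at_level("WARNING"):
            vs = prepare_views(tiny_cohort)
        assert vs.views["m"].shape[1] == tiny_cohort.mask.n_voxels - 1
        assert "dropped 1 constant" in caplog.text

    def test_all_fourteen_default_metrics_survive(self):
        ds = generate_cohort(SimConfig(
            n_a=5, n_b=5, grid_shape=(8, 8, 8), skeleton_fraction=0.15, seed=0
        ))
        vs = prepare_views(ds)
        assert len(vs.views) == 14

    def test_all_constant_view_errors(self, tiny_cohort):
        tiny_cohort.metrics["m"][:] = 1.0
        with pytest.raises(ValueError, match="zero features"):
            prepare_views(tiny_cohort)


class TestFitMCCA:
    def test_identical_single_column_views(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(40)
        col = (col - col.mean()) / col.std()
        vs = ViewSet({"a": col[:, None].copy(), "b": col[:, None].copy()})
        model = fit_mcca(vs, reg=1e-4, D=1)
        assert model.ccc[0][0, 1] >= 0.99

    def test_planted_latent_recovery(self):
        vs, t = _latent_views(seed=1, noise=0.5)
        model = fit_mcca(vs, reg=0.1, D=1)
        assert model.ccc[0][0, 1] >= 0.8
        r = np.corrcoef(model.variates["v1"][:, 0], t)[0, 1]
        assert abs(r) >= 0.9

    def test_variate_regularized_unit_variance(self):
        vs, _ = _latent_views(seed=2, v=10)
        reg = 0.05
        model = fit_mcca(vs, reg=reg, D=2)
        for name in vs.view_names:
            for d in range(2):
                w = model.weights[name][:, d]
                var = model.variates[name][:, d].var(ddof=1) + reg * (w @ w)
                assert var == pytest.approx(1.0, abs=1e-8)

    def test_ccc_bounds_and_diagonal(self):
        vs, _ = _latent_views(seed=3, k=3)
        model = fit_mcca(vs, reg=0.5, D=2)
        assert np.all(np.abs(model.ccc) <= 1 + 1e-12)
        for d in range(2):
            np.testing.assert_allclose(np.diag(model.ccc[d]), 1.0)

    def test_joint_subject_permutation_invariance(self):
        vs, _ = _latent_views(seed=4)
        rng = np.random.default_rng(9)
        perm = rng.permutation(vs.n_subjects)
        model1 = fit_mcca(vs, reg=0.2, D=1)
        model2 = fit_mcca(vs.subset(perm), reg=0.2, D=1)
        np.testing.assert_allclose(
            model1.ccc[0][0, 1], model2.ccc[0][0, 1], atol=1e-8
        )

    def test_singular_unregularized_fit_errors(self):
        rng = np.random.default_rng(5)
        vs = ViewSet({
            "a": rng.standard_normal((10, 25)),
            "b": rng.standard_normal((10, 25)),
        })
        with pytest.raises(ValueError, match="reg > 0"):
            fit_mcca(vs, reg=0.0, D=1)

    def test_excessive_D_errors(self):
        vs, _ = _latent_views(seed=6, v=3)
        with pytest.raises(ValueError, match="exceeds"):
            fit_mcca(vs, reg=0.1, D=10)

    def test_large_reg_does_not_crash_and_degrades_gracefully(self):
        vs, _ = _latent_views(seed=7)
        model = fit_mcca(vs, reg=1e4, D=1)
        assert np.isfinite(model.ccc).all()


class TestCVSelect:
    def test_independent_views_have_low_heldout_correlation(self):
        rng = np.random.default_rng(10)
        vs = ViewSet({
            "a": rng.standard_normal((50, 20)),
            "b": rng.standard_normal((50, 20)),
        })
        from skelfuse.mcca import _safe_corr

        c, D = cv_select_hyperparams(vs, D_grid=(1, 2, 3), seed=0)
        model = fit_mcca(vs.subset(np.arange(40)), reg=c, D=1)
        a_test = model.transform(vs.subset(np.arange(40, 50)).views)
        rho = _safe_corr(a_test["a"][:, 0], a_test["b"][:, 0])
        assert abs(rho) < 0.5

    def test_planted_latent_selects_one_component(self):
        vs, _ = _latent_views(seed=11, n=69, v=40, noise=0.5)
        c, D = cv_select_hyperparams(vs, seed=1)
        assert D == 1

    def test_pure_noise_does_not_always_pick_max_D(self):
        picks = []
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            vs = ViewSet({
                "a": rng.standard_normal((40, 15)),
                "b": rng.standard_normal((40, 15)),
            })
            picks.append(cv_select_hyperparams(vs, seed=s)[1])
        assert sum(1 for d in picks if d < 5) >= 3

    def test_empty_grid_errors(self):
        vs, _ = _latent_views(seed=12)
        with pytest.raises(ValueError, match="non-empty"):
            cv_select_hyperparams(vs, reg_grid=[], seed=0)


class TestBH:
    def test_stepup_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(
                bh_adjust(p), bh_stepup_oracle(p), atol=1e-12
            )

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=10)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mannwhitney_u(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_distributions_p_one(self):
        a = np.array([1.0, 2.0, 5.0])
        u, p = mannwhitney_u(a, a.copy())
        assert p == pytest.approx(1.0)

    def test_u_sum_identity_and_exact_enumeration(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            a = rng.normal(size=rng.integers(2, 5))
            b = rng.normal(size=rng.integers(2, 5))
            u_a, p = mannwhitney_u(a, b)
            u_b, _ = mannwhitney_u(b, a)
            assert u_a + u_b == pytest.approx(len(a) * len(b))
            u_oracle, p_oracle = mannwhitney_exact_oracle(a, b)
            assert u_a == pytest.approx(u_oracle)
            assert p == pytest.approx(p_oracle)


def _planted_model(seed, n=69, n_a=46, eff=2.0, k=4, loaded=("v1", "v2")):
    """CCAModel with a 1-D latent expressed in the variates of ``loaded``
    views only; the other views carry independent scores."""
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)
    t[:n_a] -= eff
    names = [f"v{i + 1}" for i in range(k)]
    variates = {}
    for name in names:
        if name in loaded:
            s = t + 0.3 * rng.standard_normal(n)
        else:
            s = rng.standard_normal(n)
        variates[name] = s[:, None]
    ccc = np.ones((1, k, k))
    return CCAModel(view_names=names, weights={}, variates=variates,
                    D=1, reg=0.01, ccc=ccc), np.array(
        ["A"] * n_a + ["B"] * (n - n_a), dtype=object)


class TestComponentGroupTest:
    def test_joint_detection_with_exact_specificity(self):
        model, labels = _planted_model(seed=0)
        rep = component_group_test(model, labels)
        assert rep.labels[0] == "joint"
        assert rep.component_views(0) == ["v1", "v2"]

    def test_unique_detection(self):
        model, labels = _planted_model(seed=1, loaded=("v3",))
        rep = component_group_test(model, labels)
        assert rep.labels[0] == "unique"
        assert rep.component_views(0) == ["v3"]

    def test_null_variates_not_discriminative(self):
        model, labels = _planted_model(seed=2, eff=0.0, loaded=())
        rep = component_group_test(model, labels)
        assert rep.labels[0] == "none"

    def test_outlier_removal_reduces_n(self):
        model, labels = _planted_model(seed=3)
        model.variates["v4"][0, 0] = 50.0  # gross outlier
        rep = component_group_test(model, labels)
        t4 = [t for t in rep.tests if t.view == "v4"][0]
        assert t4.n_after_outlier_removal < len(labels)

    def test_adjusted_at_least_raw_and_labels_consistent(self):
        model, labels = _planted_model(seed=4)
        rep = component_group_test(model, labels, alpha=0.05)
        for t in rep.tests:
            assert t.p_adj >= t.p_raw - 1e-12
        n_sig = sum(t.significant for t in rep.tests if t.component == 0)
        expected = {0: "none", 1: "unique"}.get(n_sig, "joint")
        assert rep.labels[0] == expected


class TestSpatialMaps:
    def test_self_correlated_feature_attains_max_z(self):
        vs, t = _latent_views(seed=20, v=15, noise=0.8)
        model = fit_mcca(vs, reg=0.1, D=1)
        # plant a feature equal to the variate itself
        x = vs.views["v1"].copy()
        v = model.variates["v1"][:, 0]
        x[:, 7] = (v - v.mean()) / v.std()
        vs2 = ViewSet({"v1": x, "v2": vs.views["v2"]})
        maps = spatial_maps(model, vs2, 0)
        assert np.argmax(maps["v1"]) == 7

    def test_sign_flip_negates_maps(self):
        vs, _ = _latent_views(seed=21, v=12)
        model = fit_mcca(vs, reg=0.1, D=1)
        maps1 = spatial_maps(model, vs, 0)
        flipped = CCAModel(
            view_names=model.view_names,
            weights={k: -w for k, w in model.weights.items()},
            variates={k: -v for k, v in model.variates.items()},
            D=model.D, reg=model.reg, ccc=model.ccc,
        )
        maps2 = spatial_maps(flipped, vs, 0)
        for k in maps1:
            np.testing.assert_allclose(maps1[k], -maps2[k], atol=1e-10)

    def test_support_recovery(self):
        """Latent loading support attains higher z than unloaded features."""
        rng = np.random.default_rng(22)
        n, v = 69, 40
        t = rng.standard_normal(n)
        support = np.zeros(v, dtype=bool)
        support[:12] = True
        x1 = rng.standard_normal((n, v))
        x1[:, support] += np.outer(t, np.abs(rng.normal(size=12)) + 0.5)
        x2 = np.outer(t, np.abs(rng.normal(size=v)) + 0.3) \
            + rng.standard_normal((n, v))
        vs = ViewSet({
            "a": (x1 - x1.mean(0)) / x1.std(0),
            "b": (x2 - x2.mean(0)) / x2.std(0),
        })
        model = fit_mcca(vs, reg=0.1, D=1)
        maps = spatial_maps(model, vs, 0)
        assert rank_auc(maps["a"], support) >= 0.8

    def test_bad_component_errors(self):
        vs, _ = _latent_views(seed=23)
        model = fit_mcca(vs, reg=0.1, D=1)
        with pytest.raises(ValueError, match="component"):
            spatial_maps(model, vs, 3)


def test_estimator_front_end_selects_and_transforms():
    vs, _ = _latent_views(seed=30, n=50, v=20, noise=0.5)
    est = MultiViewCCA(D_grid=(1, 2), random_state=0)
    est.fit(vs)
    assert est.D_ in (1, 2)
    out = est.transform(vs)
    assert out["v1"].shape == (50, est.D_)
    np.testing.assert_allclose(out["v1"], est.variates_["v1"], atol=1e-10)
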