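import numpy as np
import pytest
from scipy.stats import spearmanr

from parasdm import (
    FeatureSpec,
    MaxEntModel,
    auc,
    expand_features,
    fit_maxent,
    make_virtual_species,
    predict_logistic,
    predict_raw,
    sample_background,
    train_maxent,
    generate_env_layers,
    default_template,
    sample_occurrences,
)
from parasdm.maxent_core import compute_scaling, feature_info, _objective_and_grad
from parasdm.stack import occurrence_cells, predictor_matrix, values_at_cells


class TestFeatureExpansion:
    scaling = np.array([[0.0, 1.0]])

    def test_linear_at_zero(self):
        f = expand_features(np.array([[0.0]]), FeatureSpec("L"), self.scaling)
        assert f[0, 0] == 0.0

    def test_threshold_strict_inequality(self):
        spec = FeatureSpec("T", threshold_knots=3)
        # knots are interior: 0.25, 0.5, 0.75
        f = expand_features(np.array([[0.5]]), spec, self.scaling)
        assert f.tolist() == [[1.0, 0.0, 0.0]]  # u > t strictly

    def test_forward_hinge_value(self):
        spec = FeatureSpec("H", hinge_knots=3)
        f = expand_features(np.array([[0.75]]), spec, self.scaling)
        names, _ = feature_info(["v"], spec)
        by_name = dict(zip(names, f[0]))
        assert by_name["Hf(v,0.5000)"] == pytest.approx((0.75 - 0.5) / 0.5)

    def test_clamping_outside_training_range(self):
        f = expand_features(np.array([[2.5], [-1.0]]), FeatureSpec("L"), self.scaling)
        assert f[:, 0].tolist() == [1.0, 0.0]

    def test_product_features_are_pairwise(self):
        scaling = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        f = expand_features(np.array([[0.5, 0.4, 0.2]]), FeatureSpec("P"), scaling)
        assert sorted(f[0].tolist()) == sorted([0.5 * 0.4, 0.5 * 0.2, 0.4 * 0.2])


class TestBackgroundSampling:
    def test_all_cells_when_n_exceeds(self, make_grid):
        mask = make_grid(np.ones((4, 4)), kind="binary")
        cells = sample_background(mask, n=100, seed=1)
        assert len(cells) == 16

    def test_same_seed_identical(self, make_grid):
        mask = make_grid(np.ones((30, 30)), kind="binary")
        a = sample_background(mask, n=50, seed=7)
        b = sample_background(mask, n=50, seed=7)
        assert np.array_equal(a, b)

    def test_inclusion_frequency_binomial(self, make_grid):
        mask = make_grid(np.ones((10, 10)), kind="binary")
        n, trials = 20, 400
        hits = 0
        target = (0, 0)
        for seed in range(trials):
            cells = sample_background(mask, n=n, seed=seed)
            hits += any((c == target).all() for c in cells)
        p = n / 100
        sigma = np.sqrt(trials * p * (1 - p))
        assert abs(hits - trials * p) < 3 * sigma


class TestFitting:
    def test_presences_identical_to_background_gives_null_model(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(50, 2))
        scaling = compute_scaling(X)
        spec = FeatureSpec("LQ")
        F = expand_features(X, spec, scaling)
        model = fit_maxent(F, F, spec, rm=1.0, variable_names=["a", "b"], scaling=scaling)
        assert model.k_nonzero == 0
        raw = predict_raw(model, X)
        np.testing.assert_allclose(raw, 1.0 / 50, rtol=1e-9)

    def test_one_parameter_fit_matches_grid_search_oracle(self):
        # single linear feature; brute-force line search over the same objective
        rng = np.random.default_rng(1)
        xb = rng.uniform(size=(300, 1))
        # presences biased toward high x
        xp = rng.uniform(size=(800, 1)) ** 0.25
        xp = xp[:60]
        spec = FeatureSpec("L")
        scaling = np.array([[0.0, 1.0]])
        Fp = expand_features(xp, spec, scaling)
        Fb = expand_features(xb, spec, scaling)
        model = fit_maxent(Fp, Fb, spec, rm=1.0, feature_classes=["L"])

        from parasdm.maxent_core import regularization_weights

        beta = regularization_weights(Fp, ["L"], 1.0)
        grid = np.linspace(-10, 10, 200001)

        def objective(lam):
            s = Fb[:, 0] * lam
            m = s.max()
            return Fp[:, 0].mean() * lam - (m + np.log(np.exp(s - m).sum())) - beta[0] * abs(lam)

        vals = [objective(l) for l in grid]
        best = grid[int(np.argmax(vals))]
        assert model.coefficients[0] == pytest.approx(best, abs=1e-4)

    def test_huge_rm_zeroes_everything(self):
        rng = np.random.default_rng(2)
        xb = rng.uniform(size=(100, 2))
        xp = xb[:20] ** 2
        model = train_maxent(xp, xb, ["a", "b"], FeatureSpec("LQ"), rm=1e6)
        assert model.k_nonzero == 0

    def test_objective_never_below_null(self):
        rng = np.random.default_rng(3)
        xb = rng.uniform(size=(200, 2))
        xp = np.clip(xb[:40] + 0.3, 0, 1)
        spec = FeatureSpec("LQ")
        scaling = compute_scaling(xb)
        Fp = expand_features(xp, spec, scaling)
        Fb = expand_features(xb, spec, scaling)
        _, classes = feature_info(["a", "b"], spec)
        model = fit_maxent(Fp, Fb, spec, rm=1.0, feature_classes=classes)
        from parasdm.maxent_core import regularization_weights

        beta = regularization_weights(Fp, classes, 1.0)
        K = len(beta)

        def penalized(lam):
            z = np.concatenate([np.maximum(lam, 0), np.maximum(-lam, 0)])
            val, _ = _objective_and_grad(z, Fp.mean(axis=0), Fb, beta)
            return -val  # _objective_and_grad returns the minimization objective

        assert penalized(model.coefficients) >= penalized(np.zeros(K)) - 1e-7

    def test_raw_sums_to_one_over_background(self):
        rng = np.random.default_rng(4)
        xb = rng.uniform(size=(150, 2))
        xp = np.clip(xb[:30] * 1.4, 0, 1)
        model = train_maxent(xp, xb, ["a", "b"], FeatureSpec("LQ"), rm=0.5)
        raw = predict_raw(model, xb)
        assert (raw >= 0).all()
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_logistic_transform_algebra_and_monotonicity(self):
        rng = np.random.default_rng(5)
        xb = rng.uniform(size=(150, 2))
        xp = np.clip(xb[:30] + 0.25, 0, 1)
        model = train_maxent(xp, xb, ["a", "b"], FeatureSpec("LQ"), rm=1.0)
        grid_x = rng.uniform(size=(50, 2))
        raw = predict_raw(model, grid_x)
        p = predict_logistic(model, grid_x)
        # p = e^H raw / (1 + e^H raw)
        expected = np.exp(model.entropy) * raw / (1 + np.exp(model.entropy) * raw)
        np.testing.assert_allclose(p, expected, rtol=1e-9)
        assert ((p > 0) & (p < 1)).all()
        order_raw = np.argsort(raw)
        order_p = np.argsort(p)
        assert np.array_equal(order_raw, order_p)

    def test_null_model_logistic_is_half(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(80, 2))
        model = train_maxent(X[:20], X, ["a", "b"], FeatureSpec("LQ"), rm=1e6)
        p = predict_logistic(model, X)
        np.testing.assert_allclose(p, 0.5, atol=1e-9)


class TestRecovery:
    def test_lq_species_rank_recovery(self):
        # presences drawn from a known logistic L+Q response; the fitted
        # cell ranking must track the true suitability closely
        template = default_template(100, 100)
        env = generate_env_layers(template, 2, smoothness=8.0, seed=42)
        sp = make_virtual_species(env, {"env1": (10.0, -6.0), "env2": (6.0, 0.0)},
                                  intercept=-8.0)
        occ = sample_occurrences(sp, 200, seed=7)
        mask = template.copy_with(np.ones(template.shape), kind="binary")
        bg = sample_background(mask, 2000, seed=7)
        Xp = values_at_cells(env, occurrence_cells(occ, template, unique=False))
        Xb = values_at_cells(env, bg)
        model = train_maxent(Xp, Xb, ["env1", "env2"], FeatureSpec("LQ"), rm=1.0)
        X, cells, _ = predictor_matrix(env)
        pred = predict_logistic(model, X)
        truth = sp.truth_layer.values[cells[:, 0], cells[:, 1]]
        rho = spearmanr(pred, truth).statistic
        assert rho >= 0.9

    def test_auc_strong_signal_vs_no_signal(self):
        template = default_template(60, 60)
        env = generate_env_layers(template, 2, smoothness=5.0, seed=9)
        sp = make_virtual_species(env, {"env1": (44.0, -14.0), "env2": (18.0, 0.0)},
                                  intercept=-38.0)
        occ = sample_occurrences(sp, 150, seed=10)
        mask = template.copy_with(np.ones(template.shape), kind="binary")
        bg = sample_background(mask, 2000, seed=11)
        cells = occurrence_cells(occ, template, unique=False)
        Xp = values_at_cells(env, cells)
        Xb = values_at_cells(env, bg)
        # hold out 50 presences
        model = train_maxent(Xp[:100], Xb, ["env1", "env2"], FeatureSpec("LQ"), rm=1.0)
        strong = auc(predict_logistic(model, Xp[100:]), predict_logistic(model, Xb))
        assert strong >= 0.9
        # signal-free species: uniform truth
        flat = make_virtual_species(env, {"env1": (0.0, 0.0)}, intercept=1.0)
        occ0 = sample_occurrences(flat, 150, seed=12)
        Xp0 = values_at_cells(env, occurrence_cells(occ0, template, unique=False))
        model0 = train_maxent(Xp0[:100], Xb, ["env1", "env2"], FeatureSpec("LQ"), rm=1.0)
        weak = auc(predict_logistic(model0, Xp0[100:]), predict_logistic(model0, Xb))
        assert weak == pytest.approx(0.5, abs=0.05)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(13)
        xb = rng.uniform(size=(120, 3))
        xp = np.clip(xb[:25] + 0.2, 0, 1)
        model = train_maxent(xp, xb, ["a", "b", "c"], FeatureSpec("LQH", hinge_knots=5), rm=1.0)
        path = tmp_path / "model.txt"
        model.save(path)
        again = MaxEntModel.load(path)
        X = rng.uniform(size=(40, 3))
        np.testing.assert_allclose(predict_logistic(again, X), predict_logistic(model, X),
                                   rtol=1e-12)
        assert again.spec.classes == "LQH"
        assert again.k_nonzero == model.k_nonzero
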