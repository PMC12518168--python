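"""Maximum-entropy engine: features, fitting, prediction, evaluation,
importance accounting, response curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from urbanhab import (FeatureSpec, OccurrenceSet, ScenarioConfig, auc,
                      build_feature_map, build_scenario, evaluate,
                      extract_covariates, fit, jackknife_gains,
                      percent_contribution, permutation_importance,
                      predict_logistic, predict_raw, response_curve,
                      spatial_cross_validate, tss)
from oracle_utils import convex_oracle_lambdas, gibbs_instance

LINEAR = FeatureSpec(classes=("linear",), beta=1.0)


def uniform_background(n, k, seed=0, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"v{i}" for i in range(k)]
    return pd.DataFrame(rng.uniform(0, 1, size=(n, k)), columns=names)


class TestFeatureMap:
    def test_linear_feature_is_minmax_scaled(self):
        bg = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        fm = build_feature_map(bg, FeatureSpec(classes=("linear",)))
        assert fm.n_features == 1
        f = fm.transform(pd.DataFrame({"x": [2.0, 6.0, 4.0]}))
        assert f[:, 0] == pytest.approx([0.0, 1.0, 0.5])

    def test_product_feature_count(self):
        bg = uniform_background(50, 3)
        fm = build_feature_map(bg, FeatureSpec(classes=("product",)))
        assert fm.n_features == 3  # C(3,2)

    def test_hinge_feature_count(self):
        bg = uniform_background(200, 1)
        fm = build_feature_map(bg, FeatureSpec(classes=("hinge",), hinge_knots=2))
        assert fm.n_features == 4  # 2 forward + 2 reverse

    def test_constant_variable_dropped_with_warning(self):
        bg = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.warns(UserWarning, match="constant"):
            fm = build_feature_map(bg, FeatureSpec(classes=("linear",)))
        assert fm.variables == ["y"]

    def test_all_features_in_unit_interval_on_background(self):
        bg = uniform_background(300, 2, seed=3) * 10 - 5
        fm = build_feature_map(bg, FeatureSpec(classes=("linear", "quadratic",
                                                        "product", "hinge")))
        f = fm.transform(bg)
        assert f.min() >= 0.0 and f.max() <= 1.0

    def test_projection_clamped_to_training_bounds(self):
        bg = uniform_background(100, 1)
        fm = build_feature_map(bg, FeatureSpec(classes=("linear",)))
        f = fm.transform(pd.DataFrame({"v0": [-5.0, 5.0]}))
        assert fm.last_clamped == 2
        assert f[:, 0] == pytest.approx([0.0, 1.0])

    def test_categorical_indicators(self):
        bg = pd.DataFrame({"lu": [0.0, 1.0, 1.0, 2.0]})
        fm = build_feature_map(bg, FeatureSpec(classes=("categorical",)),
                               categorical=["lu"])
        f = fm.transform(bg)
        assert f.shape == (4, 3)
        assert f.sum(axis=1) == pytest.approx(np.ones(4))


class TestFit:
    def test_uniform_presences_give_near_zero_weights(self):
        fb = uniform_background(200, 2, seed=1)
        rng = np.random.default_rng(2)
        fp = fb.iloc[rng.integers(0, len(fb), size=100_000)]
        model = fit(fp, fb, LINEAR)
        assert np.abs(model.lambdas).max() <= 1e-2
        assert model.gain < 0.01

    def test_degenerate_binary_feature_mass_shift(self):
        bg = pd.DataFrame({"lu": np.repeat([0.0, 1.0], 50)})
        fp = pd.DataFrame({"lu": np.ones(40)})
        spec = FeatureSpec(classes=("categorical",), beta=1e-6)
        masses = []
        for iters in (5, 60):
            m = fit(fp, bg, spec, max_iterations=iters, categorical=["lu"], tol=0.0)
            raw = predict_raw(m, bg)
            masses.append(raw[bg["lu"] == 1.0].sum())
        assert masses[1] > masses[0] > 0.5  # mass concentrates monotonically

    def test_parameter_recovery_small_gibbs_instance(self):
        fp, fb = gibbs_instance(500, 4000, [2.0, -1.5], seed=5)
        spec = FeatureSpec(classes=("linear",), beta=0.1)
        model = fit(pd.DataFrame(fp, columns=["a", "b"]),
                    pd.DataFrame(fb, columns=["a", "b"]), spec)
        # features are already on [0,1]; min-max rescaling is near identity
        lo_a, hi_a = model.feature_map.bounds["a"]
        w = model.lambdas / np.array([hi_a - lo_a, hi_a - lo_a])
        assert np.allclose(w, [2.0, -1.5], rtol=0.15, atol=0.1)

    def test_gain_path_is_non_decreasing(self):
        fp, fb = gibbs_instance(300, 500, [1.5, -1.0], seed=8)
        model = fit(pd.DataFrame(fp, columns=["a", "b"]),
                    pd.DataFrame(fb, columns=["a", "b"]),
                    FeatureSpec(classes=("linear", "quadratic", "hinge"),
                                hinge_knots=4, beta=0.5))
        path = np.asarray(model.gain_path)
        assert (np.diff(path) >= -1e-12).all()

    def test_matches_convex_optimiser_oracle(self):
        fp, fb = gibbs_instance(150, 600, [2.0, -1.0], seed=3)
        spec = FeatureSpec(classes=("linear",), beta=0.5)
        model = fit(pd.DataFrame(fp, columns=["a", "b"]),
                    pd.DataFrame(fb, columns=["a", "b"]), spec,
                    max_iterations=200_000, tol=1e-13)
        oracle = convex_oracle_lambdas(model.feature_map.transform(pd.DataFrame(fp, columns=["a", "b"])),
                                       model.feature_map.transform(pd.DataFrame(fb, columns=["a", "b"])),
                                       model.beta)
        assert np.abs(model.lambdas - oracle).max() < 1e-4

    def test_non_finite_features_rejected(self):
        bg = uniform_background(50, 1)
        fp = pd.DataFrame({"v0": [0.2, np.nan]})
        with pytest.raises(ValueError, match="finite"):
            fit(fp, bg, LINEAR)


class TestPrediction:
    @pytest.fixture(scope="class")
    def model(self):
        fp, fb = gibbs_instance(400, 2000, [2.0, -1.5], seed=9)
        cols = ["a", "b"]
        return (fit(pd.DataFrame(fp, columns=cols), pd.DataFrame(fb, columns=cols),
                    FeatureSpec(classes=("linear",), beta=0.2)),
                pd.DataFrame(fp, columns=cols), pd.DataFrame(fb, columns=cols))

    def test_raw_sums_to_one_over_background(self, model):
        m, _, fb = model
        assert predict_raw(m, fb).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_model_is_uniform(self):
        bg = uniform_background(77, 2)
        m = fit(bg.iloc[:10], bg, FeatureSpec(classes=("linear",), beta=1e6))
        assert np.abs(m.lambdas).max() == 0.0
        assert predict_raw(m, bg) == pytest.approx(np.full(77, 1 / 77))

    def test_logistic_is_entropy_anchored_transform_of_raw(self, model):
        m, _, fb = model
        raw = predict_raw(m, fb)
        logi = predict_logistic(m, fb)
        re_h = raw * np.exp(m.entropy)
        assert logi == pytest.approx(re_h / (1 + re_h))
        # a cell with raw = e^-H sits exactly at suitability 0.5
        half = np.exp(-m.entropy) * np.exp(m.entropy)
        assert half / (1 + half) == pytest.approx(0.5)
        order = np.argsort(raw)
        assert (np.diff(logi[order]) >= -1e-15).all()
        assert logi.min() >= 0 and logi.max() <= 1

    def test_cloglog_output_flag(self, model):
        m, _, fb = model
        cll = predict_logistic(m, fb, output="cloglog")
        assert ((cll >= 0) & (cll <= 1)).all()

    def test_stronger_weight_raises_rank_correlation(self, model):
        m, _, fb = model
        f = m.feature_map.transform(fb)
        base = spearmanr(f[:, 0], predict_raw(m, fb)).statistic
        boosted = type(m)(**{**m.__dict__, "lambdas": m.lambdas * np.array([2.0, 1.0])})
        stronger = spearmanr(f[:, 0], boosted.raw_scores(fb)).statistic
        assert stronger > base

    def test_save_load_round_trip(self, model, tmp_path):
        m, fp, fb = model
        m.save(tmp_path / "model.json")
        back = type(m).load(tmp_path / "model.json")
        assert predict_raw(back, fb) == pytest.approx(predict_raw(m, fb))
        assert back.gain == pytest.approx(m.gain)


class TestMetrics:
    def test_auc_perfect_separation(self):
        assert auc([3.0, 4.0], [1.0, 2.0]) == 1.0

    def test_auc_worked_example(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    def test_auc_label_permutation_near_half(self, rng):
        scores = rng.normal(size=2000)
        assert auc(scores[:1000], scores[1000:]) == pytest.approx(0.5, abs=0.05)

    def test_auc_constant_scores_warns_half(self):
        with pytest.warns(UserWarning):
            assert auc([1.0, 1.0], [1.0]) == 0.5

    def test_auc_invariant_under_monotone_transform(self, rng):
        sp, sb = rng.exponential(size=50), rng.exponential(size=80) * 0.5
        a1 = auc(sp, sb)
        a2 = auc(np.log(sp), np.log(sb))
        e_h = 3.0
        a3 = auc(sp * e_h / (1 + sp * e_h), sb * e_h / (1 + sb * e_h))
        assert a1 == pytest.approx(a2) == pytest.approx(a3)

    def test_tss_perfect_separation(self):
        t, _ = tss([3.0, 4.0], [1.0, 2.0])
        assert t == pytest.approx(1.0)

    def test_tss_worked_example(self):
        t, thr = tss([0.9, 0.4], [0.5, 0.1])
        assert t == pytest.approx(0.5)
        assert 0.1 < thr <= 0.4  # lowest maximising threshold

    def test_tss_identical_distributions_near_zero(self, rng):
        scores = rng.normal(size=4000)
        t, _ = tss(scores[:2000], scores[2000:])
        assert abs(t) < 0.1


class TestSpatialCV:
    @pytest.fixture(scope="class")
    def scenario(self):
        cfg = ScenarioConfig(nrows=60, ncols=60, weights={"bio7": 4.0},
                             variables=("bio7", "bio17"), n_presences=800,
                             smoothness=4.0)
        return build_scenario(cfg, seed=3)

    def test_strong_signal_yields_high_fold_auc(self, scenario):
        rep = spatial_cross_validate(OccurrenceSet(scenario.occurrences),
                                     scenario.baseline_stack,
                                     FeatureSpec(classes=("linear",), beta=0.5),
                                     k=2, block_cells=10, seed=0)
        assert min(rep.fold_aucs) > 0.9

    def test_mean_is_arithmetic_mean_and_seed_deterministic(self, scenario):
        spec = FeatureSpec(classes=("linear",), beta=0.5)
        r1 = spatial_cross_validate(OccurrenceSet(scenario.occurrences),
                                    scenario.baseline_stack, spec,
                                    k=4, block_cells=15, seed=7)
        r2 = spatial_cross_validate(OccurrenceSet(scenario.occurrences),
                                    scenario.baseline_stack, spec,
                                    k=4, block_cells=15, seed=7)
        assert r1.fold_aucs == r2.fold_aucs
        assert r1.auc_mean == pytest.approx(np.mean(r1.fold_aucs))

    def test_too_few_presences_rejected(self, scenario):
        occ = OccurrenceSet(scenario.occurrences.iloc[:3])
        with pytest.raises(ValueError, match="at least"):
            spatial_cross_validate(occ, scenario.baseline_stack, LINEAR, k=10)


class TestImportance:
    def test_single_variable_contribution_is_total(self):
        fp, fb = gibbs_instance(300, 1000, [2.0], seed=1)
        m = fit(pd.DataFrame(fp, columns=["a"]), pd.DataFrame(fb, columns=["a"]),
                FeatureSpec(classes=("linear", "quadratic"), beta=0.5))
        contrib = percent_contribution(m)
        assert contrib["a"] == pytest.approx(100.0)

    def test_symmetric_variables_share_contribution(self):
        fp, fb = gibbs_instance(4000, 8000, [2.0, 2.0], seed=6)
        m = fit(pd.DataFrame(fp, columns=["a", "b"]),
                pd.DataFrame(fb, columns=["a", "b"]),
                FeatureSpec(classes=("linear",), beta=0.1))
        contrib = percent_contribution(m)
        assert contrib["a"] == pytest.approx(50.0, abs=5.0)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-6)

    def test_permutation_importance_finds_informative_variable(self, rng):
        fp, fb = gibbs_instance(2000, 3000, [3.0], seed=2)
        fp_df = pd.DataFrame(fp, columns=["signal"])
        fb_df = pd.DataFrame(fb, columns=["signal"])
        fp_df["noise"] = rng.uniform(0, 1, len(fp_df))
        fb_df["noise"] = rng.uniform(0, 1, len(fb_df))
        m = fit(fp_df, fb_df, FeatureSpec(classes=("linear",), beta=0.2))
        imp = permutation_importance(m, fp_df, fb_df, seed=0, reps=5)
        assert imp["signal"] > 90.0
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)

    def test_jackknife_nesting_and_redundancy(self):
        fp, fb = gibbs_instance(1000, 2000, [2.5, -1.5], seed=4)
        fp_df = pd.DataFrame(fp, columns=["a", "b"])
        fb_df = pd.DataFrame(fb, columns=["a", "b"])
        # duplicate the informative variable and add pure noise
        rng = np.random.default_rng(0)
        fp_df["a_copy"] = fp_df["a"]
        fb_df["a_copy"] = fb_df["a"]
        fp_df["noise"] = rng.uniform(0, 1, len(fp_df))
        fb_df["noise"] = rng.uniform(0, 1, len(fb_df))
        spec = FeatureSpec(classes=("linear",), beta=0.3)
        jk = jackknife_gains(fp_df, fb_df, spec)
        for v in jk.without:
            assert jk.without[v] <= jk.full_gain + 1e-6
        assert jk.with_only["noise"] < 0.05
        assert jk.without["a"] == pytest.approx(jk.full_gain, abs=0.05)

    def test_evaluate_reports_auc_and_tss(self):
        fp, fb = gibbs_instance(500, 1500, [2.0, -1.0], seed=12)
        cols = ["a", "b"]
        fp_df, fb_df = pd.DataFrame(fp, columns=cols), pd.DataFrame(fb, columns=cols)
        m = fit(fp_df.iloc[:1000], fb_df, FeatureSpec(classes=("linear",), beta=0.2))
        rep = evaluate(m, fp_df.iloc[:1000], fp_df.iloc[1000:], fb_df)
        assert 0.5 < rep.auc_train <= 1.0
        assert 0.5 < rep.auc_test <= 1.0
        assert -1.0 <= rep.tss <= 1.0


class TestResponseCurve:
    def test_positive_linear_weight_gives_monotone_curve(self):
        fp, fb = gibbs_instance(400, 2000, [3.0], seed=13)
        m = fit(pd.DataFrame(fp, columns=["a"]), pd.DataFrame(fb, columns=["a"]),
                FeatureSpec(classes=("linear",), beta=0.2))
        rc = response_curve(m, "a")
        assert (np.diff(rc.suitability) >= -1e-12).all()

    def test_threshold_above_maximum_gives_empty_range(self):
        fp, fb = gibbs_instance(400, 2000, [0.5], seed=14)
        m = fit(pd.DataFrame(fp, columns=["a"]), pd.DataFrame(fb, columns=["a"]),
                FeatureSpec(classes=("linear",), beta=0.5))
        rc = response_curve(m, "a", threshold=1.1)
        assert rc.optimal_intervals == []

    def test_quadratic_truth_peak_recovered(self):
        # presences concentrated around a = 0.6
        rng = np.random.default_rng(15)
        fb = pd.DataFrame({"a": rng.uniform(0, 1, 3000)})
        eta = -30 * (fb["a"] - 0.6) ** 2
        p = np.exp(eta) / np.exp(eta).sum()
        fp = fb.iloc[rng.choice(len(fb), 2000, p=p)]
        m = fit(fp, fb, FeatureSpec(classes=("linear", "quadratic"), beta=0.2))
        rc = response_curve(m, "a", threshold=0.239)
        assert rc.optimal_intervals
        lo = min(i[0] for i in rc.optimal_intervals)
        hi = max(i[1] for i in rc.optimal_intervals)
        assert lo <= 0.6 <= hi

    def test_unknown_variable_raises(self):
        fp, fb = gibbs_instance(100, 300, [1.0], seed=16)
        m = fit(pd.DataFrame(fp, columns=["a"]), pd.DataFrame(fb, columns=["a"]), LINEAR)
        with pytest.raises(KeyError):
            response_curve(m, "zz")
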