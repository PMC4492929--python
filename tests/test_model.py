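"""Linear formula evaluation, weight fitting, CV, trimming, dielectric scan."""

import numpy as np
import pandas as pd
import pytest

import ddgbind as dg
from ddgbind.model import (load_default_weights, DEFAULT_CV_SEED,
                           DielectricScanResult)
from ddgbind.terms import TERM_NAMES, MissingTermError
from ddgbind.surface import LocationClass


def _terms(value=0.0):
    return {name: value for name in TERM_NAMES}


class TestPredict:
    def test_zero_terms_give_intercept(self):
        weights = load_default_weights()["all"]
        assert dg.predict_ddg(_terms(0.0), weights) == pytest.approx(1.81729)

    def test_all_zero_weights(self):
        ws = dg.WeightSet(w0=0.0, weights={})
        assert dg.predict_ddg(_terms(1.0), ws) == 0.0

    def test_unit_terms_sum_the_weights(self):
        weights = load_default_weights()["large"]
        expected = weights.w0 + sum(weights.weights.values())
        assert dg.predict_ddg(_terms(1.0), weights) == pytest.approx(expected)

    def test_missing_required_term_named(self):
        weights = load_default_weights()["all"]
        terms = _terms(1.0)
        terms["dd_sp"] = None
        with pytest.raises(MissingTermError, match="dd_sp"):
            dg.predict_ddg(terms, weights)

    def test_linearity(self):
        ws = load_default_weights()["all"]
        rng = np.random.default_rng(0)
        a = {n: rng.normal() for n in TERM_NAMES}
        b = {n: rng.normal() for n in TERM_NAMES}
        ab = {n: a[n] + b[n] for n in TERM_NAMES}
        assert dg.predict_ddg(ab, ws) == pytest.approx(
            dg.predict_ddg(a, ws) + dg.predict_ddg(b, ws) - ws.w0)


class TestPredictAuto:
    def _tables(self, p):
        cor = LocationClass.COR
        return dg.ProbabilityTables(
            wt_residue={"A": (1 - p, p, 1)}, mt_residue={"G": (1 - p, p, 1)},
            wt_location={cor: (1 - p, p, 1)}, mt_location={cor: (1 - p, p, 1)})

    @pytest.mark.parametrize("p,expected_subset", [
        (0.24, "small"), (0.555, "large"), (0.5, "large")])
    def test_routing(self, p, expected_subset):
        ws_small = dg.WeightSet(w0=-1.0, weights={}, subset="small")
        ws_large = dg.WeightSet(w0=+1.0, weights={}, subset="large")
        ann = dg.MutationAnnotation("A", "G", LocationClass.COR,
                                    LocationClass.COR)
        ddg, subset, p_out = dg.predict_auto(
            _terms(0.0), ann, self._tables(p), ws_small, ws_large)
        assert subset == expected_subset
        assert p_out == pytest.approx(p)
        assert ddg == (1.0 if expected_subset == "large" else -1.0)


class TestFitWeights:
    def _simulate(self, n, noise_sd, seed=101):
        config = dg.SimulationConfig(
            n_cases=n, true_weights=load_default_weights()["all"],
            noise_sd=noise_sd, seed=seed)
        return dg.simulate_dataset(config)

    def test_noiseless_recovery_is_exact(self):
        features, ddg, _ = self._simulate(200, 0.0)
        fit = dg.fit_weights(features, ddg)
        truth = load_default_weights()["all"]
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-10)
        assert fit.weights.w0 == pytest.approx(truth.w0, rel=1e-8, abs=1e-10)
        for name in TERM_NAMES:
            assert fit.weights.weights[name] == pytest.approx(
                truth.weights[name], rel=1e-6, abs=1e-10), name

    def test_insufficient_data_rejected(self):
        features, ddg, _ = self._simulate(30, 0.0)
        with pytest.raises(ValueError, match="insufficient"):
            dg.fit_weights(features.iloc[:11], ddg.iloc[:11])

    def test_collinear_terms_named(self):
        features, ddg, _ = self._simulate(50, 0.0)
        features = features.copy()
        features["dd_ve"] = 2.0 * features["dd_ee"]
        with pytest.raises(ValueError, match="dd_e"):
            dg.fit_weights(features, ddg)

    def test_residuals_orthogonal_to_design(self):
        features, ddg, _ = self._simulate(300, 0.5)
        fit = dg.fit_weights(features, ddg)
        resid = np.asarray(ddg) - fit.fitted
        for name in TERM_NAMES:
            dot = float(np.dot(resid, features[name]))
            assert abs(dot) / len(resid) < 1e-6, name

    def test_noisy_recovery_within_standard_errors(self):
        """sigma=0.5, n=1000: every weight within 3 SE of the truth."""
        features, ddg, _ = self._simulate(1000, 0.5, seed=7)
        fit = dg.fit_weights(features, ddg)
        truth = load_default_weights()["all"]
        # standard error of each coefficient: sigma / (sqrt(n) * sd_x)
        for name in TERM_NAMES:
            sd_x = features[name].std()
            se = 0.5 / (np.sqrt(len(ddg)) * sd_x)
            assert abs(fit.weights.weights[name] - truth.weights[name]) \
                < 3 * se, name


class TestCrossValidate:
    def test_fold_sizes_near_equal(self):
        features, ddg, _ = dg.simulate_dataset(dg.SimulationConfig(
            n_cases=1326, true_weights=load_default_weights()["all"],
            noise_sd=0.0, seed=3))
        from sklearn.model_selection import KFold
        sizes = sorted(len(test) for _, test in
                       KFold(5, shuffle=True,
                             random_state=DEFAULT_CV_SEED).split(ddg))
        assert sizes == [265, 265, 265, 265, 266]

    def test_noiseless_mean_r_is_one(self):
        features, ddg, _ = dg.simulate_dataset(dg.SimulationConfig(
            n_cases=120, true_weights=load_default_weights()["all"],
            noise_sd=0.0, seed=4))
        mean_r, fold_rs = dg.cross_validate(features, ddg, k=5, seed=1)
        assert mean_r == pytest.approx(1.0, abs=1e-8)
        assert len(fold_rs) == 5

    def test_deterministic_given_seed(self):
        features, ddg, _ = dg.simulate_dataset(dg.SimulationConfig(
            n_cases=150, true_weights=load_default_weights()["all"],
            noise_sd=0.8, seed=5))
        r1, folds1 = dg.cross_validate(features, ddg, k=5, seed=99)
        r2, folds2 = dg.cross_validate(features, ddg, k=5, seed=99)
        assert r1 == r2 and folds1 == folds2


class TestTrim2SD:
    def test_perfect_line_unchanged(self):
        x = np.linspace(0, 5, 30)
        mask, r = dg.trim_2sd(x, 2 * x + 1)
        assert mask.all() and r == pytest.approx(1.0)

    def test_gross_outlier_dropped(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 5, 40)
        y = x + rng.normal(0, 0.1, size=40)
        y[13] += 30 * 0.1 * 10  # a >10-SD outlier
        mask, r = dg.trim_2sd(x, y)
        assert not mask[13]
        assert mask.sum() == 39
        assert r > 0.99

    def test_degenerate_predictions_rejected(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            dg.trim_2sd(np.ones(20), np.linspace(0, 1, 20))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dg.trim_2sd(np.arange(5), np.arange(5))


class TestDielectricScan:
    def test_single_point_grid(self):
        provider, ddg = dg.make_dielectric_scan_problem(n_cases=100, seed=2)
        res = dg.scan_dielectrics(provider, ddg, eps1_values=(9,),
                                  eps2_values=(8,), eps3_values=(7,))
        assert res.r_grid.shape == (1, 1, 1)
        assert res.best == (9, 8, 7)

    def test_planted_optimum_recovered_on_coarse_grid(self):
        provider, ddg = dg.make_dielectric_scan_problem(n_cases=200, seed=3)
        res = dg.scan_dielectrics(provider, ddg,
                                  eps1_values=(5, 9, 13),
                                  eps2_values=(6, 8, 10),
                                  eps3_values=(3, 7, 11))
        assert np.isfinite(res.r_grid).all()
        assert res.best == (9, 8, 7)
        assert res.best_r == res.r_grid.max()

    def test_provider_required(self):
        with pytest.raises(ValueError):
            dg.scan_dielectrics(None, [1.0, 2.0])
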