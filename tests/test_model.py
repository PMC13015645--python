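"""Random-forest LUR: metric identities, cross-validation integrity,
signal recovery and bias profiles."""

import numpy as np
import pandas as pd
import pytest

import roadproxy as rp
from roadproxy.model import ModelSpec, _metrics, binned_bias, fit_rf_cv, run_model_suite


def _table(rng, n=300, noise=0.0):
    wrnd = rng.uniform(0, 30, n)
    em = rng.uniform(0, 5, n)
    eh = rng.uniform(0, 8, n)
    pm = 10 + 2.5 * wrnd + rng.normal(0, noise, n)
    return pd.DataFrame({"wrnd_kmkm2": wrnd, "em_km": em, "eh_km": eh, "pm25": pm})


class TestMetricIdentities:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = _metrics(y, y.copy())
        assert m["rmse"] == 0 and m["mae"] == 0 and m["mbe"] == 0 and m["r2"] == 1.0

    def test_constant_shift(self):
        y = np.array([10.0, 20.0, 30.0])
        m = _metrics(y, y + 5)
        assert m["mbe"] == pytest.approx(5.0)
        assert m["mae"] == pytest.approx(5.0)
        assert m["rmse"] == pytest.approx(5.0)

    def test_rmse_dominates_mae_and_abs_mbe(self, rng):
        for _ in range(20):
            y = rng.normal(size=50)
            yhat = rng.normal(size=50)
            m = _metrics(y, yhat)
            assert m["rmse"] >= m["mae"] >= 0
            assert m["rmse"] >= abs(m["mbe"])


class TestModelSpec:
    def test_mtry_floor_sqrt(self):
        assert ModelSpec(features=("WRND",)).mtry == 1
        assert ModelSpec(features=("WRND", "EM", "EH")).mtry == 1
        with pytest.raises(ValueError):
            ModelSpec(features=())
        with pytest.raises(ValueError):
            ModelSpec(features=("XX",))

    def test_names(self):
        assert ModelSpec(features=("EH",)).name == "EH"
        assert ModelSpec(features=("WRND", "EM", "EH")).name == "Combined"


class TestFitRfCv:
    def test_single_feature_signal_recovered(self, rng):
        data = _table(rng, n=300, noise=0.0)
        res = fit_rf_cv(data, ModelSpec(features=("WRND",), seed=0))
        assert res.r2 >= 0.95
        assert res.importances is None

    def test_pure_noise_has_no_skill(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            data = _table(rng, n=120)
            data["pm25"] = rng.normal(30, 5, len(data))  # independent of features
            res = fit_rf_cv(data, ModelSpec(features=("WRND", "EM", "EH"), seed=seed))
            assert res.r2 <= 0.1

    def test_out_of_fold_predictions_complete_and_deterministic(self, rng):
        data = _table(rng, n=90, noise=5.0)
        spec = ModelSpec(features=("WRND", "EM"), seed=3)
        a = fit_rf_cv(data, spec)
        b = fit_rf_cv(data, spec)
        assert np.isfinite(a.oof_predictions).all()
        assert a.oof_predictions.size == len(data)
        assert np.array_equal(a.oof_predictions, b.oof_predictions)
        assert (a.r2, a.rmse, a.mae, a.mbe) == (b.r2, b.rmse, b.mae, b.mbe)
        assert len(a.per_fold_metrics) == 3
        assert sum(m["n"] for m in a.per_fold_metrics) == len(data)

    def test_too_few_observations_rejected(self, rng):
        data = _table(rng, n=2)
        with pytest.raises(ValueError):
            fit_rf_cv(data, ModelSpec(features=("WRND",), n_folds=3))

    def test_missing_values_rejected(self, rng):
        data = _table(rng, n=30)
        data.loc[0, "em_km"] = np.nan
        with pytest.raises(ValueError):
            fit_rf_cv(data, ModelSpec(features=("WRND", "EM")))

    def test_importances_sum_to_one(self, rng):
        data = _table(rng, n=200, noise=3.0)
        res = fit_rf_cv(data, ModelSpec(features=("WRND", "EM", "EH"), seed=1))
        imp = rp.feature_importance(res)
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in imp.values())

    def test_dominant_feature_gets_top_importance(self, rng):
        # pm25 depends only on eh
        n = 200
        data = pd.DataFrame({
            "wrnd_kmkm2": rng.uniform(0, 30, n),
            "em_km": rng.uniform(0, 5, n),
            "eh_km": rng.uniform(0, 8, n),
        })
        data["pm25"] = 50 * np.exp(-data["eh_km"] / 2) + rng.normal(0, 1, n)
        res = fit_rf_cv(data, ModelSpec(features=("WRND", "EM", "EH"), seed=2))
        imp = rp.feature_importance(res)
        assert max(imp, key=imp.get) == "EH"

    def test_single_feature_importance_errors(self, rng):
        res = fit_rf_cv(_table(rng, n=60), ModelSpec(features=("WRND",)))
        with pytest.raises(ValueError):
            rp.feature_importance(res)

    def test_permuted_feature_control(self, rng):
        """A model on the true EH feature beats one on permuted EH."""
        n = 240
        data = pd.DataFrame({
            "wrnd_kmkm2": rng.uniform(0, 30, n),
            "em_km": rng.uniform(0, 5, n),
            "eh_km": rng.uniform(0, 8, n),
        })
        data["pm25"] = 60 * np.exp(-data["eh_km"] / 2) + rng.normal(0, 2, n)
        r_true = fit_rf_cv(data, ModelSpec(features=("EH",), seed=0))
        perm = data.copy()
        perm["eh_km"] = rng.permutation(perm["eh_km"].values)
        r_perm = fit_rf_cv(perm, ModelSpec(features=("EH",), seed=0))
        assert r_true.r2 - r_perm.r2 >= 0.2


class TestModelSuite:
    def test_enumeration_with_strata(self, rng):
        data = _table(rng, n=90, noise=5.0)
        strata = ["A"] * 30 + ["B"] * 30 + ["C"] * 30
        results = run_model_suite(data, strata=strata, seed=0)
        assert len(results) == 16  # 4 models x (3 strata + global)
        names = [(r.spec.stratum, r.spec.name) for r in results]
        assert ("global", "Combined") in names
        table = rp.metrics_table(results)
        assert len(table) == 16


class TestBinnedBias:
    def test_zero_and_constant_shift(self, rng):
        y = rng.uniform(0, 100, 200)
        prof = binned_bias(y.copy(), y, seed=0, n_boot=200)
        assert np.nanmax(np.abs(prof.mean_bias)) == 0
        prof5 = binned_bias(y + 5, y, seed=0, n_boot=200)
        finite = np.isfinite(prof5.mean_bias)
        assert np.allclose(prof5.mean_bias[finite], 5.0)
        assert np.allclose(prof5.median_bias[finite], 5.0)

    def test_matches_groupby_oracle_and_normal_ci(self, rng):
        y = rng.uniform(0, 100, 400)
        yhat = y + rng.normal(0, 8, 400)
        prof = binned_bias(yhat, y, bin_width=20.0, n_boot=2000, seed=1)
        bias = yhat - y
        bins = np.floor(y / 20).astype(int)
        for b in range(prof.bin_edges.size - 1):
            sel = bias[bins == b]
            if sel.size == 0:
                continue
            assert prof.mean_bias[b] == pytest.approx(sel.mean(), abs=1e-12)
            assert prof.median_bias[b] == pytest.approx(np.median(sel), abs=1e-12)
            if sel.size >= 30:
                half = 1.96 * sel.std(ddof=1) / np.sqrt(sel.size)
                boot_half = (prof.ci95_high[b] - prof.ci95_low[b]) / 2
                assert boot_half == pytest.approx(half, rel=0.2)
        assert prof.n_per_bin.sum() == 400
        assert np.all(prof.ci95_low[np.isfinite(prof.ci95_low)]
                      <= prof.mean_bias[np.isfinite(prof.ci95_low)])

    def test_sparse_bins_flagged(self):
        y = np.array([1.0, 2.0, 50.0])
        prof = binned_bias(y + 1, y, bin_width=20.0, n_boot=50, seed=0)
        assert prof.sparse_bins[prof.n_per_bin < 3].all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binned_bias(np.array([]), np.array([]))
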