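"""Path analysis: ML estimation, mediation, fit indices, pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multidiv import PathModel, PathModelSpec, simulate_path_data
from multidiv.pathmodel import standardize, stepwise_exogenous_pruning

MEDIATORS = ("vascular_plants", "bryophytes", "invertebrates", "fungi", "bacteria")
SPEC = PathModelSpec(exogenous=("time", "temperature"), mediators=MEDIATORS)


@pytest.fixture(scope="module")
def big_fit():
    data, truth = simulate_path_data(n=2000, seed=7)
    return PathModel(data, SPEC).fit(), truth


class TestEstimation:
    def test_recovers_known_coefficients(self, big_fit):
        fit, truth = big_fit
        for exo, paths in truth["a"].items():
            for med, val in paths.items():
                assert fit.estimate(("a", exo, med)) == pytest.approx(val, abs=0.05)
        for med, val in truth["b"].items():
            assert fit.estimate(("b", med)) == pytest.approx(val, abs=0.05)
        for pair, val in truth["residual_cov"].items():
            m1, m2 = pair.split("~~")
            assert fit.estimate(("psi", m1, m2)) == pytest.approx(val, abs=0.05)

    def test_matches_equation_by_equation_ols(self, big_fit):
        # for this recursive model with identical regressors per block, ML on
        # the covariance equals per-equation OLS -- an independent oracle
        fit, _ = big_fit
        d = fit.model.data
        X = np.column_stack([np.ones(len(d)), d["time"], d["temperature"]])
        for med in MEDIATORS:
            coef, *_ = np.linalg.lstsq(X, d[med].to_numpy(), rcond=None)
            assert fit.estimate(("a", "time", med)) == pytest.approx(coef[1], abs=1e-3)
            assert fit.estimate(("a", "temperature", med)) == pytest.approx(
                coef[2], abs=1e-3
            )

    def test_null_data_gives_null_paths(self, rng):
        cols = ["time", "temperature", *MEDIATORS, "mD"]
        data = pd.DataFrame(rng.normal(0, 1, (800, len(cols))), columns=cols)
        fit = PathModel(data, SPEC).fit()
        paths = fit.path_coefficients()
        assert np.abs(paths["estimate"]).max() < 0.12
        assert np.abs(fit.residual_covariances()["estimate"]).max() < 0.12

    def test_saturated_model_chi2_zero(self, rng):
        spec = PathModelSpec(
            exogenous=("time", "temperature"), mediators=MEDIATORS,
            include_direct=True,
        )
        data, _ = simulate_path_data(n=300, seed=3)
        fit = PathModel(data, spec).fit()
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-4)
        fi = fit.fit_indices()
        assert fi["cfi"] == pytest.approx(1.0)
        assert fi["saturated"]

    def test_deterministic_refits(self):
        data, _ = simulate_path_data(n=200, seed=5)
        a = PathModel(data, SPEC).fit()
        b = PathModel(data, SPEC).fit()
        assert np.array_equal(a.theta, b.theta)

    def test_standardize_guard(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            standardize(df)


class TestIndirectEffects:
    def test_zero_b_paths_zero_indirect(self, rng):
        # outcome independent of mediators: indirect effects vanish
        data, _ = simulate_path_data(n=1500, seed=9)
        data["mD"] = rng.normal(0, 1, len(data))
        fit = PathModel(data, SPEC).fit()
        ind = fit.indirect_effects()
        assert np.abs(ind["indirect"]).max() < 0.06

    def test_sum_of_products_identity(self, big_fit):
        # indirect effect equals sum(a_i * b_i) of the extracted paths exactly
        fit, _ = big_fit
        ind = fit.indirect_effects().set_index("exogenous")["indirect"]
        for exo in SPEC.exogenous:
            acc = sum(
                fit.estimate(("a", exo, med)) * fit.estimate(("b", med))
                for med in MEDIATORS
            )
            assert ind[exo] == pytest.approx(acc, abs=1e-12)

    def test_two_mediator_arithmetic(self):
        # a = (0.5, 0.2), b = (0.4, 0.1) -> indirect = 0.2 + 0.02 = 0.22
        a = {"x": {"m1": 0.5, "m2": 0.2}}
        b = {"m1": 0.4, "m2": 0.1}
        data, truth = simulate_path_data(n=500, a=a, b=b, seed=11, exo_corr=0.0)
        assert truth["indirect"]["x"] == pytest.approx(0.22)

    def test_delta_se_close_to_bootstrap(self):
        data, _ = simulate_path_data(n=500, seed=13)
        fit = PathModel(data, SPEC).fit()
        ind = fit.indirect_effects(bootstrap=200, seed=1)
        for _, row in ind.iterrows():
            assert abs(row["se"] - row["se_boot"]) < 0.15 * row["se_boot"]


class TestFitIndices:
    def test_correct_model_limit(self, big_fit):
        fit, _ = big_fit
        fi = fit.fit_indices()
        assert fi["rmsea"] < 0.03
        assert fi["srmr"] < 0.02
        assert fi["cfi"] > 0.99

    def test_formula_oracle(self, big_fit):
        # recompute every index from chi2/df with independent formulas
        fit, _ = big_fit
        fi = fit.fit_indices()
        n, chi2, df = fit.model.n, fit.chi2, fit.df
        chi2_b, df_b = fit._baseline()
        d_t, d_b = max(chi2 - df, 0), max(chi2_b - df_b, 0)
        assert fi["cfi"] == pytest.approx(1 - d_t / max(d_b, d_t), abs=1e-12)
        assert fi["tli"] == pytest.approx(
            (chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1), abs=1e-12
        )
        assert fi["rmsea"] == pytest.approx(np.sqrt(d_t / (df * (n - 1))), abs=1e-12)
        # SRMR by explicit loop over standardized residuals
        S, Sig = fit.model.S, fit.implied
        p = S.shape[0]
        acc = []
        for i in range(p):
            for j in range(i, p):
                acc.append(((S[i, j] - Sig[i, j]) / np.sqrt(S[i, i] * S[j, j])) ** 2)
        assert fi["srmr"] == pytest.approx(np.sqrt(np.mean(acc)), abs=1e-12)
        # RMSEA CI endpoints invert the noncentral-chi2 coverage
        lam_lo = fi["rmsea_ci_lower"] ** 2 * df * (n - 1)
        if lam_lo > 0:
            assert stats.ncx2.sf(chi2, df, lam_lo) == pytest.approx(0.05, abs=1e-4)

    def test_worse_nested_model_has_worse_indices(self):
        data, _ = simulate_path_data(n=800, seed=17)
        good = PathModel(data, SPEC).fit()
        # constrain the time->mediator paths to zero: misspecified nested model
        bad_spec = PathModelSpec(
            exogenous=("time", "temperature"), mediators=MEDIATORS,
            zero_paths=tuple(("time", m) for m in MEDIATORS),
        )
        bad = PathModel(data, bad_spec).fit()
        assert bad.fit_indices()["rmsea"] > good.fit_indices()["rmsea"]
        assert bad.fit_indices()["srmr"] > good.fit_indices()["srmr"]


class TestPruning:
    def _data_with_extras(self, ph_effect=0.0, n=600, seed=22):
        a = {
            "time": {m: c for m, c in zip(MEDIATORS, (0.5, 0.6, 0.4, 0.3, 0.35))},
            "temperature": {m: c for m, c in zip(MEDIATORS, (0.2, 0.1, 0.3, 0.25, 0.15))},
            "ph": {m: 0.0 for m in MEDIATORS},
            "nutrients": {m: 0.0 for m in MEDIATORS},
        }
        a["ph"]["bryophytes"] = ph_effect
        b = {m: c for m, c in zip(MEDIATORS, (0.25, 0.2, 0.2, 0.15, 0.2))}
        data, _ = simulate_path_data(n=n, a=a, b=b, seed=seed, exo_corr=0.2)
        return data

    def test_null_exogenous_pruned(self):
        data = self._data_with_extras(ph_effect=0.0)
        full = PathModelSpec(
            exogenous=("time", "temperature", "ph", "nutrients"), mediators=MEDIATORS
        )
        reduced, trail = stepwise_exogenous_pruning(
            data, full, prunable=("ph", "nutrients")
        )
        assert set(reduced.exogenous) == {"time", "temperature"}
        assert sum(t["action"] == "remove" for t in trail) == 2

    def test_effective_exogenous_retained(self):
        data = self._data_with_extras(ph_effect=0.5)
        full = PathModelSpec(
            exogenous=("time", "temperature", "ph", "nutrients"), mediators=MEDIATORS
        )
        reduced, trail = stepwise_exogenous_pruning(
            data, full, prunable=("ph", "nutrients")
        )
        assert "ph" in reduced.exogenous
        assert "nutrients" not in reduced.exogenous

    def test_pruning_order_invariant(self):
        data = self._data_with_extras(ph_effect=0.0, seed=23)
        full = PathModelSpec(
            exogenous=("time", "temperature", "ph", "nutrients"), mediators=MEDIATORS
        )
        r1, _ = stepwise_exogenous_pruning(data, full, prunable=("ph", "nutrients"))
        r2, _ = stepwise_exogenous_pruning(data, full, prunable=("nutrients", "ph"))
        assert set(r1.exogenous) == set(r2.exogenous)

    def test_unknown_prunable_rejected(self):
        data = self._data_with_extras()
        with pytest.raises(ValueError, match="not in the model"):
            stepwise_exogenous_pruning(data, SPEC, prunable=("ph",))
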