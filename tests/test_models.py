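"""Built-in MLR models, OLS fitting and GA descriptor selection."""
import itertools

import numpy as np
import pandas as pd
import pytest

from azoleqsar import (
    DescriptorVector,
    GAConfig,
    ModelSpec,
    builtin_models,
    fit_ols,
    ga_select,
    gen_descriptor_matrix,
    gen_response,
    predict,
    q2_loo,
)
from azoleqsar.errors import CollinearityError, MissingDescriptorError, UnitsError
from azoleqsar.models import RatioRuleWarning


@pytest.fixture(scope="module")
def models():
    return {m.name: m for m in builtin_models()}


class TestBuiltinModels:
    def test_four_models_with_printed_coefficients(self, models):
        assert len(models) == 4
        tri = models["triazole_antagonist"]
        assert tri.intercept == 1.4676
        assert dict(tri.terms)["omega_HF"] == 488.5007
        assert dict(tri.terms)["E_LUMO_PM7"] == 4.3535
        assert dict(tri.terms)["Eta_shape_Y"] == 5.6602
        dia = models["diazole_antagonist"]
        assert dict(dia.terms)["NRS"] == -0.6724
        assert dict(dia.terms)["E_HOMONL_PM7"] == -22.4173
        assert dict(dia.terms)["ETA_etaP_B"] == -103.9622
        ago = models["diazole_agonist"]
        assert dict(ago.terms)["Qmax_pos_PM7"] == -0.7252
        assert dict(ago.terms)["Eta_dAlpha_B"] == -19.4372
        assert dict(ago.terms)["Eta_betans_d"] == 1.1130
        thi = models["thiazole_agonist"]
        assert dict(thi.terms)["GGI9"] == -8.0767
        assert dict(thi.terms)["F03_C_C"] == 0.1177
        assert dict(thi.terms)["F04_N_O"] == 0.5873

    def test_activity_types(self, models):
        assert models["triazole_antagonist"].activity == "pIC50"
        assert models["thiazole_agonist"].activity == "pEC50"

    def test_json_round_trip(self, models):
        spec = models["diazole_antagonist"]
        again = ModelSpec.from_json(spec.to_json())
        assert again == spec


class TestPredict:
    def test_zero_descriptors_return_intercepts(self, models):
        for m in models.values():
            zeros = {name: 0.0 for name in m.descriptor_names}
            assert predict(m, zeros) == pytest.approx(m.intercept)

    def test_diazole_antagonist_arithmetic(self, models):
        m = models["diazole_antagonist"]
        d = {"E_HOMONL_PM7": -0.35, "ETA_etaP_B": 0.01, "NRS": 2.0}
        expected = 3.5936 + 22.4173 * 0.35 - 103.9622 * 0.01 - 0.6724 * 2
        assert predict(m, d) == pytest.approx(expected)

    def test_thiazole_agonist_arithmetic(self, models):
        m = models["thiazole_agonist"]
        d = {"GGI9": 0.0, "F03_C_C": 10.0, "F04_N_O": 1.0}
        assert predict(m, d) == pytest.approx(7.3704 + 1.177 + 0.5873)

    def test_missing_descriptor_named(self, models):
        with pytest.raises(MissingDescriptorError, match="NRS"):
            predict(models["diazole_antagonist"], {"E_HOMONL_PM7": 0.0,
                                                   "ETA_etaP_B": 0.0})

    def test_unit_mismatch_refused(self, models):
        m = models["triazole_antagonist"]
        d = DescriptorVector(
            values={"omega_HF": 0.05, "E_LUMO_PM7": -1.0, "Eta_shape_Y": 0.1},
            units={"omega_HF": ("HF", "eV")},  # model expects hartree
        )
        with pytest.raises(UnitsError):
            predict(m, d)

    def test_linearity_in_descriptors(self, models):
        m = models["thiazole_agonist"]
        rng = np.random.default_rng(0)
        d1 = dict(zip(m.descriptor_names, rng.normal(size=3)))
        d2 = dict(zip(m.descriptor_names, rng.normal(size=3)))
        a, b = 0.3, 1.7
        mix = {k: a * d1[k] + b * d2[k] for k in d1}
        lhs = predict(m, mix) - m.intercept
        rhs = a * (predict(m, d1) - m.intercept) + b * (predict(m, d2) - m.intercept)
        assert lhs == pytest.approx(rhs)


class TestFitOls:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x1", "x2"])
        y = 2 + 3 * X["x1"] - X["x2"]
        fit = fit_ols(X, y)
        assert fit.model.intercept == pytest.approx(2.0, abs=1e-10)
        assert dict(fit.model.terms)["x1"] == pytest.approx(3.0, abs=1e-10)
        assert dict(fit.model.terms)["x2"] == pytest.approx(-1.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 2))
        fit = fit_ols(X, np.full(25, 3.3))
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert all(abs(c) < 1e-10 for _, c in fit.model.terms)

    def test_noisy_recovery_within_3_se(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        beta = np.array([1.5, -2.0])
        y = 0.5 + X @ beta + rng.normal(0, 0.1, 30)
        fit = fit_ols(X, y)
        d = np.column_stack([np.ones(30), X])
        s2 = fit.residuals @ fit.residuals / (30 - 3)
        se = np.sqrt(s2 * np.diag(np.linalg.inv(d.T @ d)))
        est = np.array([fit.model.intercept] + [c for _, c in fit.model.terms])
        assert np.all(np.abs(est - np.array([0.5, 1.5, -2.0])) < 3 * se)

    def test_collinearity_names_columns(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        X["c"] = X["a"] + X["b"]
        with pytest.raises(CollinearityError) as err:
            fit_ols(X, rng.normal(size=20))
        assert any(name in str(err.value) for name in ("a", "b", "c"))

    def test_ratio_rule_warning(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))  # ratio 4 < 5
        with pytest.warns(RatioRuleWarning):
            fit_ols(X, rng.normal(size=12))

    def test_builtin_coefficients_recovered_from_synthetic_data(self):
        model = builtin_models()[1]  # diazole antagonist
        X, _ = gen_descriptor_matrix(
            26, 3, seed=7, names=model.descriptor_names,
            loc=[-0.35, 0.008, 3.0], scale=[0.03, 0.004, 0.9],
        )
        y, _ = gen_response(X, model, sigma=0.0, seed=7)
        fit = fit_ols(X, y)
        assert fit.model.intercept == pytest.approx(model.intercept, abs=1e-4)
        for name, coef in model.terms:
            assert dict(fit.model.terms)[name] == pytest.approx(coef, abs=1e-4)


class TestGaSelect:
    def _planted(self, n=60, p=20, sigma=0.3, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"x{i}" for i in range(p)])
        y = 1.0 + 2.5 * X["x0"] - 1.8 * X["x1"] + 3.1 * X["x2"]
        y = y + rng.normal(0, sigma, n)
        return X, y

    def test_matches_brute_force_on_small_space(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=list("abcde"))
        y = 0.3 + X["a"] - 2 * X["c"] + rng.normal(0, 0.5, 40)
        best_bf = max(
            itertools.combinations(range(5), 3),
            key=lambda cols: q2_loo(X.iloc[:, list(cols)], y),
        )
        res = ga_select(X, y, k=3, config=GAConfig(population=30, generations=20,
                                                   seed=1))
        assert set(res.subset) == {X.columns[i] for i in best_bf}

    def test_recovers_planted_informative_columns(self):
        X, y = self._planted()
        res = ga_select(X, y, k=3,
                        config=GAConfig(population=50, generations=40, seed=2))
        assert set(res.subset) == {"x0", "x1", "x2"}

    def test_deterministic_given_seed(self):
        X, y = self._planted(seed=3)
        cfg = GAConfig(population=30, generations=15, seed=42)
        r1 = ga_select(X, y, k=3, config=cfg)
        r2 = ga_select(X, y, k=3, config=cfg)
        assert r1.subset == r2.subset
        assert r1.q2_loo == r2.q2_loo
        assert r1.fit.model.terms == r2.fit.model.terms

    def test_beats_random_restart_hill_climb(self):
        X, y = self._planted(n=50, p=12, sigma=1.5, seed=4)
        Xm = X.to_numpy()

        def hill_climb(seed, budget):
            rng = np.random.default_rng(seed)
            evals = 0
            best, best_q = None, -np.inf
            while evals < budget:
                cur = tuple(sorted(rng.choice(12, 3, replace=False)))
                cur_q = q2_loo(Xm[:, list(cur)], y)
                evals += 1
                improved = True
                while improved and evals < budget:
                    improved = False
                    for drop in cur:
                        for add in range(12):
                            if add in cur:
                                continue
                            cand = tuple(sorted(set(cur) - {drop} | {add}))
                            q = q2_loo(Xm[:, list(cand)], y)
                            evals += 1
                            if q > cur_q:
                                cur, cur_q, improved = cand, q, True
                                break
                        if improved:
                            break
                if cur_q > best_q:
                    best, best_q = cur, cur_q
            return best_q

        baseline = hill_climb(seed=0, budget=600)
        res = ga_select(X, y, k=3,
                        config=GAConfig(population=30, generations=20, seed=0))
        assert res.q2_loo >= baseline - 1e-9

    def test_upto_mode_and_infeasible_k(self):
        X, y = self._planted(n=60, p=8, seed=5)
        res = ga_select(X, y, k=4, mode="upto",
                        config=GAConfig(population=30, generations=20, seed=6))
        assert 1 <= len(res.subset) <= 4
        with pytest.raises(ValueError):
            ga_select(X, y, k=9)
        with pytest.raises(ValueError):  # ratio rule: n/k < 5
            ga_select(X.iloc[:12], y[:12], k=3)
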