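"""FIML likelihood, optimizer, and profile CIs against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from twinprs import (FitOptions, ModelParams, SimConfig, fiml_neg2ll,
                     fit_model, profile_ci, simulate_pairs)
from twinprs.fiml import PatternData
from twinprs.moments import build_saturated, build_univariate_ace


@pytest.fixture(scope="module")
def small_complete():
    data, _ = simulate_pairs(SimConfig(n_mz=50, n_dz=60, n_sib=70, seed=3))
    return data


def mvn_oracle(model, data, theta, groups=("MZ", "DZ", "SIB")):
    """Independent -2LL: scipy's multivariate-normal density summed per pair."""
    mom = model.group_moments(theta)
    total = 0.0
    for g in groups:
        X = data.member_matrix(["roi"], group=g)
        mu, S = mom[g]
        total += -2.0 * stats.multivariate_normal(mu, S).logpdf(X).sum()
    return total


class TestNeg2LL:
    def test_complete_data_matches_density_oracle(self, small_complete):
        model = build_univariate_ace("ACE")
        theta = np.array([0.1, 0.7, 0.4, 0.5])
        val = fiml_neg2ll(model, small_complete, theta, variables=["roi"])
        assert val == pytest.approx(mvn_oracle(model, small_complete, theta),
                                    abs=1e-8)

    def test_duplicated_dataset_doubles_exactly(self, small_complete):
        from twinprs.pair_data import PairDataset
        import pandas as pd
        model = build_univariate_ace("ACE")
        theta = np.array([0.1, 0.7, 0.4, 0.5])
        t2 = pd.concat([small_complete.table,
                        small_complete.table.assign(
                            family_id=small_complete.table.family_id + "b")],
                       ignore_index=True)
        doubled = PairDataset(t2, small_complete.schema)
        v1 = fiml_neg2ll(model, small_complete, theta, variables=["roi"])
        v2 = fiml_neg2ll(model, doubled, theta, variables=["roi"])
        assert v2 == pytest.approx(2 * v1, abs=1e-9)

    def test_single_member_missing_matches_marginal_oracle(self, small_complete):
        model = build_univariate_ace("ACE", groups=("MZ",))
        theta = np.array([0.1, 0.7, 0.4, 0.5])
        X = small_complete.member_matrix(["roi"], group="MZ").copy()
        X[0, 1] = np.nan
        pats = PatternData.from_arrays({"MZ": X}, 1)
        val = fiml_neg2ll(model, pats, theta)
        mu, S = model.group_moments(theta)["MZ"]
        oracle = -2 * stats.norm(mu[0], np.sqrt(S[0, 0])).logpdf(X[0, 0])
        oracle += -2 * stats.multivariate_normal(mu, S).logpdf(X[1:]).sum()
        assert val == pytest.approx(oracle, abs=1e-8)

    def test_all_missing_pair_contributes_zero(self, small_complete):
        model = build_univariate_ace("ACE", groups=("MZ",))
        theta = np.array([0.1, 0.7, 0.4, 0.5])
        X = small_complete.member_matrix(["roi"], group="MZ").copy()
        base = fiml_neg2ll(model, PatternData.from_arrays({"MZ": X}, 1), theta)
        X2 = np.vstack([X, [np.nan, np.nan]])
        pats = PatternData.from_arrays({"MZ": X2}, 1)
        assert fiml_neg2ll(model, pats, theta) == pytest.approx(base, abs=1e-10)
        assert pats.n_all_missing["MZ"] == 1
        assert pats.n_pairs["MZ"] == len(X2)

    def test_non_psd_gives_infinity(self, small_complete):
        model = build_saturated("none", groups=("MZ",))
        theta = model.start()
        theta[model.param_names.index("cov_MZ")] = 5.0  # |cov| > var
        pats = PatternData.from_dataset(small_complete, ["roi"], groups=("MZ",))
        assert fiml_neg2ll(model, pats, theta) == np.inf


class TestFitModel:
    def test_saturated_mle_matches_sample_moments(self, small_complete):
        model = build_saturated("none")
        pats = PatternData.from_dataset(small_complete, ["roi"])
        fit = fit_model(model, pats, FitOptions(n_starts=3,
                                                check_identification=False))
        assert fit.converged
        e = fit.estimates
        for g in ("MZ", "DZ", "SIB"):
            X = small_complete.member_matrix(["roi"], group=g)
            S = np.cov(X.T, bias=True)  # ML (denominator n)
            assert e[f"mu1_{g}"] == pytest.approx(X[:, 0].mean(), abs=1e-4)
            assert e[f"mu2_{g}"] == pytest.approx(X[:, 1].mean(), abs=1e-4)
            assert e[f"var1_{g}"] == pytest.approx(S[0, 0], abs=1e-4)
            assert e[f"var2_{g}"] == pytest.approx(S[1, 1], abs=1e-4)
            assert e[f"cov_{g}"] == pytest.approx(S[0, 1], abs=1e-4)

    def test_nested_minus2ll_ordering(self):
        cfg = SimConfig(params=ModelParams(a11=0.9, e11=np.sqrt(1 - 0.81)),
                        seed=21, age_effect=0, sex_effect=0, icv_effect=0,
                        pc_effects=(0.0,) * 10)
        data, _ = simulate_pairs(cfg)
        pats = PatternData.from_dataset(data, ["roi"])
        opts = FitOptions(n_starts=3, check_identification=False)
        fits = {s: fit_model(build_univariate_ace(s), pats, opts)
                for s in ("ACE", "AE", "CE", "E")}
        assert fits["E"].minus2LL > fits["AE"].minus2LL
        # submodel -2LL >= supermodel -2LL up to optimizer tolerance
        for sub in ("AE", "CE", "E"):
            assert fits[sub].minus2LL >= fits["ACE"].minus2LL - 1e-4

    def test_slot_swap_invariance(self, small_complete):
        model = build_univariate_ace("ACE")
        theta = np.array([0.1, 0.7, 0.4, 0.5])
        swapped = {}
        for g in ("MZ", "DZ", "SIB"):
            X = small_complete.member_matrix(["roi"], group=g)
            swapped[g] = X[:, ::-1]
        v1 = fiml_neg2ll(model, small_complete, theta, variables=["roi"])
        v2 = fiml_neg2ll(model, PatternData.from_arrays(swapped, 1), theta)
        assert abs(v1 - v2) < 1e-8

    def test_aic_definition(self, small_complete):
        model = build_univariate_ace("AE")
        pats = PatternData.from_dataset(small_complete, ["roi"])
        fit = fit_model(model, pats, FitOptions(n_starts=2,
                                                check_identification=False))
        assert fit.AIC == pytest.approx(fit.minus2LL + 2 * 3)

    def test_empty_data_raises(self):
        model = build_univariate_ace("ACE", groups=("MZ",))
        pats = PatternData.from_arrays({"MZ": np.empty((0, 2))}, 1)
        with pytest.raises(ValueError, match="no data"):
            fit_model(model, pats)

    def test_mcar_estimates_stay_consistent(self):
        p = ModelParams(a11=np.sqrt(0.6), c11=np.sqrt(0.15), e11=np.sqrt(0.25))
        cfg = SimConfig(n_mz=5000, n_dz=5000, n_sib=5000, params=p, seed=22,
                        missing_rate=0.2, age_effect=0, sex_effect=0,
                        icv_effect=0, pc_effects=(0.0,) * 10)
        data, _ = simulate_pairs(cfg)
        pats = PatternData.from_dataset(data, ["roi"])
        fit = fit_model(build_univariate_ace("ACE"), pats,
                        FitOptions(n_starts=3, check_identification=False))
        assert fit.converged
        # 3 Monte-Carlo SEs at this n are well under 0.05 on path scale
        assert fit.estimates["a11"] == pytest.approx(p.a11, abs=0.05)
        assert fit.estimates["c11"] == pytest.approx(p.c11, abs=0.07)
        assert fit.estimates["e11"] == pytest.approx(p.e11, abs=0.03)


class TestProfileCI:
    def test_gaussian_mean_wald_equivalence(self):
        rng = np.random.default_rng(1)
        X = rng.normal(2.0, 1.5, size=(4000, 2))
        pats = PatternData.from_arrays({"MZ": X}, 1)
        model = build_saturated("within-pair", groups=("MZ",))
        fit = fit_model(model, pats, FitOptions(n_starts=2,
                                                check_identification=False))
        lo, hi, flag = profile_ci(fit, model, pats, "mu_MZ")
        est = fit.estimates["mu_MZ"]
        v, r = fit.estimates["var_MZ"], fit.estimates["r_MZ"]
        se = np.sqrt(v * (1 + r) / (2 * len(X)))  # mean of n correlated pairs
        assert (hi - lo) == pytest.approx(2 * 1.96 * se, rel=0.01)
        assert lo < est < hi
        assert flag == ""

    def test_boundary_parameter_flagged(self):
        p = ModelParams(a11=np.sqrt(0.6), e11=np.sqrt(0.4))
        data, _ = simulate_pairs(SimConfig(params=p, seed=5, age_effect=0,
                                           sex_effect=0, icv_effect=0,
                                           pc_effects=(0.0,) * 10))
        model = build_univariate_ace("ACE")
        pats = PatternData.from_dataset(data, ["roi"])
        fit = fit_model(model, pats, FitOptions(n_starts=3,
                                                check_identification=False))
        lo, hi, flag = profile_ci(fit, model, pats, "c11")
        assert lo == 0.0
        assert "lower-boundary" in flag

    def test_requires_convergence(self, small_complete):
        from twinprs.fiml import FitResult
        bad = FitResult(estimates={}, theta=np.zeros(1), minus2LL=np.inf,
                        n_free=1, converged=False, status="x")
        with pytest.raises(ValueError, match="converged"):
            profile_ci(bad, build_univariate_ace("E"), small_complete, "e11",
                       variables=["roi"])
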