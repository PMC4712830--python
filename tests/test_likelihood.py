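"""FIML objective, implied moments and the variance-component algebra."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from twinmotion.data import compile_dataset
from twinmotion.likelihood import neg2ll, neg2ll_and_grad
from twinmotion.model import (
    ModelSpec,
    build_pair_covariance,
    build_param_index,
    component_correlation,
    fiml_neg2ll,
    implied_pair_moments,
    make_cov_builder,
    standardize,
)
from twinmotion.simulate import preset, simulate_families

from conftest import small_ae_config


class TestComponentCorrelation:
    @pytest.mark.parametrize(
        "component,group,expected",
        [
            ("A", "MZF", 1.0),
            ("A", "MZM", 1.0),
            ("A", "DZM", 0.5),
            ("A", "SIB", 0.5),
            ("D", "DZM", 0.25),
            ("D", "MZF", 1.0),
            ("C", "DZOS", 1.0),
            ("E", "MZF", 0.0),
        ],
    )
    def test_biometrical_expectations(self, component, group, expected):
        assert component_correlation(component, group) == expected

    def test_opposite_sex_scaled_by_rg_mf(self):
        assert component_correlation("A", "DZOS", rg_mf=1.0) == 0.5
        assert component_correlation("A", "DZOS", rg_mf=0.6) == pytest.approx(0.3)
        # same-sex pairs are never scaled
        assert component_correlation("A", "DZF", rg_mf=0.6, sexes=("F", "F")) == 0.5


class TestImpliedMoments:
    def ae_spec(self):
        return ModelSpec(traits=("hm_log",), components="AE")

    def test_univariate_ae_mz(self):
        params = {"mu_hm_log": 0.0, "a_11": np.sqrt(0.4), "e_11": np.sqrt(0.6)}
        mean, cov = implied_pair_moments(self.ae_spec(), params, "MZF")
        assert np.allclose(mean, 0.0)
        assert np.allclose(cov, [[1.0, 0.4], [0.4, 1.0]])

    def test_univariate_ae_dz(self):
        params = {"mu_hm_log": 0.0, "a_11": np.sqrt(0.4), "e_11": np.sqrt(0.6)}
        _, cov = implied_pair_moments(self.ae_spec(), params, "DZF")
        assert cov[0, 1] == pytest.approx(0.2)

    def test_univariate_ade_dz_cross_covariance(self):
        spec = ModelSpec(traits=("hm_log",), components="ADE")
        params = {
            "mu_hm_log": 0.0,
            "a_11": np.sqrt(0.3),
            "d_11": np.sqrt(0.4),
            "e_11": np.sqrt(0.3),
        }
        _, cov = implied_pair_moments(spec, params, "DZM")
        assert cov[0, 1] == pytest.approx(0.5 * 0.3 + 0.25 * 0.4)

    def test_ade_dz_against_brute_force_factor_simulation(self):
        """Independent oracle: simulate correlated factor scores directly."""
        rng = np.random.default_rng(7)
        n = 400_000
        a1 = rng.standard_normal(n)
        a2 = 0.5 * a1 + np.sqrt(0.75) * rng.standard_normal(n)
        d1 = rng.standard_normal(n)
        d2 = 0.25 * d1 + np.sqrt(1 - 0.25**2) * rng.standard_normal(n)
        y1 = np.sqrt(0.3) * a1 + np.sqrt(0.4) * d1 + np.sqrt(0.3) * rng.standard_normal(n)
        y2 = np.sqrt(0.3) * a2 + np.sqrt(0.4) * d2 + np.sqrt(0.3) * rng.standard_normal(n)
        emp = float(np.cov(y1, y2)[0, 1])
        assert emp == pytest.approx(0.25, abs=0.01)

    def test_mean_model_covariates(self):
        spec = ModelSpec(traits=("hm_log",), components="AE", covariates=("sex",))
        params = {
            "mu_hm_log": -2.6,
            "beta_sex_hm_log": 0.1,
            "a_11": 0.5,
            "e_11": 0.5,
        }
        mean, _ = implied_pair_moments(
            spec, params, "DZOS", covariates=[{"sex": 0.0}, {"sex": 1.0}]
        )
        assert mean[0] == pytest.approx(-2.6)
        assert mean[1] == pytest.approx(-2.5)

    def test_covariance_psd_for_random_paths(self):
        rng = np.random.default_rng(0)
        spec = ModelSpec(traits=("hm_log", "swan_mi"), components="ACE")
        for _ in range(50):
            params = {"mu_hm_log": 0, "mu_swan_mi": 0}
            for pre in ("a", "c", "e"):
                for nm in (f"{pre}_11", f"{pre}_21", f"{pre}_22"):
                    params[nm] = rng.normal(0, 1)
            for g in ("MZF", "DZM", "DZOS", "SIB"):
                _, cov = implied_pair_moments(spec, params, g)
                assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_contrast_noninvertible_regime_rejected(self):
        spec = ModelSpec(traits=("hm_log",), components="AE", contrast=True)
        params = {"mu_hm_log": 0, "a_11": 0.5, "e_11": 0.5, "s_hm_log": 1.0}
        with pytest.raises(ValueError, match="contrast"):
            implied_pair_moments(spec, params, "MZF")

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            implied_pair_moments(
                self.ae_spec(), {"mu_hm_log": np.nan, "a_11": 1, "e_11": 1}, "MZF"
            )


class TestFimlObjective:
    def test_singleton_standard_normal_density(self, tiny_table):
        """A single standard-normal observation at its mean scores ln(2pi)."""
        df = tiny_table.iloc[[4]].copy()
        df["hm_log"] = 0.0
        spec = ModelSpec(traits=("hm_log",), components="AE")
        compiled = compile_dataset(df, spec.traits)
        # mu=0, a^2+e^2=1
        theta = np.array([0.0, np.sqrt(0.5), np.sqrt(0.5)])
        val = fiml_neg2ll(compiled, spec, theta)
        assert val == pytest.approx(np.log(2 * np.pi), abs=1e-10)
        assert val == pytest.approx(1.83788, abs=1e-5)

    def test_matches_brute_force_mvn_oracle(self, biv_cohort):
        """On complete data the FIML objective equals a per-family sum of
        multivariate-normal log densities computed with scipy."""
        spec = ModelSpec(traits=("hm_log", "swan_mi"), components="AE")
        compiled = compile_dataset(biv_cohort, spec.traits)
        rng = np.random.default_rng(5)
        theta = np.concatenate(
            [[-2.6, -1.0], rng.uniform(0.2, 0.6, 6)]
        )  # 2 means + 3 A paths + 3 E paths
        val = fiml_neg2ll(compiled, spec, theta)

        index = build_param_index(compiled, spec)
        full = dict(zip(index.names, theta))
        oracle = 0.0
        p = 2
        for blk in compiled.blocks:
            mean_full, cov_full = implied_pair_moments(
                spec, full, blk.group, sexes=blk.sexes if len(blk.sexes) == 2 else None
            )
            idx = blk.obs_idx
            mean = mean_full[idx]
            cov = cov_full[np.ix_(idx, idx)]
            mvn = multivariate_normal(mean=mean, cov=cov)
            oracle += -2.0 * mvn.logpdf(blk.Y).sum()
        assert val == pytest.approx(oracle, abs=1e-8)

    def test_doubling_families_doubles_objective(self, tiny_table):
        import pandas as pd

        spec = ModelSpec(traits=("hm_log",), components="AE")
        theta = np.array([-2.6, 0.3, 0.4])
        one = fiml_neg2ll(compile_dataset(tiny_table, spec.traits), spec, theta)
        dup = tiny_table.copy()
        dup["family_id"] = dup["family_id"] + "_b"
        dup["individual_id"] = dup["individual_id"] + "_b"
        both = pd.concat([tiny_table, dup])
        two = fiml_neg2ll(compile_dataset(both, spec.traits), spec, theta)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_family_order_invariance(self, tiny_table):
        spec = ModelSpec(traits=("hm_log",), components="AE")
        theta = np.array([-2.6, 0.3, 0.4])
        a = fiml_neg2ll(compile_dataset(tiny_table, spec.traits), spec, theta)
        b = fiml_neg2ll(
            compile_dataset(tiny_table.iloc[::-1], spec.traits), spec, theta
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpd_returns_penalty_not_crash(self, tiny_table):
        spec = ModelSpec(traits=("hm_log",), components="AE")
        theta = np.array([-2.6, 0.0, 0.0])  # zero variance
        val = fiml_neg2ll(compile_dataset(tiny_table, spec.traits), spec, theta)
        assert np.isfinite(val) and val > 1e10

    def test_analytic_gradient_matches_finite_differences(self, hm_cohort):
        spec = ModelSpec(
            traits=("hm_log",), components="ACE", covariates=("sex", "age")
        )
        compiled = compile_dataset(hm_cohort, spec.traits, spec.covariates)
        index = build_param_index(compiled, spec)
        builder, key = make_cov_builder(compiled, spec, index)
        theta = np.array([-2.6, 0.03, -0.006, 0.2, 0.15, 0.25])
        _, g = neg2ll_and_grad(compiled.blocks, index.q_mean, builder, theta, cov_key=key)
        h = 1e-6
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = h
            fd = (
                neg2ll(compiled.blocks, index.q_mean, builder, theta + e, cov_key=key)
                - neg2ll(compiled.blocks, index.q_mean, builder, theta - e, cov_key=key)
            ) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-4)


class TestContrastAndScaling:
    def test_contrast_zero_reproduces_plain_likelihood_bitwise(self, hm_cohort):
        plain = ModelSpec(traits=("hm_log",), components="AE")
        con = ModelSpec(traits=("hm_log",), components="AE", contrast=True)
        compiled = compile_dataset(hm_cohort, plain.traits)
        theta = np.array([-2.6, 0.25, 0.28])
        theta_con = np.array([-2.6, 0.25, 0.28, 0.0])  # s = 0
        assert fiml_neg2ll(compiled, plain, theta) == fiml_neg2ll(compiled, con, theta_con)

    def test_contrast_deflates_dz_correlation_more(self):
        spec = ModelSpec(traits=("hm_log",), components="AE", contrast=True)
        params = {"mu_hm_log": 0, "a_11": np.sqrt(0.5), "e_11": np.sqrt(0.5), "s_hm_log": -0.2}
        _, mz = implied_pair_moments(spec, params, "MZF")
        _, dz = implied_pair_moments(spec, params, "DZF")
        r_mz = mz[0, 1] / mz[0, 0]
        r_dz = dz[0, 1] / dz[0, 0]
        assert r_dz < 0.5 * r_mz  # negative contrast pushes DZ below half rMZ

    def test_group_variance_scaling_inflates_one_group(self):
        spec = ModelSpec(
            traits=("hm_log",), components="AE", group_variance_scaling=("DZOS",)
        )
        params = {
            "mu_hm_log": 0,
            "a_11": np.sqrt(0.4),
            "e_11": np.sqrt(0.6),
            "log_vscale_DZOS": np.log(1.5),
        }
        cov_os = build_pair_covariance(spec, params, "DZOS", ("F", "M"))
        cov_ss = build_pair_covariance(spec, params, "DZF", ("F", "F"))
        assert np.allclose(cov_os, 1.5 * cov_ss)


class TestStandardize:
    def biv_params(self, rg=0.24, re=0.12, h2=(0.40, 0.72), v=(1.0, 1.0)):
        h2 = np.array(h2)
        v = np.array(v)
        e2 = 1 - h2
        SA = np.array(
            [
                [h2[0] * v[0], rg * np.sqrt(h2[0] * v[0] * h2[1] * v[1])],
                [rg * np.sqrt(h2[0] * v[0] * h2[1] * v[1]), h2[1] * v[1]],
            ]
        )
        SE = np.array(
            [
                [e2[0] * v[0], re * np.sqrt(e2[0] * v[0] * e2[1] * v[1])],
                [re * np.sqrt(e2[0] * v[0] * e2[1] * v[1]), e2[1] * v[1]],
            ]
        )
        LA, LE = np.linalg.cholesky(SA), np.linalg.cholesky(SE)
        return {
            "a_11": LA[0, 0], "a_21": LA[1, 0], "a_22": LA[1, 1],
            "e_11": LE[0, 0], "e_21": LE[1, 0], "e_22": LE[1, 1],
        }

    def test_rp_identity_for_ae(self):
        """rp = rg sqrt(h2_1 h2_2) + re sqrt(e2_1 e2_2), exactly, in AE."""
        spec = ModelSpec(traits=("hm_log", "swan_mi"), components="AE")
        std = standardize(spec, self.biv_params())
        h2 = std["components"]["h2"]
        e2 = std["components"]["e2"]
        rhs = std["rg"] * np.sqrt(h2[0] * h2[1]) + std["re"] * np.sqrt(e2[0] * e2[1])
        assert std["rp"] == pytest.approx(rhs, abs=1e-12)
        assert std["rp"] == pytest.approx(0.178, abs=2e-3)

    def test_diagonal_paths_zero_rg(self):
        spec = ModelSpec(traits=("hm_log", "swan_mi"), components="AE")
        params = {"a_11": 0.6, "a_21": 0.0, "a_22": 0.8, "e_11": 0.8, "e_21": 0.3, "e_22": 0.5}
        std = standardize(spec, params)
        assert std["rg"] == pytest.approx(0.0)
        e2 = std["components"]["e2"]
        assert std["rp"] == pytest.approx(std["re"] * np.sqrt(e2[0] * e2[1]), abs=1e-12)

    def test_collinear_a_paths_rg_one(self):
        spec = ModelSpec(traits=("hm_log", "swan_mi"), components="AE")
        params = {"a_11": 0.6, "a_21": 0.9, "a_22": 0.0, "e_11": 0.8, "e_21": 0.0, "e_22": 0.5}
        assert standardize(spec, params)["rg"] == pytest.approx(1.0)

    def test_shares_sum_to_one(self):
        spec = ModelSpec(traits=("hm_log",), components="ADE")
        std = standardize(spec, {"a_11": 0.5, "d_11": 0.4, "e_11": 0.6})
        total = sum(v[0] for v in std["components"].values())
        assert total == pytest.approx(1.0, abs=1e-12)


class TestModelSpecValidation:
    def test_e_mandatory(self):
        with pytest.raises(ValueError, match="E component"):
            ModelSpec(traits=("hm_log",), components="AC")

    def test_c_d_exclusive(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            ModelSpec(traits=("hm_log",), components="ACDE")

    def test_drop_path_fixes_to_zero(self):
        spec = ModelSpec(traits=("hm_log", "swan_mi"), components="AE")
        nested = spec.drop_path("a_21")
        assert nested.fixed["a_21"] == 0.0


class TestSexLimitationEquivalence:
    def test_tied_sexlim_matches_standard_objective_on_female_data(self):
        """With every male path tied to its female counterpart, the general
        sex-limitation likelihood equals the standard model's."""
        cfg = small_ae_config(n_mzf=60, n_dzf=60, seed=19)
        ds = simulate_families(cfg, seed=19)
        std_spec = ModelSpec(traits=("hm_log",), components="AE")
        lim_spec = ModelSpec(
            traits=("hm_log",), components="AE",
            sex_limitation="quantitative_general", rg_mf=1.0,
        )
        compiled = compile_dataset(ds, std_spec.traits)
        theta_std = np.array([-2.6, 0.22, 0.27])
        # layout: mu, a_f, a_m, e_f, e_m  (rg_mf fixed)
        theta_lim = np.array([-2.6, 0.22, 0.22, 0.27, 0.27])
        assert fiml_neg2ll(compiled, std_spec, theta_std) == pytest.approx(
            fiml_neg2ll(compiled, lim_spec, theta_lim), rel=1e-12
        )
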