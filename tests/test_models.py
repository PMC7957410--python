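"""NB likelihood and Bayesian fits of the bursting models M1-M4."""

import dataclasses

import numpy as np
import pytest
from scipy import stats


from circaburst import (M3Model, M4Model, StudyDesign, default_params,
                        fit_model, model_loglik, nb_log_pmf,
                        simulate_dataset)
from circaburst.models import fit_cosinor_per_gene

FAST = dict(chains=2, draws=200, n_burn=300, n_extra_steps=50)


class TestNbLogPmf:
    def test_zero_count_closed_form(self):
        for b, f in [(3.0, 5.0), (0.7, 2.2)]:
            assert nb_log_pmf(0, b, f) == pytest.approx(-f * np.log1p(b))

    def test_geometric_special_case(self):
        y = np.arange(20)
        assert np.allclose(nb_log_pmf(y, 1.0, 1.0),
                           -(y + 1) * np.log(2.0))

    def test_normalisation(self):
        y = np.arange(10 ** 4)
        total = np.exp(nb_log_pmf(y, 3.0, 5.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_parameterisation(self):
        # independent cross-check: NB(b, f) is nbinom(n=f, p=1/(1+b))
        y = np.arange(50)
        b, f = 2.5, 7.3
        ref = stats.nbinom.logpmf(y, f, 1.0 / (1.0 + b))
        assert np.allclose(nb_log_pmf(y, b, f), ref, atol=1e-10)

    @pytest.mark.parametrize("b,f", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_domain_errors(self, b, f):
        with pytest.raises(ValueError):
            nb_log_pmf(1, b, f)

    def test_non_integer_count_rejected(self):
        with pytest.raises(ValueError):
            nb_log_pmf(1.5, 1.0, 1.0)


class TestModelLoglik:
    def test_single_cell_m1_equals_pmf(self, m1_table, pair_params):
        cell = m1_table.iloc[[0]]
        fits = fit_cosinor_per_gene(m1_table)
        params = {}
        for g in pair_params.genes:
            params[f"b_{g.name}"] = g.b
            params[f"gamma_{g.name}"] = g.gamma
        pointwise, total = model_loglik(cell, "M1", params,
                                        cosinor_fits=fits)
        expect = sum(
            nb_log_pmf(cell[f"count_{g}"].iloc[0], params[f"b_{g}"],
                       params[f"gamma_{g}"]
                       * fits[g].mean(cell["time_h"].iloc[0]))
            for g in ("Nr1d1", "Cry1"))
        assert total == pytest.approx(float(expect), abs=1e-10)

    def test_m2_with_unit_areas_equals_m1(self, m1_table, pair_params):
        tab = m1_table.copy()
        tab["area"] = 1.0
        fits = fit_cosinor_per_gene(tab)
        params = {}
        for g in pair_params.genes:
            params[f"b_{g.name}"] = g.b
            params[f"gamma_{g.name}"] = g.gamma
            params[f"beta_{g.name}"] = g.beta
        _, t1 = model_loglik(tab, "M1", params, cosinor_fits=fits)
        _, t2 = model_loglik(tab, "M2", params, cosinor_fits=fits)
        assert t2 == pytest.approx(t1, abs=1e-8)

    def test_matches_bruteforce_pmf_product(self, m4_table, pair_params,
                                            rng):
        """The vectorised likelihood must equal a direct per-cell product of
        the printed pmf evaluated with an independent implementation."""
        tab = m4_table.head(50)
        fits = fit_cosinor_per_gene(m4_table)
        params = {}
        for g in pair_params.genes:
            params[f"b_{g.name}"] = g.b
            params[f"gamma_{g.name}"] = g.gamma
            params[f"beta_{g.name}"] = g.beta
        pointwise, total = model_loglik(tab, "M2", params, cosinor_fits=fits)
        ref = 0.0
        for _, row in tab.iterrows():
            for g in pair_params.genes:
                b = g.b * row["area"] ** g.beta
                f = g.gamma * fits[g.name].mean(row["time_h"])
                ref += stats.nbinom.logpmf(row[f"count_{g.name}"], f,
                                           1.0 / (1.0 + b))
        assert total == pytest.approx(float(ref), abs=1e-8)

    def test_permutation_invariance(self, m4_table, pair_params):
        fits = fit_cosinor_per_gene(m4_table)
        params = {}
        for g in pair_params.genes:
            params[f"b_{g.name}"] = g.b
            params[f"gamma_{g.name}"] = g.gamma
        perm = m4_table.sample(frac=1.0, random_state=0)
        _, t1 = model_loglik(m4_table, "M1", params, cosinor_fits=fits)
        _, t2 = model_loglik(perm, "M1", params, cosinor_fits=fits)
        assert t2 == pytest.approx(t1, rel=1e-12)

    def test_m1_is_m2_with_beta_zero(self, m4_table, pair_params):
        # nesting: sup_theta loglik(M2) >= sup_theta loglik(M1)
        fits = fit_cosinor_per_gene(m4_table)
        params = {}
        for g in pair_params.genes:
            params[f"b_{g.name}"] = g.b
            params[f"gamma_{g.name}"] = g.gamma
            params[f"beta_{g.name}"] = 0.0
        _, t1 = model_loglik(m4_table, "M1", params, cosinor_fits=fits)
        _, t2 = model_loglik(m4_table, "M2", params, cosinor_fits=fits)
        assert t2 == pytest.approx(t1, abs=1e-8)

    def test_missing_latents_rejected(self, m4_table, pair_params):
        fits = fit_cosinor_per_gene(m4_table)
        params = {f"{k}_{g.name}": 1.0 for g in pair_params.genes
                  for k in ("b", "gamma", "beta", "lam")}
        with pytest.raises(ValueError, match="latent"):
            model_loglik(m4_table, "M4", params, cosinor_fits=fits)


class TestFits:
    def test_m1_recovers_truth(self, m1_table, pair_params):
        est = fit_model(m1_table, "M1", seed=31, **FAST)
        assert est.samples_.shape == (2, 200, 4)
        for g in pair_params.genes:
            for name, truth in ((f"b_{g.name}", g.b),
                                (f"gamma_{g.name}", g.gamma)):
                mean = est.posterior_mean_[name]
                sd = est.posterior_sd_[name]
                assert abs(mean - truth) < 5 * sd, name

    def test_m2_recovers_bmal1_exponent(self):
        params = default_params(("Bmal1", "Cry1"))
        design = StudyDesign(cells_per_timepoint=150,
                             gene_pair=("Bmal1", "Cry1"))
        tab = simulate_dataset("M2", params, design, seed=32)
        est = fit_model(tab, "M2", seed=33, **FAST)
        # generating exponent for the Bmal1-like gene is 0.70
        assert est.posterior_mean_["beta_Bmal1"] == pytest.approx(0.70,
                                                                  abs=0.15)
        assert set(est.rhat_) == set(est.param_names_)

    @pytest.mark.parametrize("rho", [0.4, -0.4])
    def test_m4_recovers_rho_sign(self, rho, pair_params):
        params = dataclasses.replace(pair_params, rho=rho)
        design = StudyDesign(cells_per_timepoint=100)
        tab = simulate_dataset("M4", params, design, seed=34)
        fixed = {g.name: {"b": g.b, "gamma": g.gamma, "beta": g.beta}
                 for g in params.genes}
        est = M4Model(fixed=fixed, random_state=35, **FAST).fit(tab)
        post_rho = est.posterior_mean_["rho"]
        assert np.sign(post_rho) == np.sign(rho)
        assert abs(post_rho - rho) < 0.35

    def test_m3_marginal_reduces_to_m2_at_large_kappa(self, m4_table,
                                                      pair_params):
        """With kappa -> inf the phase prior collapses to 0 and the M3
        marginal equals the plain NB likelihood with lambda-rescaled
        amplitudes."""
        from circaburst import models as M
        fixed = {g.name: {"b": g.b, "gamma": g.gamma, "beta": g.beta}
                 for g in pair_params.genes}
        m3 = M3Model(fixed=fixed, kappa=1e6, n_phase=129)
        data = M._prepare(m4_table, None)
        m3._setup(data)
        lam = np.array([1.0, 1.0])
        marg = m3._pointwise(lam, data)
        params = {}
        for g in pair_params.genes:
            params[f"b_{g.name}"] = g.b
            params[f"gamma_{g.name}"] = g.gamma
            params[f"beta_{g.name}"] = g.beta
            params[f"lam_{g.name}"] = 1.0
        direct, _ = model_loglik(m4_table, "M3", params,
                                 cosinor_fits=data.cosinor_fits,
                                 latent=np.zeros(len(m4_table)))
        assert np.allclose(marg, direct, atol=1e-4)

    def test_m3_smoke_fit(self, pair_params):
        design = StudyDesign(cells_per_timepoint=30)
        tab = simulate_dataset("M3", pair_params, design, seed=36)
        m2 = fit_model(tab, "M2", seed=37, **FAST)
        est = M3Model(m2=m2, n_restarts=2, n_phase=32, random_state=38,
                      chains=2, draws=100, n_burn=200, n_extra_steps=30)
        est.fit(tab)
        for g in pair_params.gene_names:
            lam = est.posterior_mean_[f"lam_{g}"]
            assert 0.0 < lam < 2.0
        assert np.isfinite(est.restart_best_loglik_)

    def test_fit_is_deterministic(self, m1_table):
        sub = m1_table.iloc[::4]
        a = fit_model(sub, "M1", seed=39, chains=2,
                      draws=50, n_burn=100, n_extra_steps=20)
        b = fit_model(sub, "M1", seed=39, chains=2,
                      draws=50, n_burn=100, n_extra_steps=20)
        assert np.array_equal(a.samples_, b.samples_)

    def test_log_lik_stored_pointwise(self, m1_table):
        sub = m1_table.iloc[::4]
        est = fit_model(sub, "M1", seed=40, chains=2,
                        draws=50, n_burn=100, n_extra_steps=20)
        assert est.log_lik_.shape == (2, 50, len(sub))
        # spot-check one draw against the direct evaluation
        th = {nm: est.samples_[0, 0, k]
              for k, nm in enumerate(est.param_names_)}
        ll = est.pointwise_loglik(theta=th)
        assert np.allclose(ll, est.log_lik_[0, 0])
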