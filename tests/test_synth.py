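"""Synthetic-data generator: NB moments, model reductions, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circaburst import (GeneParams, StudyDesign, default_gene, default_params,
                        sample_areas, simulate_dataset, simulate_three_gene,
                        three_gene_covariance)
from circaburst.synth import _nb_draw


class TestSampleAreas:
    def test_degenerate_spread(self):
        assert np.allclose(sample_areas(4, log_sd=0.0, seed=0), 1.0)

    def test_mean_exactly_one(self):
        a = sample_areas(10 ** 5, log_sd=0.4, seed=1)
        assert a.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(a > 0)

    def test_lognormal_cv(self):
        a = sample_areas(10 ** 5, log_sd=0.4, seed=2)
        expected_cv = np.sqrt(np.exp(0.16) - 1.0)
        assert a.std() / a.mean() == pytest.approx(expected_cv, rel=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sample_areas(0, log_sd=0.4, seed=0)


def test_nb_draw_moments(rng):
    """The Gamma-Poisson sampler must match the NB mean bf and variance
    bf + b^2 f within 3 Monte-Carlo standard errors."""
    for b, f in [(3.0, 5.0), (0.5, 20.0), (2.0, 7.3)]:
        y = _nb_draw(rng, np.full(10 ** 5, b), np.full(10 ** 5, f))
        mean, var = b * f, b * f * (1 + b)
        se_mean = np.sqrt(var / y.size)
        assert abs(y.mean() - mean) < 3 * se_mean
        # variance of the sample variance via the fourth moment
        se_var = np.sqrt((y.var() ** 2) * 2 / y.size
                         + stats.moment(y, 4) / y.size)
        assert abs(y.var() - var) < 3 * se_var


def test_m1_flat_mean(small_design):
    genes = tuple(
        GeneParams(name=n, a0=40.0, a1=0.0, a2=0.0, phi1=0.0, phi2=0.0,
                   b=b) for n, b in (("Nr1d1", 3.0), ("Cry1", 1.5)))
    params = default_params().__class__(genes=genes)
    big = StudyDesign(cells_per_timepoint=2000)
    tab = simulate_dataset("M1", params, big, seed=7)
    for g in genes:
        y = tab[f"count_{g.name}"]
        mean = g.b * g.gamma * g.a0 / 2  # = 20
        se = y.std() / np.sqrt(len(y))
        assert abs(y.mean() - mean) < 3 * se


def test_m2_beta_zero_reduces_to_m1(pair_params, small_design):
    import dataclasses
    genes0 = tuple(dataclasses.replace(g, beta=0.0)
                   for g in pair_params.genes)
    p0 = dataclasses.replace(pair_params, genes=genes0)
    big = StudyDesign(cells_per_timepoint=500)
    t1 = simulate_dataset("M1", p0, big, seed=11)
    t2 = simulate_dataset("M2", p0, big, seed=12)
    for g in p0.gene_names:
        p = stats.ks_2samp(t1[f"count_{g}"], t2[f"count_{g}"]).pvalue
        assert p > 0.01


def test_m4_sigma_zero_reduces_to_m2(pair_params):
    import dataclasses
    genes0 = tuple(dataclasses.replace(g, sigma=0.0)
                   for g in pair_params.genes)
    p0 = dataclasses.replace(pair_params, genes=genes0, rho=0.0)
    big = StudyDesign(cells_per_timepoint=500)
    t2 = simulate_dataset("M2", p0, big, seed=13)
    t4 = simulate_dataset("M4", p0, big, seed=14)
    for g in p0.gene_names:
        assert np.allclose(t4[f"true_eps_{g}"], p0.gene(g).b)
        p = stats.ks_2samp(t2[f"count_{g}"], t4[f"count_{g}"]).pvalue
        assert p > 0.01


def test_m3_large_kappa_reduces_to_m2(pair_params):
    import dataclasses
    p0 = dataclasses.replace(pair_params, kappa=1e8)
    big = StudyDesign(cells_per_timepoint=500)
    t3 = simulate_dataset("M3", p0, big, seed=15)
    assert np.abs(t3["true_phase"]).max() < 1e-3
    t2 = simulate_dataset("M2", p0, big, seed=16)
    for g in p0.gene_names:
        p = stats.ks_2samp(t2[f"count_{g}"], t3[f"count_{g}"]).pvalue
        assert p > 0.01


def test_same_seed_round_trip(pair_params, small_design):
    a = simulate_dataset("M4", pair_params, small_design, seed=42)
    b = simulate_dataset("M4", pair_params, small_design, seed=42)
    pd.testing.assert_frame_equal(a, b)


def test_table_structure(m4_table, small_design):
    assert len(m4_table) == 7 * small_design.cells_per_timepoint
    assert set(m4_table["replicate"]) == {1, 2, 3}
    assert m4_table["area"].mean() == pytest.approx(1.0, abs=1e-9)
    for g in ("Nr1d1", "Cry1"):
        y = m4_table[f"count_{g}"]
        assert (y >= 0).all() and (y == y.astype(int)).all()
        assert f"true_eps_{g}" in m4_table


def test_negative_frequency_rejected(small_design):
    bad = GeneParams(name="Nr1d1", a0=10.0, a1=50.0, a2=0.0, phi1=0.0,
                     phi2=0.0, b=2.0)
    ok = default_gene("Cry1")
    params = default_params().__class__(genes=(bad, ok))
    with pytest.raises(ValueError, match="Nr1d1"):
        simulate_dataset("M1", params, small_design, seed=1)


def test_unknown_model_rejected(pair_params, small_design):
    with pytest.raises(ValueError, match="model id"):
        simulate_dataset("M9", pair_params, small_design, seed=1)


class TestThreeGene:
    def test_precision_entry_zero(self):
        cov = three_gene_covariance([0.5, 0.4, 0.6], rho_cb=0.5,
                                    rho_cn=-0.4)
        prec = np.linalg.inv(cov)
        assert abs(prec[1, 2]) < 1e-10
        # implied Nr1d1-Bmal1 correlation is the product through Cry1
        corr = cov[1, 2] / np.sqrt(cov[1, 1] * cov[2, 2])
        assert corr == pytest.approx(0.5 * -0.4, abs=1e-12)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            three_gene_covariance([0.5, 0.5, 0.5], rho_cb=1.2, rho_cn=0.0)

    def test_sampled_correlations(self):
        params = default_params(("Cry1", "Nr1d1", "Bmal1"))
        design = StudyDesign(times=(17.0, 29.0), cells_per_timepoint=50000,
                             gene_pair=("Cry1", "Nr1d1", "Bmal1"))
        tab = simulate_three_gene(params, rho_cb=0.5, rho_cn=-0.4,
                                  design=design, seed=3)
        le = np.log(tab[[f"true_eps_{g}"
                         for g in ("Cry1", "Nr1d1", "Bmal1")]].to_numpy())
        r = np.corrcoef(le.T)
        assert r[0, 1] == pytest.approx(-0.4, abs=0.02)
        assert r[0, 2] == pytest.approx(0.5, abs=0.02)
        assert r[1, 2] == pytest.approx(-0.2, abs=0.02)

    def test_zero_correlations(self):
        params = default_params(("Cry1", "Nr1d1", "Bmal1"))
        design = StudyDesign(times=(17.0,), cells_per_timepoint=20000,
                             gene_pair=("Cry1", "Nr1d1", "Bmal1"))
        tab = simulate_three_gene(params, rho_cb=0.0, rho_cn=0.0,
                                  design=design, seed=4)
        le = np.log(tab[[f"true_eps_{g}"
                         for g in ("Cry1", "Nr1d1", "Bmal1")]].to_numpy())
        r = np.corrcoef(le.T)
        off = r[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.03)
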