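"""Thinning SSA of the 3-gene telegraph clock network."""

import dataclasses

import numpy as np
import pytest

from circaburst.network import (GENES, NetworkParams, default_network,
                                hill_rates, population_snapshot, simulate)


def _constant_rate_params(**kw):
    base = default_network()
    genes = tuple(dataclasses.replace(g, a1=0.0, a2=0.0, **kw.get(g.name, {}))
                  for g in base.genes)
    return NetworkParams(genes=genes, delta=base.delta,
                         alpha_P=base.alpha_P, P0=base.P0,
                         hill_n=base.hill_n)


class TestHillRates:
    def test_saturated_activation_no_repression(self):
        p = default_network()
        h = hill_rates([0.0, 0.0, 1e12], p)
        assert h[0] == pytest.approx(p.genes[0].alpha_M, rel=1e-9)
        assert h[1] == pytest.approx(p.genes[1].alpha_M, rel=1e-9)

    def test_zero_activator_shuts_gene_off(self):
        p = default_network()
        h = hill_rates([0.0, 0.0, 0.0], p)
        assert h[0] == 0.0 and h[1] == 0.0
        assert h[2] == pytest.approx(p.genes[2].alpha_M)  # no repressor

    def test_hill_half_point(self):
        p = dataclasses.replace(default_network(), hill_n=1.0)
        h = hill_rates([0.0, p.P0, 1e12], p)
        assert h[2] == pytest.approx(p.genes[2].alpha_M / 2.0, rel=1e-9)

    def test_all_at_threshold_closed_form(self):
        p = default_network()  # n = 2, weight 5
        P0 = p.P0
        h = hill_rates([P0, P0, P0], p)
        a = [g.alpha_M for g in p.genes]
        assert h[0] == pytest.approx(a[0] * 0.5 * 0.5 * 0.5, abs=1e-12)
        assert h[1] == pytest.approx(a[1] * 0.5 / (1 + 25.0), abs=1e-12)
        assert h[2] == pytest.approx(a[2] * 0.5, abs=1e-12)

    def test_negative_protein_rejected(self):
        with pytest.raises(ValueError):
            hill_rates([-1.0, 0.0, 0.0], default_network())


def test_invalid_thinning_bound_rejected():
    base = default_network()
    with pytest.raises(ValueError, match="thinning bound"):
        NetworkParams(genes=base.genes, u_kon=(0.01, 0.01, 0.01))


def test_constant_rate_telegraph_stationary_mean():
    """With frozen Hill factors and constant k_on the stationary mRNA mean
    has the closed form alpha_M * k_on/(k_on+k_off) / delta."""
    p = _constant_rate_params(Cry1={"alpha_M": 50.0},
                              Nr1d1={"alpha_M": 80.0},
                              Bmal1={"alpha_M": 40.0})
    traj = simulate(p, T=1600.0, seed=71, record_every=1.0,
                    freeze_hill=True)
    burn = 100
    for j, g in enumerate(GENES):
        kon = float(p.kon(g, 0.0))
        gene = p.genes[j]
        expect = gene.alpha_M * kon / (kon + gene.k_off) / p.delta
        m = traj[f"M_{g}"].to_numpy()[burn:]
        # batch means over 100-h blocks to estimate the autocorrelated SE
        batches = m[:len(m) // 100 * 100].reshape(-1, 100).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(batches.size)
        assert abs(m.mean() - expect) < 3 * se
        # promoter occupancy
        on = traj[f"on_{g}"].to_numpy()[burn:]
        occ = kon / (kon + gene.k_off)
        assert abs(on.mean() - occ) < 5 * np.sqrt(occ * (1 - occ)
                                                  / batches.size)


def test_thinned_activation_rate_matches_kon_profile():
    """Activation events of an (effectively) always-off promoter follow an
    inhomogeneous Poisson process with rate k_on(t); the binned event rate
    must match the analytic integral of k_on over each bin."""
    base = default_network()
    # huge k_off: the promoter returns to `off` essentially instantly
    genes = tuple(dataclasses.replace(g, k_off=1e6, alpha_M=0.0)
                  for g in base.genes)
    p = NetworkParams(genes=genes, delta=base.delta, alpha_P=base.alpha_P,
                      P0=base.P0, hill_n=base.hill_n)
    T = 30 * 24.0
    traj = simulate(p, T=T, seed=72, record_every=2.0, freeze_hill=True)
    nact = traj["nact_Cry1"].to_numpy()
    events = np.diff(nact)
    tgrid = traj["time_h"].to_numpy()
    t_fine = np.linspace(0, 24, 2401)
    kon = np.asarray(p.kon("Cry1", t_fine))
    # fold the 2-h bins onto the 24-h cycle
    folded = events.reshape(-1, 12).sum(axis=0)  # counts per 2-h phase bin
    for k in range(12):
        lo, hi = 2.0 * k, 2.0 * (k + 1)
        sel = (t_fine >= lo) & (t_fine <= hi)
        lam = np.trapezoid(kon[sel], t_fine[sel]) * 30  # 30 cycles
        assert abs(folded[k] - lam) < 3 * np.sqrt(lam) + 1e-9


def test_homogeneous_process_time_invariant():
    p = _constant_rate_params(Cry1={"alpha_M": 30.0},
                              Nr1d1={"alpha_M": 30.0},
                              Bmal1={"alpha_M": 30.0})
    traj = simulate(p, T=2000.0, seed=73, record_every=1.0,
                    freeze_hill=True)
    # subsample every 20 h (>> mRNA lifetime) for near-independent draws
    m = traj["M_Bmal1"].to_numpy()[100::20]
    half = len(m) // 2
    from scipy import stats
    pval = stats.ks_2samp(m[:half], m[half:]).pvalue
    assert pval > 0.01


def test_decoupled_genes_are_independent():
    p = _constant_rate_params(Cry1={"alpha_M": 30.0},
                              Nr1d1={"alpha_M": 30.0},
                              Bmal1={"alpha_M": 30.0})
    snap = population_snapshot(p, n_cells=800, t_snapshot=25.0,
                               burn_in=40.0, seed=74, freeze_hill=True)
    c = snap[[f"count_{g}" for g in GENES]].to_numpy()
    r = np.corrcoef(c.T)
    assert np.all(np.abs(r[np.triu_indices(3, 1)]) < 0.1)


def test_snapshot_feeds_cell_table_contract():
    p = default_network()
    snap = population_snapshot(p, n_cells=20, t_snapshot=20.0,
                               burn_in=24.0, seed=75)
    assert {"time_h", "area", "replicate", "count_Cry1", "count_Nr1d1",
            "count_Bmal1"} <= set(snap.columns)
    assert (snap["area"] == 1.0).all()
    assert (snap[[f"count_{g}" for g in GENES]] >= 0).all().all()
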