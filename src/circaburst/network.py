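"""Stochastic 3-gene telegraph network of the core circadian clock
(Cry1 / Nr1d1 / Bmal1) with time-varying promoter activation.

Each gene has a two-state promoter (off/on), mRNA M and protein P.  The
promoter activation rate k_on,g(t) oscillates over 24 h through the
two-harmonic burst-frequency curve (rescaled by the degradation rate delta),
while the transcription rate in the on-state is regulated by the protein
levels of the other genes through Hill functions encoding the clock
topology: BMAL1 activates Cry1 and Nr1d1; NR1D1 represses Bmal1 and Cry1;
CRY1 represses itself and (strongly, with a 5-fold weight) Nr1d1.

Reactions per gene g (seven channels):

    g_off -> g_on              rate k_on,g(t)          promoter activation
    g_off -> g_off + R         rate w_g(t)             thinning counter
    g_on  -> g_off             rate k_off,g            promoter deactivation
    g_on  -> g_on + M          rate h_g(P)             transcription
    M     -> M + P             rate alpha_P * M        translation
    M     -> 0                 rate delta * M          mRNA degradation
    P     -> 0                 rate delta * P          protein degradation

The inhomogeneous activation hazard is simulated exactly by thinning: the
thinning channel has hazard w_g(t) = U_g - k_on,g(t) so that the combined
activation+thinning process is homogeneous Poisson with the constant bound
U_g, and each event is an activation with probability k_on,g(t)/U_g.  The
event loop draws tau ~ Exponential(rate a0), advances time, re-evaluates the
propensities at the post-step time and then selects the channel
(Algorithm-1-style thinning SSA).

Default kinetic constants are artifact defaults chosen to give mRNA means of
10-35 and sustained oscillations; they are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

GENES = ("Cry1", "Nr1d1", "Bmal1")
_W = 2.0 * np.pi / 24.0


@dataclass(frozen=True)
class NetworkGene:
    """Per-gene kinetics: transcription scale, promoter deactivation and the
    cosinor coefficients (with gamma) of the activation rate."""

    name: str
    alpha_M: float       # transcription rate in the on state (1/h), before
                         # Hill regulation
    k_off: float         # promoter deactivation rate (1/h)
    gamma: float         # burst-frequency rescale of the cosinor curve
    a0: float
    a1: float
    a2: float
    phi1: float
    phi2: float


@dataclass(frozen=True)
class NetworkParams:
    """Kinetics of the 3-gene network.

    ``delta`` is the common mRNA/protein degradation rate (1/h); ``P0`` the
    Hill threshold protein number; ``hill_n`` the Hill exponent.  The
    thinning bound per gene defaults to the guaranteed cosine-sum bound
    gamma * delta * (a0/2 + |a1| + |a2|).
    """

    genes: tuple
    delta: float = 0.25
    alpha_P: float = 4.0
    P0: float = 500.0
    hill_n: float = 2.0
    cry1_weight: float = 5.0   # fold-strength of CRY1 repression of Nr1d1
    u_kon: tuple | None = None

    def __post_init__(self):
        if len(self.genes) != 3:
            raise ValueError("the network model has exactly three genes")
        names = tuple(g.name for g in self.genes)
        if names != GENES:
            raise ValueError(f"genes must be ordered {GENES}, got {names}")
        for g in self.genes:
            if min(g.alpha_M, g.k_off, g.gamma) < 0:
                raise ValueError(f"{g.name}: rates must be >= 0")
        if min(self.delta, self.alpha_P, self.P0) <= 0 or self.hill_n <= 0:
            raise ValueError("delta, alpha_P, P0 and hill_n must be > 0")
        if self.u_kon is None:
            object.__setattr__(self, "u_kon", tuple(
                g.gamma * self.delta * (g.a0 / 2 + abs(g.a1) + abs(g.a2))
                for g in self.genes))
        # the bound must dominate k_on(t) everywhere
        tgrid = np.linspace(0.0, 24.0, 4801)
        for g, u in zip(self.genes, self.u_kon):
            if np.any(self.kon(g.name, tgrid) > u * (1 + 1e-12)):
                raise ValueError(
                    f"thinning bound for {g.name} is below max k_on(t); "
                    "w(t) would be negative")

    def gene(self, name: str) -> NetworkGene:
        return self.genes[GENES.index(name)]

    def kon(self, name: str, t):
        g = self.gene(name)
        t = np.asarray(t, dtype=float)
        return self.delta * g.gamma * (
            g.a0 / 2.0 + g.a1 * np.cos(_W * t - g.phi1)
            + g.a2 * np.cos(2 * _W * t - g.phi2))


def default_network(repression_scale: float = 1.0) -> NetworkParams:
    """Artifact default kinetics giving means ~10-35 mRNAs and sustained
    oscillations; ``repression_scale`` multiplies the CRY1->Nr1d1 weight to
    scan the high-repression regime."""

    def gene(name, alpha_M, mean_f, fold, peak):
        a0 = 2.0 * mean_f
        a1 = mean_f * (fold - 1.0) / (fold + 1.0)
        return NetworkGene(name=name, alpha_M=alpha_M, k_off=10.0,
                           gamma=1.0, a0=a0, a1=a1, a2=0.1 * a1,
                           phi1=(_W * peak) % (2 * np.pi),
                           phi2=(2 * _W * peak) % (2 * np.pi))

    # alpha_M values tuned by simulation to give mRNA means of roughly
    # (19, 19, 23) at the default Hill threshold P0 = 500
    genes = (gene("Cry1", 130.0, 10.0, 1.5, 20.0),
             gene("Nr1d1", 680.0, 7.0, 2.1, 14.0),
             gene("Bmal1", 45.0, 12.0, 1.6, 8.0))
    return NetworkParams(genes=genes, cry1_weight=5.0 * repression_scale)


def hill_rates(P, params: NetworkParams) -> np.ndarray:
    """Transcription rates (h_Cry1, h_Nr1d1, h_Bmal1) given protein numbers
    P = (P_Cry1, P_Nr1d1, P_Bmal1).

    h_Cry1  = alpha_Cry1  * act(P_Bmal1) * rep(P_Nr1d1) * rep(P_Cry1)
    h_Nr1d1 = alpha_Nr1d1 * act(P_Bmal1) * rep(w * P_Cry1)
    h_Bmal1 = alpha_Bmal1 * rep(P_Nr1d1)

    with act(x) = 1/(1+(P0/x)^n) (act(0) = 0) and rep(x) = 1/(1+(x/P0)^n).
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("protein numbers must be >= 0")
    p0, n = params.P0, params.hill_n
    pc, pn, pb = P[..., 0], P[..., 1], P[..., 2]

    def act(x):
        with np.errstate(divide="ignore"):
            return np.where(x > 0, 1.0 / (1.0 + (p0 / np.maximum(x, 1e-300))
                                          ** n), 0.0)

    def rep(x):
        return 1.0 / (1.0 + (x / p0) ** n)

    a = np.array([g.alpha_M for g in params.genes])
    return np.stack([
        a[0] * act(pb) * rep(pn) * rep(pc),
        a[1] * act(pb) * rep(params.cry1_weight * pc),
        a[2] * rep(pn),
    ], axis=-1)


# ---------------------------------------------------------------------------
# numba SSA core.  State per gene: [g_on, M, P, R]; 7 channels per gene.


@njit(cache=False)
def _ssa_core(seed, t0, t_end, record_times, g_on, M, P, R,
              u_kon, k_off, delta, alpha_P, alpha_M, p0, hill_n,
              cry1_w, gam, a0c, a1c, a2c, ph1, ph2, freeze_hill):
    np.random.seed(seed)
    w = 2.0 * np.pi / 24.0
    n_rec = record_times.shape[0]
    rec = np.zeros((n_rec, 12))
    act_count = np.zeros(3)
    rec_act = np.zeros((n_rec, 3))
    i_rec = 0
    t = t0
    a = np.zeros(21)
    while True:
        # propensities at current time/state
        for g in range(3):
            kon = delta * gam[g] * (a0c[g] / 2.0
                                    + a1c[g] * np.cos(w * t - ph1[g])
                                    + a2c[g] * np.cos(2.0 * w * t - ph2[g]))
            if kon < 0.0:
                kon = 0.0
            off = 1.0 - g_on[g]
            base = 7 * g
            a[base + 0] = kon * off
            a[base + 1] = (u_kon[g] - kon) * off
            a[base + 2] = k_off[g] * g_on[g]
            if freeze_hill:
                h = alpha_M[g]
            else:
                if g == 0:
                    if P[2] > 0.0:
                        actb = 1.0 / (1.0 + (p0 / P[2]) ** hill_n)
                    else:
                        actb = 0.0
                    h = (alpha_M[0] * actb
                         / (1.0 + (P[1] / p0) ** hill_n)
                         / (1.0 + (P[0] / p0) ** hill_n))
                elif g == 1:
                    if P[2] > 0.0:
                        actb = 1.0 / (1.0 + (p0 / P[2]) ** hill_n)
                    else:
                        actb = 0.0
                    h = (alpha_M[1] * actb
                         / (1.0 + (cry1_w * P[0] / p0) ** hill_n))
                else:
                    h = alpha_M[2] / (1.0 + (P[1] / p0) ** hill_n)
            a[base + 3] = h * g_on[g]
            a[base + 4] = alpha_P * M[g]
            a[base + 5] = delta * M[g]
            a[base + 6] = delta * P[g]
        a0_tot = a.sum()
        if a0_tot <= 0.0:
            t_next = t_end + 1.0
        else:
            t_next = t + np.random.exponential(1.0 / a0_tot)
        # record the state on the grid up to the jump time
        while i_rec < n_rec and record_times[i_rec] <= min(t_next, t_end):
            for g in range(3):
                rec[i_rec, 4 * g + 0] = g_on[g]
                rec[i_rec, 4 * g + 1] = M[g]
                rec[i_rec, 4 * g + 2] = P[g]
                rec[i_rec, 4 * g + 3] = R[g]
                rec_act[i_rec, g] = act_count[g]
            i_rec += 1
        if t_next > t_end:
            break
        t = t_next
        # re-evaluate propensities at the post-step time (the activation /
        # thinning split depends on t; their sum is the constant bound)
        for g in range(3):
            kon = delta * gam[g] * (a0c[g] / 2.0
                                    + a1c[g] * np.cos(w * t - ph1[g])
                                    + a2c[g] * np.cos(2.0 * w * t - ph2[g]))
            if kon < 0.0:
                kon = 0.0
            off = 1.0 - g_on[g]
            a[7 * g + 0] = kon * off
            a[7 * g + 1] = (u_kon[g] - kon) * off
        a0_tot = a.sum()
        u = np.random.random() * a0_tot
        acc = 0.0
        j = 0
        for k in range(21):
            acc += a[k]
            if acc >= u:
                j = k
                break
        g = j // 7
        ch = j % 7
        if ch == 0:
            g_on[g] = 1
            act_count[g] += 1.0
        elif ch == 1:
            R[g] += 1
        elif ch == 2:
            g_on[g] = 0
        elif ch == 3:
            M[g] += 1
        elif ch == 4:
            P[g] += 1
        elif ch == 5:
            M[g] -= 1
        else:
            P[g] -= 1
    return rec, rec_act


def _param_arrays(params: NetworkParams):
    g = params.genes
    return dict(
        u_kon=np.array(params.u_kon, dtype=float),
        k_off=np.array([x.k_off for x in g]),
        delta=params.delta, alpha_P=params.alpha_P,
        alpha_M=np.array([x.alpha_M for x in g]),
        p0=params.P0, hill_n=params.hill_n, cry1_w=params.cry1_weight,
        gam=np.array([x.gamma for x in g]),
        a0c=np.array([x.a0 for x in g]), a1c=np.array([x.a1 for x in g]),
        a2c=np.array([x.a2 for x in g]),
        ph1=np.array([x.phi1 for x in g]),
        ph2=np.array([x.phi2 for x in g]))


def simulate(params: NetworkParams, T: float, seed: int = 0,
             record_every: float = 0.1, t0: float = 0.0,
             freeze_hill: bool = False, x0: dict | None = None
             ) -> pd.DataFrame:
    """Simulate one cell from t0 to t0+T; returns a gridded trajectory.

    Columns per gene: promoter state ``on_<g>``, mRNA ``M_<g>``, protein
    ``P_<g>``, thinning counter ``R_<g>`` and the cumulative count of
    promoter-activation events ``nact_<g>``.  With ``freeze_hill`` the
    transcription rates are fixed at alpha_M (no feedback).
    """
    record_times = t0 + np.arange(0.0, T + record_every / 2, record_every)
    g_on = np.zeros(3, dtype=np.int64)
    M = np.zeros(3, dtype=np.int64)
    P = np.zeros(3, dtype=np.int64)
    R = np.zeros(3, dtype=np.int64)
    if x0:
        for j, g in enumerate(GENES):
            g_on[j] = x0.get(f"on_{g}", 0)
            M[j] = x0.get(f"M_{g}", 0)
            P[j] = x0.get(f"P_{g}", 0)
    rec, rec_act = _ssa_core(seed % (2 ** 32), t0, t0 + T, record_times,
                             g_on, M, P, R, freeze_hill=freeze_hill,
                             **_param_arrays(params))
    out = {"time_h": record_times}
    for j, g in enumerate(GENES):
        out[f"on_{g}"] = rec[:, 4 * j + 0].astype(int)
        out[f"M_{g}"] = rec[:, 4 * j + 1].astype(int)
        out[f"P_{g}"] = rec[:, 4 * j + 2].astype(int)
        out[f"R_{g}"] = rec[:, 4 * j + 3].astype(int)
        out[f"nact_{g}"] = rec_act[:, j].astype(int)
    return pd.DataFrame(out)


def population_snapshot(params: NetworkParams, n_cells: int,
                        t_snapshot: float, burn_in: float = 72.0,
                        seed: int = 0, freeze_hill: bool = False
                        ) -> pd.DataFrame:
    """mRNA counts of n_cells independent cells sampled at t_snapshot.

    Each cell is simulated from t_snapshot - burn_in so the oscillating
    k_on(t) has the correct phase at the snapshot.  Output is in CellTable
    form (area = 1) and feeds directly into the bursting models.
    """
    seqs = np.random.SeedSequence(seed).spawn(n_cells)
    counts = np.empty((n_cells, 3), dtype=int)
    t0 = t_snapshot - burn_in
    record_times = np.array([t_snapshot])
    pa = _param_arrays(params)
    for i, sq in enumerate(seqs):
        rec, _ = _ssa_core(int(sq.generate_state(1)[0]) % (2 ** 31), t0,
                           t_snapshot + 1e-9, record_times,
                           np.zeros(3, dtype=np.int64),
                           np.zeros(3, dtype=np.int64),
                           np.zeros(3, dtype=np.int64),
                           np.zeros(3, dtype=np.int64),
                           freeze_hill=freeze_hill, **pa)
        counts[i] = rec[0, [1, 5, 9]]
    out = pd.DataFrame({"cell_id": np.arange(n_cells),
                        "time_h": t_snapshot, "area": 1.0, "replicate": 1})
    for j, g in enumerate(GENES):
        out[f"count_{g}"] = counts[:, j]
    return out


def snapshot_cell_table(params: NetworkParams, times, cells_per_time: int,
                        burn_in: float = 72.0, seed: int = 0) -> pd.DataFrame:
    """Population snapshots at several times, stacked as one CellTable with
    replicate ids assigned cyclically (area = 1)."""
    seqs = np.random.SeedSequence(seed).spawn(len(list(times)))
    frames = []
    for t, sq in zip(times, seqs):
        snap = population_snapshot(
            params, cells_per_time, float(t), burn_in=burn_in,
            seed=int(sq.generate_state(1)[0] % (2 ** 31)))
        frames.append(snap)
    table = pd.concat(frames, ignore_index=True)
    table["cell_id"] = np.arange(len(table))
    table["replicate"] = 1 + np.arange(len(table)) % 3
    return table
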