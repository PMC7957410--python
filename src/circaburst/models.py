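"""Bayesian negative-binomial mixture models of bursty transcription (M1-M4).

Observation model: the smFISH count of gene g in cell i is

    y_{i,g} ~ NB(b_{i,g}, f_{i,g}),
    p(y | b, f) = Gamma(f+y) / (Gamma(y+1) Gamma(f))
                  * (1/(1+b))**f * (b/(1+b))**y,

with mean b*f and variance b*f + b**2*f: b is the transcriptional burst size
(mRNAs per burst) and f the burst frequency (bursts per mRNA lifetime).  The
burst frequency oscillates over circadian time through the two-harmonic
cosinor mean curve m_g(t), rescaled by gamma_g: f_{i,g} = gamma_g * m_g(t_i).

Model features:

* M1 - constant burst size b_g.
* M2 - burst size scales with cell area, b_{i,g} = b_g * A_i**beta_g.
* M3 - M2 with a per-cell circadian phase phi_i ~ von Mises(kappa) shifting
  both harmonics, and a per-gene amplitude rescale lambda_g ~ U(0, 2); the
  M2-level parameters are locked at their M2 posterior means.
* M4 - M2 with a per-cell, per-gene burst-size factor eps_{i,g},
  b_{i,g} = eps_{i,g} * A_i**beta_g, where log eps is bivariate normal with
  means mu_g, scales sigma_g and inter-gene correlation rho (LKJ(4) prior);
  the burst frequency (gamma_g) and beta_g are locked at their M2 posterior
  means.

Inference: the per-cell latent variables of M3/M4 are marginalised with
deterministic quadrature (a von Mises phase grid for M3; 2-D Gauss-Hermite
for M4), leaving <= 3 parameters per gene.  The resulting low-dimensional
posteriors are sampled with an affine-invariant ensemble MCMC (emcee), run
as 4 independent chains of 1000 retained draws with R-hat diagnostics, and
pointwise log-likelihoods are stored per draw for PSIS-LOO.

Priors follow the published model blocks - Normal(0, 100) on location/scale
parameters (half-normal for positivity-constrained b, gamma, sigma),
U(0, 2) on lambda, von Mises kappa = 2 on phases and LKJ(4) on rho.
"""

from __future__ import annotations

import math
import warnings
from types import SimpleNamespace

import emcee
import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

from .cosinor import OMEGA, fit_cosinor
from .synth import gene_names

__all__ = [
    "nb_log_pmf", "model_loglik", "fit_model", "replicate_means",
    "fit_cosinor_per_gene", "M1Model", "M2Model", "M3Model", "M4Model",
]

_PRIOR_SCALE = 100.0
RHAT_WARN = 1.05


def nb_log_pmf(y, b, f):
    """Log NB pmf in burst-size / burst-frequency form (Gamma-form pmf).

    Vectorised over broadcastable y, b, f.  y must be a non-negative
    integer; b and f must be strictly positive.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be non-negative integers")
    b = np.asarray(b, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(b <= 0) or np.any(f <= 0):
        raise ValueError("burst size b and burst frequency f must be > 0")
    y = y.astype(float)
    return (gammaln(f + y) - gammaln(y + 1.0) - gammaln(f)
            + y * np.log(b) - (f + y) * np.log1p(b))


def replicate_means(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Mean count per (time point, replicate slide), skipping held-out NaNs."""
    col = f"count_{gene}"
    sub = table[["time_h", "replicate", col]].dropna(subset=[col])
    out = (sub.groupby(["time_h", "replicate"], as_index=False)[col]
              .mean().rename(columns={col: "mean_count"}))
    return out


def fit_cosinor_per_gene(table: pd.DataFrame) -> dict:
    """Two-harmonic cosinor fit to replicate-mean counts, per gene."""
    fits = {}
    for g in gene_names(table):
        rm = replicate_means(table, g)
        fits[g] = fit_cosinor(rm["time_h"].to_numpy(),
                              rm["mean_count"].to_numpy(), gene=g)
    return fits


def _half_normal_lp(x, scale=_PRIOR_SCALE):
    if x <= 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2


def _normal_lp(x, scale=_PRIOR_SCALE):
    return -0.5 * (x / scale) ** 2


# ---------------------------------------------------------------------------
# data preparation shared by all models


def _prepare(table: pd.DataFrame, cosinor_fits=None) -> SimpleNamespace:
    genes = gene_names(table)
    if cosinor_fits is None:
        cosinor_fits = fit_cosinor_per_gene(table)
    t = table["time_h"].to_numpy(dtype=float)
    area = table["area"].to_numpy(dtype=float)
    counts = np.column_stack([table[f"count_{g}"].to_numpy(dtype=float)
                              for g in genes])
    mask = np.isfinite(counts)
    y = np.where(mask, counts, 0.0)
    if np.any((y < 0) | (y != np.round(y))):
        raise ValueError("counts must be non-negative integers")
    m = np.column_stack([cosinor_fits[g].mean(t) for g in genes])
    if np.any(m <= 0):
        i, j = np.argwhere(m <= 0)[0]
        raise ValueError(
            f"cosinor mean curve for gene {genes[j]!r} is non-positive at "
            f"t = {t[i]:g} h; burst frequency would be invalid")
    return SimpleNamespace(genes=genes, t=t, area=area, y=y, mask=mask,
                           m=m, n=len(table), cosinor_fits=cosinor_fits,
                           # per-(cell,gene) pmf constant given f (M3/M4 use
                           # model-specific versions)
                           gammaln_y1=gammaln(y + 1.0))


@njit(cache=False, fastmath=True)
def _m4_marginal_kernel(y, f, const, log_ab, mask, log_eps1, log_eps2, logw):
    """Per-cell marginal log-likelihood under M4: log-sum over the 2-D
    Gauss-Hermite grid of the product-NB likelihood.  y, f, const, log_ab,
    mask are (n, 2); log_eps*, logw are (K,)."""
    n = y.shape[0]
    K = logw.shape[0]
    out = np.empty(n)
    vals = np.empty(K)
    for i in range(n):
        m = -1e300
        for k in range(K):
            s = logw[k]
            if mask[i, 0]:
                lb = log_ab[i, 0] + log_eps1[k]
                s += (const[i, 0] + y[i, 0] * lb
                      - (f[i, 0] + y[i, 0]) * np.log1p(np.exp(lb)))
            if mask[i, 1]:
                lb = log_ab[i, 1] + log_eps2[k]
                s += (const[i, 1] + y[i, 1] * lb
                      - (f[i, 1] + y[i, 1]) * np.log1p(np.exp(lb)))
            vals[k] = s
            if s > m:
                m = s
        acc = 0.0
        for k in range(K):
            acc += np.exp(vals[k] - m)
        out[i] = m + np.log(acc)
    return out


@njit(cache=False, fastmath=True)
def _m3_marginal_kernel(y, gammaln_y1, log_b, log1p_b, mask, f_base, f_osc,
                        lam, logw):
    """Per-cell marginal log-likelihood under M3: log-sum over the von Mises
    phase grid.  f_osc is (n, G, K); f_base (G,); lam (G,).  Returns None
    marker (-inf everywhere) if any f is non-positive."""
    n, G, K = f_osc.shape
    out = np.empty(n)
    vals = np.empty(K)
    for i in range(n):
        m = -1e300
        for k in range(K):
            s = logw[k]
            for g in range(G):
                if mask[i, g]:
                    fv = f_base[g] + lam[g] * f_osc[i, g, k]
                    if fv <= 0.0:
                        out[0] = np.nan
                        return out
                    s += (math.lgamma(fv + y[i, g]) - math.lgamma(fv)
                          - gammaln_y1[i, g] + y[i, g] * log_b[i, g]
                          - (fv + y[i, g]) * log1p_b[i, g])
            vals[k] = s
            if s > m:
                m = s
        acc = 0.0
        for k in range(K):
            acc += np.exp(vals[k] - m)
        out[i] = m + np.log(acc)
    return out


def _nb_pointwise(y, mask, b, f):
    """Per-cell log-likelihood summed over observed genes; b, f (n, G)."""
    ll = (gammaln(f + y) - gammaln(y + 1.0) - gammaln(f)
          + y * np.log(b) - (f + y) * np.log1p(b))
    return np.where(mask, ll, 0.0).sum(axis=1)


# ---------------------------------------------------------------------------
# ensemble sampling machinery


def _n_walkers(ndim):
    n = max(2 * ndim + 2, 16)
    return n + n % 2


def _run_chain(log_prob, x0, scales, n_steps, n_burn, draws, seed_seq):
    ndim = x0.size
    nwalkers = _n_walkers(ndim)
    rs = np.random.RandomState(int(seed_seq.generate_state(1)[0]) % (2 ** 31))
    p0 = np.empty((nwalkers, ndim))
    for w in range(nwalkers):
        for attempt in range(200):
            cand = x0 + scales * rs.randn(ndim) * (0.5 ** (attempt // 20))
            if np.isfinite(log_prob(cand)):
                p0[w] = cand
                break
        else:
            raise RuntimeError("could not find a valid starting point; "
                               "check priors/initialisation")
    # differential-evolution moves mix much faster than the default stretch
    # move on the correlated low-dimensional posteriors sampled here
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, moves=moves)
    sampler.random_state = rs.get_state()
    sampler.run_mcmc(p0, n_steps, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=n_burn)  # (kept, walkers, ndim)
    flat = chain.reshape(-1, ndim)
    if flat.shape[0] < draws:
        raise ValueError("n_steps too small for the requested draws")
    return flat[-draws:]


class _BurstModelBase(BaseEstimator):
    """Shared fit machinery; subclasses define priors and likelihoods."""

    model_id = ""

    def __init__(self, chains=4, draws=1000, n_burn=500, n_extra_steps=150,
                 random_state=0, cosinor_fits=None):
        self.chains = chains
        self.draws = draws
        self.n_burn = n_burn
        self.n_extra_steps = n_extra_steps
        self.random_state = random_state
        self.cosinor_fits = cosinor_fits

    # subclass API ---------------------------------------------------------
    def _param_names(self, data):
        raise NotImplementedError

    def _log_prior(self, theta, data):
        raise NotImplementedError

    def _pointwise(self, theta, data):
        """Per-cell log-likelihood (latents marginalised where applicable)."""
        raise NotImplementedError

    def _init(self, data):
        """Return (center, jitter scales) for walker initialisation."""
        raise NotImplementedError

    def _setup(self, data):
        """Hook for model-specific precomputation on ``data``."""

    # ----------------------------------------------------------------------
    def _log_prob(self, theta, data):
        lp = self._log_prior(theta, data)
        if not np.isfinite(lp):
            return -np.inf
        ll = self._pointwise(theta, data)
        if ll is None:
            return -np.inf
        return lp + float(ll.sum())

    def _sample(self, data, seed):
        names = self._param_names(data)
        ndim = len(names)
        x0, scales = self._init(data)
        nwalkers = _n_walkers(ndim)
        per_walker = math.ceil(self.draws / nwalkers)
        n_steps = self.n_burn + per_walker + self.n_extra_steps
        seqs = np.random.SeedSequence(seed).spawn(self.chains)
        log_prob = lambda th: self._log_prob(th, data)
        out = np.empty((self.chains, self.draws, ndim))
        for c in range(self.chains):
            out[c] = _run_chain(log_prob, x0, scales, n_steps, self.n_burn,
                                self.draws, seqs[c])
        return names, out

    def fit(self, X, y=None):
        data = _prepare(X, self.cosinor_fits)
        self._setup(data)
        names, samples = self._sample(data, self.random_state)
        self._finalise(data, names, samples)
        return self

    def _finalise(self, data, names, samples):
        self.genes_ = list(data.genes)
        self.cosinor_fits_ = data.cosinor_fits
        self.param_names_ = names
        self.samples_ = samples  # (chains, draws, ndim)
        self.posterior_ = {nm: samples[:, :, k]
                           for k, nm in enumerate(names)}
        self.posterior_mean_ = {nm: float(samples[:, :, k].mean())
                                for k, nm in enumerate(names)}
        self.posterior_sd_ = {nm: float(samples[:, :, k].std())
                              for k, nm in enumerate(names)}
        self.rhat_ = _rhat(self.posterior_)
        bad = {k: v for k, v in self.rhat_.items() if v > RHAT_WARN}
        if bad:
            warnings.warn(
                f"{self.model_id}: R-hat exceeds {RHAT_WARN} for "
                f"{sorted(bad)}; consider more steps/draws", stacklevel=2)
        ll = np.empty(samples.shape[:2] + (data.n,))
        for c in range(samples.shape[0]):
            for d in range(samples.shape[1]):
                ll[c, d] = self._pointwise(samples[c, d], data)
        self.log_lik_ = ll
        self._data_ = data

    # ----------------------------------------------------------------------
    def theta_hat_(self):
        """Posterior mean parameter point (flat dict)."""
        return dict(self.posterior_mean_)

    def pointwise_loglik(self, table=None, theta=None):
        """Per-cell marginal log-likelihood at a parameter point
        (posterior mean by default)."""
        data = self._data_ if table is None else _prepare(
            table, self.cosinor_fits_)
        if table is not None:
            self._setup(data)
        theta_vec = self._pack(theta or self.theta_hat_())
        ll = self._pointwise(theta_vec, data)
        if ll is None:
            raise ValueError("parameter point outside the model's support")
        return ll

    def _pack(self, theta_dict):
        return np.array([theta_dict[nm] for nm in self.param_names_])

    def summary(self) -> pd.DataFrame:
        rows = [{"parameter": nm, "mean": self.posterior_mean_[nm],
                 "sd": self.posterior_sd_[nm], "rhat": self.rhat_[nm]}
                for nm in self.param_names_]
        return pd.DataFrame(rows)


def _rhat(posterior: dict) -> dict:
    import arviz as az
    idata = az.from_dict(posterior=posterior)
    r = az.rhat(idata)
    return {k: float(r[k]) for k in posterior}


# ---------------------------------------------------------------------------


class M1Model(_BurstModelBase):
    """Oscillatory burst frequency, constant burst size per gene."""

    model_id = "M1"

    def _param_names(self, data):
        return ([f"b_{g}" for g in data.genes]
                + [f"gamma_{g}" for g in data.genes])

    def _split(self, theta, data):
        G = len(data.genes)
        return theta[:G], theta[G:2 * G]

    def _log_prior(self, theta, data):
        return sum(_half_normal_lp(v) for v in theta)

    def _bf(self, theta, data):
        b, gam = self._split(theta, data)
        return np.broadcast_to(b, (data.n, b.size)), gam * data.m

    def _pointwise(self, theta, data):
        b, f = self._bf(theta, data)
        return _nb_pointwise(data.y, data.mask, b, f)

    def _init(self, data):
        b0, g0 = _moment_init(data)
        x0 = np.concatenate([b0, g0])
        return x0, 0.1 * np.abs(x0)

    def predictive_loglik(self, table, gene, S=None, seed=None):
        """Held-out log-likelihood of one gene's counts at the posterior
        mean (plain NB evaluation; no latent variables)."""
        data = _prepare(table, self.cosinor_fits_)
        theta = self._pack(self.theta_hat_())
        b, f = self._bf(theta, data)
        j = data.genes.index(gene)
        sel = data.mask[:, j]
        return float(nb_log_pmf(data.y[sel, j], b[sel, j], f[sel, j]).sum())


def _moment_init(data):
    """Moment-matched starting values: Fano-1 for b, mean/(b*mean m) for
    gamma (NB mean bf, variance bf(1+b))."""
    G = len(data.genes)
    b0 = np.empty(G)
    g0 = np.empty(G)
    for j in range(G):
        yj = data.y[data.mask[:, j], j]
        mj = data.m[data.mask[:, j], j]
        mean, var = yj.mean(), yj.var()
        b0[j] = np.clip(var / max(mean, 1e-6) - 1.0, 0.2, 50.0)
        g0[j] = mean / (b0[j] * mj.mean())
    return b0, g0


class M2Model(M1Model):
    """M1 plus power-law scaling of burst size with cell area."""

    model_id = "M2"

    def _param_names(self, data):
        return super()._param_names(data) + [f"beta_{g}" for g in data.genes]

    def _split(self, theta, data):
        G = len(data.genes)
        return theta[:G], theta[G:2 * G], theta[2 * G:3 * G]

    def _log_prior(self, theta, data):
        b, gam, beta = self._split(theta, data)
        return (sum(_half_normal_lp(v) for v in np.concatenate([b, gam]))
                + sum(_normal_lp(v) for v in beta))

    def _bf(self, theta, data):
        b, gam, beta = self._split(theta, data)
        return b * data.area[:, None] ** beta, gam * data.m

    def _pointwise(self, theta, data):
        b, f = self._bf(theta, data)
        return _nb_pointwise(data.y, data.mask, b, f)

    def _init(self, data):
        b0, g0 = _moment_init(data)
        G = len(data.genes)
        beta0 = np.zeros(G)
        la = np.log(data.area)
        if np.std(la) > 1e-8:  # constant areas leave beta unidentified
            for j in range(G):
                sel = data.mask[:, j]
                beta0[j] = np.polyfit(la[sel],
                                      np.log(data.y[sel, j] + 1.0), 1)[0]
        x0 = np.concatenate([b0, g0, beta0])
        scales = np.concatenate([0.1 * b0, 0.1 * g0,
                                 np.full(G, 0.1)])
        return x0, scales

    def fixed_params(self) -> dict:
        """Posterior-mean (b, gamma, beta) per gene, for locking in M3/M4."""
        out = {}
        for g in self.genes_:
            out[g] = {"b": self.posterior_mean_[f"b_{g}"],
                      "gamma": self.posterior_mean_[f"gamma_{g}"],
                      "beta": self.posterior_mean_[f"beta_{g}"]}
        return out


def _lock_from_m2(model, data):
    """Parameters locked at M2 posterior means for M3/M4.

    Accepts an explicit ``fixed`` dict, a fitted M2Model, or neither - in
    which case an M2 model is fitted on the same table first (the published
    workflow: M3/M4 lock values from an upstream M2 fit)."""
    if model.fixed is not None:
        return model.fixed
    if model.m2 is None:
        model.m2 = M2Model(chains=model.chains, draws=model.draws,
                           n_burn=model.n_burn,
                           n_extra_steps=model.n_extra_steps,
                           random_state=model.random_state + 1,
                           cosinor_fits=data.cosinor_fits)
    if not hasattr(model.m2, "posterior_mean_"):
        if data is None:
            raise ValueError("no data available to fit the locking M2 model")
        table = pd.DataFrame({"time_h": data.t, "area": data.area,
                              "replicate": 0})
        for j, g in enumerate(data.genes):
            table[f"count_{g}"] = np.where(data.mask[:, j],
                                           data.y[:, j], np.nan)
        model.m2.cosinor_fits = data.cosinor_fits
        model.m2.fit(table)
    return model.m2.fixed_params()


class M3Model(_BurstModelBase):
    """Per-cell circadian phase (partial synchronisation) with amplitude
    rescale lambda_g; M2 parameters locked at their posterior means.

    The per-cell phase is marginalised on a uniform grid over (-pi, pi]
    weighted by the von Mises(kappa) prior.  The optimisation landscape is
    multimodal, so the sampler is restarted ``n_restarts`` times (the
    published analysis used eight) and the run with the highest mean
    log-likelihood is retained.
    """

    model_id = "M3"

    def __init__(self, m2=None, fixed=None, kappa=2.0, n_phase=64,
                 n_restarts=8, chains=4, draws=1000, n_burn=500,
                 n_extra_steps=150, random_state=0, cosinor_fits=None):
        super().__init__(chains=chains, draws=draws, n_burn=n_burn,
                         n_extra_steps=n_extra_steps,
                         random_state=random_state,
                         cosinor_fits=cosinor_fits)
        self.m2 = m2
        self.fixed = fixed
        self.kappa = kappa
        self.n_phase = n_phase
        self.n_restarts = n_restarts

    def _resolve_fixed(self, data):
        return _lock_from_m2(self, data)

    def _param_names(self, data):
        return [f"lam_{g}" for g in data.genes]

    def _log_prior(self, theta, data):
        if np.any(theta <= 0) or np.any(theta >= 2):
            return -np.inf
        return 0.0  # U(0, 2)

    def _setup(self, data):
        fixed = self._resolve_fixed(data)
        K = self.n_phase
        phi = -np.pi + 2 * np.pi * (np.arange(K) + 0.5) / K
        lw = self.kappa * np.cos(phi)
        data.phase_grid = phi
        data.log_w = lw - logsumexp(lw)  # overflow-safe for large kappa
        G = len(data.genes)
        data.f_base = np.empty((G,))
        data.f_osc = np.empty((data.n, G, K))
        data.b_fix = np.empty((data.n, G))
        data.gamma_fix = np.empty(G)
        for j, g in enumerate(data.genes):
            fx = fixed[g]
            cf = data.cosinor_fits[g]
            data.gamma_fix[j] = fx["gamma"]
            data.f_base[j] = fx["gamma"] * cf.a0 / 2.0
            data.f_osc[:, j, :] = fx["gamma"] * (
                cf.a1 * np.cos(OMEGA * data.t[:, None] - cf.phi1 - phi)
                + cf.a2 * np.cos(2 * OMEGA * data.t[:, None] - cf.phi2 - phi))
            data.b_fix[:, j] = fx["b"] * data.area ** fx["beta"]
        # parts of the NB pmf that do not depend on lambda
        data.log_b = np.log(data.b_fix)
        data.log1p_b = np.log1p(data.b_fix)

    def _pointwise(self, theta, data):
        out = _m3_marginal_kernel(data.y, data.gammaln_y1, data.log_b,
                                  data.log1p_b, data.mask, data.f_base,
                                  data.f_osc, np.asarray(theta, dtype=float),
                                  data.log_w)
        if np.isnan(out[0]):  # non-positive burst frequency on the grid
            return None
        return out

    def _init(self, data):
        return np.ones(len(data.genes)), np.full(len(data.genes), 0.15)

    def fit(self, X, y=None):
        data = _prepare(X, self.cosinor_fits)
        self._setup(data)
        seqs = np.random.SeedSequence(self.random_state).spawn(
            self.n_restarts)
        best = None
        for r, sq in enumerate(seqs):
            names, samples = self._sample(data, sq.generate_state(1)[0]
                                          % (2 ** 31))
            mean_ll = np.mean([
                self._pointwise(samples[c, d], data).sum()
                for c in range(samples.shape[0])
                for d in range(0, samples.shape[1],
                               max(1, samples.shape[1] // 50))])
            if best is None or mean_ll > best[0]:
                best = (mean_ll, names, samples)
        self.restart_best_loglik_ = best[0]
        self._finalise(data, best[1], best[2])
        return self

    def predictive_loglik(self, table, gene, S=None, seed=None):
        """Held-out log-likelihood of one gene's counts at the posterior
        mean, marginal over the von Mises phase (deterministic)."""
        data = _prepare(table, self.cosinor_fits_)
        self._setup(data)
        j = data.genes.index(gene)
        lam = self.posterior_mean_[f"lam_{gene}"]
        f = data.f_base[j] + lam * data.f_osc[:, j, :]
        f = np.clip(f, 1e-12, None)
        y = data.y[:, j][:, None]
        ll = (gammaln(f + y) - gammaln(f) - data.gammaln_y1[:, j][:, None]
              + y * data.log_b[:, j][:, None]
              - (f + y) * data.log1p_b[:, j][:, None])
        marg = logsumexp(ll + data.log_w[None, :], axis=1)
        return float(marg[data.mask[:, j]].sum())


class M4Model(_BurstModelBase):
    """Cell-specific burst size: b_{i,g} = eps_{i,g} * A_i**beta_g with
    log eps bivariate normal (mu_g, sigma_g, rho); gamma_g and beta_g are
    locked at their M2 posterior means and eps is marginalised by 2-D
    Gauss-Hermite quadrature."""

    model_id = "M4"

    def __init__(self, m2=None, fixed=None, gh_nodes=8, chains=4,
                 draws=1000, n_burn=500, n_extra_steps=150, random_state=0,
                 cosinor_fits=None):
        super().__init__(chains=chains, draws=draws, n_burn=n_burn,
                         n_extra_steps=n_extra_steps,
                         random_state=random_state,
                         cosinor_fits=cosinor_fits)
        self.m2 = m2
        self.fixed = fixed
        self.gh_nodes = gh_nodes

    def _resolve_fixed(self, data):
        return _lock_from_m2(self, data)

    def _param_names(self, data):
        g1, g2 = data.genes
        return [f"mu_{g1}", f"mu_{g2}", f"sigma_{g1}", f"sigma_{g2}", "rho"]

    def _log_prior(self, theta, data):
        mu1, mu2, s1, s2, rho = theta
        if s1 <= 0 or s2 <= 0 or not -1 < rho < 1:
            return -np.inf
        return (_normal_lp(mu1) + _normal_lp(mu2)
                + _half_normal_lp(s1) + _half_normal_lp(s2)
                + 3.0 * np.log1p(-rho * rho))  # LKJ(4) on a 2x2 correlation

    def _setup(self, data):
        if len(data.genes) != 2:
            raise ValueError("M4 is defined for a two-gene table")
        fixed = self._resolve_fixed(data)
        x, w = np.polynomial.hermite_e.hermegauss(self.gh_nodes)
        w = w / w.sum()
        Z1, Z2 = np.meshgrid(x, x, indexing="ij")
        data.gh_z = (Z1.ravel(), Z2.ravel())
        data.gh_logw = np.log(np.outer(w, w).ravel())
        G = 2
        data.log_area_beta = np.empty((data.n, G))
        data.f_fix = np.empty((data.n, G))
        for j, g in enumerate(data.genes):
            fx = fixed[g]
            data.log_area_beta[:, j] = fx["beta"] * np.log(data.area)
            data.f_fix[:, j] = fx["gamma"] * data.m[:, j]
        data.nb_const = (gammaln(data.f_fix + data.y) - gammaln(data.f_fix)
                         - data.gammaln_y1)

    def _pointwise(self, theta, data):
        mu1, mu2, s1, s2, rho = theta
        z1, z2 = data.gh_z
        log_eps1 = mu1 + s1 * z1
        log_eps2 = mu2 + s2 * (rho * z1 + np.sqrt(1 - rho * rho) * z2)
        return _m4_marginal_kernel(data.y, data.f_fix, data.nb_const,
                                   data.log_area_beta, data.mask,
                                   log_eps1, log_eps2, data.gh_logw)

    def _init(self, data):
        b0, _ = _moment_init(data)
        x0 = np.array([np.log(b0[0]), np.log(b0[1]), 0.3, 0.3, 0.0])
        return x0, np.array([0.2, 0.2, 0.1, 0.1, 0.1])

    def predictive_loglik(self, table, gene, S=1000, seed=0):
        """Held-out log-likelihood of one gene's counts at the posterior
        mean, integrating eps over its log-normal prior marginal with S
        Monte-Carlo draws: log (1/S) sum_s p(y | eps_s, theta-hat)."""
        data = _prepare(table, self.cosinor_fits_)
        self._setup(data)
        j = data.genes.index(gene)
        mu = self.posterior_mean_[f"mu_{gene}"]
        sig = self.posterior_mean_[f"sigma_{gene}"]
        rng = np.random.default_rng(seed)
        log_eps = rng.normal(mu, sig, size=S)
        log_b = data.log_area_beta[:, j][:, None] + log_eps[None, :]
        log1p_b = np.logaddexp(0.0, log_b)
        ll = (data.nb_const[:, j][:, None]
              + data.y[:, j][:, None] * log_b
              - (data.f_fix[:, j] + data.y[:, j])[:, None] * log1p_b)
        marg = logsumexp(ll, axis=1) - np.log(S)
        return float(marg[data.mask[:, j]].sum())


MODEL_CLASSES = {"M1": M1Model, "M2": M2Model, "M3": M3Model, "M4": M4Model}


def fit_model(table: pd.DataFrame, model_id: str, chains: int = 4,
              draws: int = 1000, seed: int = 0, **kwargs):
    """Fit one of M1-M4 to a CellTable and return the fitted estimator."""
    cls = MODEL_CLASSES[model_id]
    est = cls(chains=chains, draws=draws, random_state=seed, **kwargs)
    return est.fit(table)


# ---------------------------------------------------------------------------
# direct (conditional) likelihood evaluation at an explicit parameter point


def model_loglik(table: pd.DataFrame, model_id: str, params: dict,
                 cosinor_fits: dict | None = None, latent=None):
    """Total and per-cell log-likelihood at an explicit parameter point.

    ``params`` is a flat dict keyed like the posterior (``b_<gene>``,
    ``gamma_<gene>``, ``beta_<gene>``, ``lam_<gene>``).  For M3, ``latent``
    is the per-cell phase vector; for M4 it is an (n, G) array of eps values
    (conditional likelihood given the latents).
    """
    data = _prepare(table, cosinor_fits)
    G = len(data.genes)
    gam = np.array([params[f"gamma_{g}"] for g in data.genes])
    if model_id == "M1":
        b = np.broadcast_to(
            np.array([params[f"b_{g}"] for g in data.genes]), (data.n, G))
        f = gam * data.m
    elif model_id == "M2":
        beta = np.array([params[f"beta_{g}"] for g in data.genes])
        b = (np.array([params[f"b_{g}"] for g in data.genes])
             * data.area[:, None] ** beta)
        f = gam * data.m
    elif model_id == "M3":
        if latent is None:
            raise ValueError("M3 conditional likelihood requires per-cell "
                             "phases in `latent`")
        phi = np.asarray(latent, dtype=float)
        beta = np.array([params[f"beta_{g}"] for g in data.genes])
        lam = np.array([params[f"lam_{g}"] for g in data.genes])
        b = (np.array([params[f"b_{g}"] for g in data.genes])
             * data.area[:, None] ** beta)
        f = np.empty((data.n, G))
        for j, g in enumerate(data.genes):
            cf = data.cosinor_fits[g]
            f[:, j] = gam[j] * (
                cf.a0 / 2.0
                + lam[j] * cf.a1 * np.cos(OMEGA * data.t - cf.phi1 - phi)
                + lam[j] * cf.a2 * np.cos(2 * OMEGA * data.t - cf.phi2 - phi))
    elif model_id == "M4":
        if latent is None:
            raise ValueError("M4 conditional likelihood requires per-cell "
                             "eps values in `latent`")
        eps = np.asarray(latent, dtype=float).reshape(data.n, G)
        beta = np.array([params[f"beta_{g}"] for g in data.genes])
        b = eps * data.area[:, None] ** beta
        f = gam * data.m
    else:
        raise ValueError(f"unknown model id {model_id!r}")
    if np.any(b[data.mask] <= 0) or np.any(f[data.mask] <= 0):
        raise ValueError("parameter point yields non-positive b or f")
    pointwise = _nb_pointwise(data.y, data.mask, b, f)
    return pointwise, float(pointwise.sum())
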