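"""Synthetic smFISH count tables with the generative structure of models M1-M4.

Each cell i carries a sampling time t_i, a cell area A_i (log-normal,
normalised to mean 1), a replicate/slide id, and per-gene mRNA counts drawn
from a negative binomial with per-cell burst size b_{i,g} and burst frequency
f_{i,g} assembled per model:

* M1 : b_{i,g} = b_g,                 f_{i,g} = gamma_g * m_g(t_i)
* M2 : b_{i,g} = b_g * A_i**beta_g,   f as M1
* M3 : b as M2 (fixed), per-cell phase phi_i ~ von Mises(kappa) shifts both
       harmonics of m_g and lambda_g rescales the harmonic amplitudes
* M4 : b_{i,g} = eps_{i,g} * A_i**beta_g with log eps bivariate normal
       (mu_g, sigma_g, rho), f as M1

NB sampling uses the Gamma-Poisson mixture (shape f, mean b*f), which matches
the Gamma-form pmf exactly for non-integer f.  Hidden ground-truth columns
(``true_phase``, ``true_eps_<gene>``) are stored so downstream inference can
be validated against the generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cosinor import cosinor_mean

MODEL_IDS = ("M1", "M2", "M3", "M4")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: time points, cells per time point, replicates."""

    times: tuple = tuple(range(17, 42, 4))  # 17..41 h, 4-h spacing
    cells_per_timepoint: int = 450
    n_replicates: int = 3
    gene_pair: tuple = ("Nr1d1", "Cry1")

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.cells_per_timepoint < 1:
            raise ValueError("cells_per_timepoint must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class GeneParams:
    """Per-gene generator parameters (cosinor curve in count units).

    ``gamma`` defaults to 1/b so that the NB mean b*gamma*m(t) equals the
    cosinor curve m(t); ``mu`` defaults to log(b) so that M4 with sigma -> 0
    reduces to M2.
    """

    name: str
    a0: float
    a1: float
    a2: float
    phi1: float
    phi2: float
    b: float
    beta: float = 0.0
    gamma: float | None = None
    lam: float = 1.0
    mu: float | None = None
    sigma: float = 0.5

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError(f"{self.name}: burst size b must be > 0")
        if self.sigma < 0:
            raise ValueError(f"{self.name}: sigma must be >= 0")
        if self.gamma is None:
            object.__setattr__(self, "gamma", 1.0 / self.b)
        if self.gamma <= 0:
            raise ValueError(f"{self.name}: gamma must be > 0")
        if self.mu is None:
            object.__setattr__(self, "mu", float(np.log(self.b)))

    def mean_curve(self, t):
        return cosinor_mean(t, self.a0, self.a1, self.a2, self.phi1, self.phi2)


def _peak_phi(peak_h: float, harmonic: int) -> float:
    return (harmonic * 2 * np.pi * peak_h / 24.0) % (2 * np.pi)


def default_gene(name: str) -> GeneParams:
    """Defaults emulating the study conditions (mean counts 15-24, fold
    changes 1.5/1.6/2.1, area exponents 0.42-0.70, antiphasic Bmal1/Cry1)."""
    table = {
        # name: (half-mean a0/2, fold, peak h, b, beta)
        "Cry1": (15.0, 1.5, 20.0, 1.5, 0.55),
        "Bmal1": (24.0, 1.6, 8.0, 2.0, 0.70),
        "Nr1d1": (21.0, 2.1, 14.0, 3.0, 0.42),
    }
    if name not in table:
        raise KeyError(f"no default parameters for gene {name!r}")
    half, fold, peak, b, beta = table[name]
    # dominant 24-h harmonic plus a 12-h harmonic (10% of a1) peaking at the
    # same time: peak = half + 1.1 a1, trough = half - 0.9 a1, solved so the
    # peak-to-trough ratio equals `fold` exactly
    a1 = half * (fold - 1.0) / (1.1 + 0.9 * fold)
    a2 = 0.1 * a1
    return GeneParams(name=name, a0=2 * half, a1=a1, a2=a2,
                      phi1=_peak_phi(peak, 1), phi2=_peak_phi(peak, 2),
                      b=b, beta=beta)


@dataclass(frozen=True)
class GeneratorParams:
    """Full generator configuration: per-gene parameters plus shared
    inter-gene log-burst correlation rho, von Mises concentration kappa and
    the log-normal area spread."""

    genes: tuple
    rho: float = 0.0
    kappa: float = 2.0
    area_log_sd: float = 0.4
    area_log_mean: float = 0.0

    def __post_init__(self):
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.area_log_sd < 0:
            raise ValueError("area_log_sd must be >= 0")

    @property
    def gene_names(self):
        return tuple(g.name for g in self.genes)

    def gene(self, name: str) -> GeneParams:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


def default_params(pair=("Nr1d1", "Cry1"), rho: float | None = None,
                   **overrides) -> GeneratorParams:
    """Study-condition defaults for a gene pair.

    rho defaults to the pair-specific sign observed in the data:
    +0.3 for Bmal1/Cry1, -0.2 for Nr1d1/Cry1.
    """
    if rho is None:
        rho = 0.3 if "Bmal1" in pair else -0.2
    genes = tuple(default_gene(n) for n in pair)
    return GeneratorParams(genes=genes, rho=rho, **overrides)


def sample_areas(n: int, log_mean: float = 0.0, log_sd: float = 0.4,
                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw n log-normal cell areas, rescaled to arithmetic mean exactly 1."""
    if n < 1:
        raise ValueError("need at least one cell to sample areas")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    a = np.exp(rng.normal(log_mean, log_sd, size=n))
    return a / a.mean()


def _design_frame(design: StudyDesign, params: GeneratorParams,
                  rng: np.random.Generator) -> pd.DataFrame:
    times = np.repeat(design.times, design.cells_per_timepoint)
    n = times.size
    reps = np.tile(1 + np.arange(n) % design.n_replicates,
                   1)[:n]  # cyclic assignment within each time point
    areas = sample_areas(n, params.area_log_mean, params.area_log_sd, rng)
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "time_h": times,
        "area": areas,
        "replicate": reps,
    })


def _nb_draw(rng: np.random.Generator, b: np.ndarray, f: np.ndarray):
    """NB(b, f) via the Gamma-Poisson mixture: Gamma(shape=f, scale=b)."""
    return rng.poisson(rng.gamma(np.broadcast_to(f, b.shape), b))


def _check_positive_f(f: np.ndarray, gene: str, times: np.ndarray):
    if np.any(f <= 0):
        i = int(np.argmax(f <= 0))
        raise ValueError(
            f"non-positive burst frequency for gene {gene!r} at cell {i} "
            f"(t = {times[i]:g} h); check the cosinor coefficients")


def simulate_dataset(model_id: str, params: GeneratorParams,
                     design: StudyDesign, seed: int) -> pd.DataFrame:
    """Generate a CellTable under one of the generative models M1-M4."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of "
                         f"{MODEL_IDS}")
    rng = np.random.default_rng(seed)
    table = _design_frame(design, params, rng)
    t = table["time_h"].to_numpy()
    area = table["area"].to_numpy()
    n = len(table)

    phases = None
    if model_id == "M3":
        phases = rng.vonmises(0.0, params.kappa, size=n)
        table["true_phase"] = phases

    eps = None
    if model_id == "M4":
        sig = np.array([g.sigma for g in params.genes])
        mu = np.array([g.mu for g in params.genes])
        cov = np.array([[sig[0] ** 2, params.rho * sig[0] * sig[1]],
                        [params.rho * sig[0] * sig[1], sig[1] ** 2]])
        eps = np.exp(rng.multivariate_normal(mu, cov, size=n))
        for j, g in enumerate(params.genes):
            table[f"true_eps_{g.name}"] = eps[:, j]

    for j, g in enumerate(params.genes):
        if model_id == "M3":
            w = 2 * np.pi / 24.0
            m = (g.a0 / 2.0
                 + g.lam * g.a1 * np.cos(w * t - g.phi1 - phases)
                 + g.lam * g.a2 * np.cos(2 * w * t - g.phi2 - phases))
        else:
            m = g.mean_curve(t)
        f = g.gamma * m
        _check_positive_f(f, g.name, t)
        if model_id == "M1":
            b = np.full(n, g.b)
        elif model_id in ("M2", "M3"):
            b = g.b * area ** g.beta
        else:  # M4
            b = eps[:, j] * area ** g.beta
        table[f"count_{g.name}"] = _nb_draw(rng, b, f)

    return table


def three_gene_covariance(sigmas: Sequence[float], rho_cb: float,
                          rho_cn: float) -> np.ndarray:
    """Covariance of (log eps_Cry1, log eps_Nr1d1, log eps_Bmal1) under
    conditional independence of Nr1d1 and Bmal1 given Cry1.

    The zero entry in the precision matrix for the (Nr1d1, Bmal1) pair
    implies corr(log eps_N, log eps_B) = rho_cn * rho_cb.
    """
    for r, lbl in ((rho_cb, "rho_cb"), (rho_cn, "rho_cn")):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{lbl} must lie in (-1, 1)")
    s = np.asarray(sigmas, dtype=float)
    if s.shape != (3,) or np.any(s < 0):
        raise ValueError("sigmas must be three non-negative values "
                         "(Cry1, Nr1d1, Bmal1)")
    corr = np.array([
        [1.0, rho_cn, rho_cb],
        [rho_cn, 1.0, rho_cn * rho_cb],
        [rho_cb, rho_cn * rho_cb, 1.0],
    ])
    cov = corr * np.outer(s, s)
    # degenerate sigmas are allowed for limits; validate PD on the corr part
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValueError("correlations admit no positive-definite completion")
    return cov


def simulate_three_gene(params: GeneratorParams, rho_cb: float, rho_cn: float,
                        design: StudyDesign, seed: int) -> pd.DataFrame:
    """3-gene CellTable under the M4 mechanism with Bmal1 and Nr1d1
    conditionally independent given Cry1.

    ``params.genes`` must contain Cry1, Nr1d1 and Bmal1 (any order); rho_cb
    and rho_cn are the log-eps correlations of Cry1 with Bmal1 and Nr1d1.
    """
    order = ("Cry1", "Nr1d1", "Bmal1")
    genes = [params.gene(n) for n in order]
    sig = [g.sigma for g in genes]
    mu = np.array([g.mu for g in genes])
    cov = three_gene_covariance(sig, rho_cb, rho_cn)

    rng = np.random.default_rng(seed)
    table = _design_frame(design, params, rng)
    t = table["time_h"].to_numpy()
    area = table["area"].to_numpy()
    n = len(table)
    eps = np.exp(rng.multivariate_normal(mu, cov, size=n))
    for j, g in enumerate(genes):
        table[f"true_eps_{g.name}"] = eps[:, j]
        f = g.gamma * g.mean_curve(t)
        _check_positive_f(f, g.name, t)
        b = eps[:, j] * area ** g.beta
        table[f"count_{g.name}"] = _nb_draw(rng, b, f)
    return table


def count_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c.startswith("count_")]


def gene_names(table: pd.DataFrame) -> list:
    return [c[len("count_"):] for c in count_columns(table)]
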