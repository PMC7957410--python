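"""Two-harmonic cosinor regression of population-mean mRNA counts.

The mean count of gene ``g`` over circadian time ``t`` (hours) is modelled as

    m_g(t) = a0/2 + a1 * cos(w t - phi1) + a2 * cos(2 w t - phi2),

with fundamental angular frequency ``w = 2 pi / 24`` (24-h first harmonic,
12-h second harmonic).  The model is linear in ``(a0/2, a1 cos phi1,
a1 sin phi1, a2 cos phi2, a2 sin phi2)`` and is fitted by ordinary least
squares on replicate means, then converted to amplitude/phase form.

Peak phase and the peak-to-trough fold change are evaluated on a dense grid
(30-s spacing by default) because the two-harmonic curve has no closed-form
extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

PERIOD_H = 24.0
OMEGA = 2.0 * np.pi / PERIOD_H

#: grid spacing (hours) used for peak phase / fold change: 30 s
_GRID_STEP_H = 1.0 / 120.0


@dataclass
class CosinorFit:
    """Amplitude/phase coefficients of a fitted two-harmonic cosinor."""

    a0: float
    a1: float
    a2: float
    phi1: float
    phi2: float
    gene: str = ""
    rss: float = 0.0
    positive: bool = field(default=True)

    def mean(self, t):
        """Evaluate the fitted mean curve m(t) at times ``t`` (hours)."""
        return cosinor_mean(np.asarray(t, dtype=float), self.a0, self.a1,
                            self.a2, self.phi1, self.phi2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fold_change"] = fold_change(self)
        d["peak_phase_h"] = peak_phase(self)
        return d


def cosinor_mean(t, a0, a1, a2, phi1, phi2):
    """m(t) = a0/2 + a1 cos(wt - phi1) + a2 cos(2wt - phi2)."""
    t = np.asarray(t, dtype=float)
    return (a0 / 2.0
            + a1 * np.cos(OMEGA * t - phi1)
            + a2 * np.cos(2.0 * OMEGA * t - phi2))


class TwoHarmonicCosinor(BaseEstimator, RegressorMixin):
    """Least-squares two-harmonic cosinor regression.

    Parameters
    ----------
    period_h : float
        Fundamental period in hours (24 for the circadian clock).

    Attributes
    ----------
    a0_, a1_, a2_, phi1_, phi2_ : float
        Coefficients in amplitude/phase form; amplitudes are non-negative.
    rss_ : float
        Residual sum of squares at the optimum.
    positive_ : bool
        Whether the fitted curve is positive over a dense 24-h grid.
    """

    def __init__(self, period_h: float = PERIOD_H):
        self.period_h = period_h

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")
        if np.unique(t).size < 5:
            raise ValueError(
                "two-harmonic cosinor has 5 free parameters; need >= 5 "
                f"distinct time points, got {np.unique(t).size}")
        w = 2.0 * np.pi / self.period_h
        X = np.column_stack([
            np.ones_like(t),
            np.cos(w * t), np.sin(w * t),
            np.cos(2 * w * t), np.sin(2 * w * t),
        ])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        c0, c1, s1, c2, s2 = coef
        self.a0_ = 2.0 * c0
        self.a1_ = float(np.hypot(c1, s1))
        self.phi1_ = float(np.arctan2(s1, c1) % (2 * np.pi))
        self.a2_ = float(np.hypot(c2, s2))
        self.phi2_ = float(np.arctan2(s2, c2) % (2 * np.pi))
        resid = y - X @ coef
        self.rss_ = float(resid @ resid)
        grid = np.arange(0.0, self.period_h, _GRID_STEP_H)
        self.positive_ = bool(np.all(self._mean(grid) > 0))
        return self

    def _mean(self, t):
        return (self.a0_ / 2.0
                + self.a1_ * np.cos(2 * np.pi / self.period_h * t - self.phi1_)
                + self.a2_ * np.cos(4 * np.pi / self.period_h * t - self.phi2_))

    def predict(self, t):
        return self._mean(np.asarray(t, dtype=float))

    def result_(self, gene: str = "") -> CosinorFit:
        return CosinorFit(a0=float(self.a0_), a1=self.a1_, a2=self.a2_,
                          phi1=self.phi1_, phi2=self.phi2_, gene=gene,
                          rss=self.rss_, positive=self.positive_)


def fit_cosinor(times, means, gene: str = "") -> CosinorFit:
    """Fit the two-harmonic cosinor to replicate-mean counts.

    ``times``/``means`` are paired vectors with one entry per (time point,
    replicate); replicate means at the same time simply repeat the time value.
    """
    est = TwoHarmonicCosinor().fit(times, means)
    fit = est.result_(gene=gene)
    if not fit.positive:
        import warnings
        warnings.warn(
            f"fitted cosinor for gene {gene!r} is not positive over a full "
            "period; downstream burst-frequency models require m(t) > 0",
            stacklevel=2)
    return fit


def _dense_grid(step_h: float = _GRID_STEP_H):
    return np.arange(0.0, PERIOD_H, step_h)


def fold_change(fit: CosinorFit, step_h: float = _GRID_STEP_H) -> float:
    """Peak-to-trough ratio max m(t) / min m(t) over one period."""
    m = fit.mean(_dense_grid(step_h))
    m_min = m.min()
    if m_min <= 0:
        raise ValueError(
            "fold change undefined: fitted mean curve reaches a non-positive "
            f"minimum ({m_min:.4g})")
    return float(m.max() / m_min)


def peak_phase(fit: CosinorFit, step_h: float = _GRID_STEP_H) -> float:
    """Time of maximum of m(t) in [0, 24) h; ties broken by smallest t."""
    grid = _dense_grid(step_h)
    m = fit.mean(grid)
    return float(grid[int(np.argmax(m))])
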