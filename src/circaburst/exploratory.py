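"""Descriptive statistics: area-count power-law scaling and inter-gene
correlations (raw and area-regressed).

The binned scaling procedure sorts cells by area into 20 equal-width bins
spanning the 5th-95th area percentiles; the conditional mean E[m|A] is the
mean count of each bin and the scaling exponent is the least-squares slope of
log E[m|A] against log mean bin area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AreaScalingResult:
    """Binned log-log area scaling of the conditional mean count."""

    gene: str
    slope: float
    intercept: float
    log_area: np.ndarray      # log mean area per (non-empty) bin
    log_mean: np.ndarray      # log mean count per bin
    n_per_bin: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"log_area": self.log_area,
                             "log_mean_count": self.log_mean,
                             "n": self.n_per_bin})


def conditional_mean_by_area(table: pd.DataFrame, gene: str,
                             n_bins: int = 20,
                             pct_range=(5.0, 95.0)) -> AreaScalingResult:
    """Estimate the log-log scaling exponent of E[count | area]."""
    area = table["area"].to_numpy(dtype=float)
    y = table[f"count_{gene}"].to_numpy(dtype=float)
    lo, hi = np.percentile(area, pct_range)
    keep = (area >= lo) & (area <= hi)
    if keep.sum() < n_bins:
        raise ValueError(
            f"need at least {n_bins} cells inside the {pct_range} percentile "
            f"window, got {int(keep.sum())}")
    area, y = area[keep], y[keep]
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(area, edges) - 1, 0, n_bins - 1)
    mean_area = np.full(n_bins, np.nan)
    mean_count = np.full(n_bins, np.nan)
    n_per = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        n_per[b] = sel.sum()
        if n_per[b]:
            mean_area[b] = area[sel].mean()
            mean_count[b] = y[sel].mean()
    ok = n_per > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} empty area bin(s) dropped from the "
                      f"log-log fit for gene {gene!r}", stacklevel=2)
    if np.any(mean_count[ok] <= 0):
        warnings.warn("bins with zero mean count dropped from the log-log "
                      "fit", stacklevel=2)
        ok &= mean_count > 0
    la, lm = np.log(mean_area[ok]), np.log(mean_count[ok])
    slope, intercept = np.polyfit(la, lm, 1)
    return AreaScalingResult(gene=gene, slope=float(slope),
                             intercept=float(intercept),
                             log_area=la, log_mean=lm, n_per_bin=n_per[ok])


def recover_area_exponent(beta: float, n_cells: int = 5000,
                          n_seeds: int = 20, seed: int = 0,
                          mean_count: float = 20.0, b: float = 2.0,
                          area_log_sd: float = 0.4) -> float:
    """Generate-and-recover experiment for the area-scaling exponent.

    Simulates ``n_seeds`` datasets of ``n_cells`` cells whose NB burst size
    scales as b * A**beta (log-normal areas normalised to mean 1, flat mean
    count), re-estimates the exponent with the 20-bin log-log procedure and
    returns the average recovered slope.
    """
    from .synth import GeneParams, GeneratorParams, StudyDesign, \
        simulate_dataset
    gene = GeneParams(name="g", a0=2 * mean_count, a1=0.0, a2=0.0,
                      phi1=0.0, phi2=0.0, b=b, beta=beta)
    params = GeneratorParams(genes=(gene,), area_log_sd=area_log_sd)
    design = StudyDesign(times=(25.0,), cells_per_timepoint=n_cells,
                         gene_pair=("g",))
    seeds = np.random.SeedSequence(seed).spawn(n_seeds)
    slopes = [
        conditional_mean_by_area(
            simulate_dataset("M2", params, design,
                             int(s.generate_state(1)[0] % (2 ** 31))),
            "g").slope
        for s in seeds]
    return float(np.mean(slopes))


def _pearson(x: np.ndarray, y: np.ndarray):
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(stats.pearsonr(x, y).statistic)


def _iter_groups(table: pd.DataFrame, per_time: bool):
    if per_time:
        for t, sub in table.groupby("time_h", sort=True):
            yield float(t), sub
    else:
        yield np.nan, table


def pairwise_correlation(table: pd.DataFrame, g1: str, g2: str,
                         per_time: bool = True) -> pd.DataFrame:
    """Pearson correlation of raw counts, per time point (or pooled)."""
    rows = []
    for t, sub in _iter_groups(table, per_time):
        x = sub[f"count_{g1}"].to_numpy(dtype=float)
        y = sub[f"count_{g2}"].to_numpy(dtype=float)
        rows.append({"time_h": t, "r": _pearson(x, y), "n": len(sub)})
    return pd.DataFrame(rows)


def area_regressed_correlation(table: pd.DataFrame, g1: str, g2: str,
                               per_time: bool = True) -> pd.DataFrame:
    """Pearson correlation of counts after regressing out cell area.

    Per gene and group, counts are regressed on raw area by ordinary least
    squares and the correlation is computed on the two residual vectors.
    """
    rows = []
    for t, sub in _iter_groups(table, per_time):
        a = sub["area"].to_numpy(dtype=float)
        res = []
        for g in (g1, g2):
            y = sub[f"count_{g}"].to_numpy(dtype=float)
            if np.std(a) == 0:
                res.append(y - y.mean())
            else:
                coef = np.polyfit(a, y, 1)
                res.append(y - np.polyval(coef, a))
        rows.append({"time_h": t, "r": _pearson(res[0], res[1]),
                     "n": len(sub)})
    return pd.DataFrame(rows)
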