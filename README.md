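# circaburst

Probabilistic modelling of circadian single-molecule FISH (smFISH) mRNA
counts: negative-binomial (NB) mixture models of transcriptional bursting
with circadian burst-frequency modulation, Bayesian model selection by
PSIS-LOO and leave-replicate-out cross-validation, decomposition of
cell-to-cell variability into intrinsic and extrinsic sources, and a
stochastic simulator of the three-gene core clock circuit
(*Cry1* / *Nr1d1* / *Bmal1*).

## The problem

smFISH counts single mRNA molecules per cell. For core clock genes in
synchronised fibroblasts, the population-mean count oscillates over 24 h,
yet single-cell counts are far noisier than a Poisson process would allow
(CV 0.5–1 versus 0.17–0.32 for Poisson means of 10–35). The question this
package addresses quantitatively: how much of the cell-to-cell spread in
mRNA number comes from the clock (time), from cell size, from other
cell-specific states, and from transcriptional bursting itself?

## The models

Counts are modelled per cell *i* and gene *g* as

```
y_ig ~ NB(b_ig, f_ig)        mean = b f,  variance = b f + b² f
```

where `b` is the burst size and `f` the burst frequency (normalised by the
mRNA lifetime). The burst frequency oscillates through a two-harmonic
cosinor fitted to replicate-mean counts,

```
m_g(t) = a0/2 + a1 cos(2πt/24 − φ1) + a2 cos(2πt/12 − φ2),
f_ig   = γ_g · m_g(t_i),
```

and four nested models specify the burst size:

| model | burst size | extra latent structure |
|-------|------------|------------------------|
| M1 | `b_g` | — |
| M2 | `b_g · A_i^β_g` (cell area `A`, gene-specific exponent) | — |
| M3 | as M2 (locked) | per-cell circadian phase `φ_i ~ von Mises(κ=2)` |
| M4 | `ε_ig · A_i^β_g` | per-cell burst scale, `log ε` bivariate normal `(μ_g, σ_g, ρ)` |

Priors are Normal(0, 100) (half-normal where positivity is required),
U(0, 2) on the M3 amplitude rescale, and LKJ(4) on the inter-gene burst
correlation ρ. M3 and M4 lock the M2-level parameters at their M2
posterior means. Per-cell latents are marginalised by quadrature and the
remaining hyperparameters are sampled with ensemble MCMC (4 chains × 1000
draws, R-hat diagnostics). Models are compared by PSIS-LOO and by
leave-replicate-out cross-validation (for M4 the held-out likelihood
integrates ε over its prior with Monte-Carlo draws).

The variance of the counts is then decomposed with the law of total
variance over the extrinsic variables (time, area, ε) — averaging over all
6 conditioning orders — plus the intrinsic NB variance split into a Poisson
part `E[bf]` and a bursting part `E[b²f]` (dispersion α = 1/f).

Finally, a thinning-based stochastic simulation algorithm (exact for
time-varying promoter activation `k_on(t)`) simulates the telegraph-model
clock network with Hill-function feedback, reproducing the observed
gene-pair correlation signs (positive *Bmal1*/*Cry1*, negative
*Nr1d1*/*Cry1*) from the network topology alone.

## Worked example

```python
from circaburst import (StudyDesign, default_params, simulate_dataset,
                        fit_model, fold_change, peak_phase, psis_loo)
from circaburst.models import fit_cosinor_per_gene
from circaburst.exploratory import conditional_mean_by_area
from circaburst.selection import compare

design = StudyDesign(cells_per_timepoint=150)   # 7 times, 3 replicates
table = simulate_dataset("M4", default_params(("Nr1d1", "Cry1")),
                         design, seed=0)

fits = fit_cosinor_per_gene(table)
for g, f in fits.items():
    print(f"{g}: fold change {fold_change(f):.2f}, peak {peak_phase(f):.1f} h")

for g in ("Nr1d1", "Cry1"):
    print(f"{g}: area-scaling exponent "
          f"{conditional_mean_by_area(table, g).slope:.2f}")

m1 = fit_model(table, "M1", chains=2, draws=250, seed=1)
m2 = fit_model(table, "M2", chains=2, draws=250, seed=2)
m4 = fit_model(table, "M4", chains=2, draws=250, seed=3, m2=m2)
print(compare([psis_loo(m) for m in (m1, m2, m4)]).round(1))
print("rho posterior mean: %.2f" % m4.posterior_mean_["rho"])
```

prints

```
Nr1d1: fold change 2.28, peak 14.4 h
Cry1: fold change 1.73, peak 20.0 h
Nr1d1: area-scaling exponent 0.38
Cry1: area-scaling exponent 0.44
model  elpd_total   se  n_high_k
   M4     -8023.5 39.8         1
   M2     -8045.1 44.5         1
   M1     -8120.4 44.3         0
rho posterior mean: -0.67
```

The cosinor fit recovers the generating peak-to-trough ratios and peak
phases; the binned log-log procedure recovers the generating area-scaling
exponents (0.42 / 0.55) within sampling error; PSIS-LOO ranks the
generating model M4 first; and the inferred burst-scale correlation is
negative, matching the anticorrelated *Nr1d1*/*Cry1* generator (ρ = −0.2;
the posterior magnitude is larger because the burst frequency is locked at
the M2 posterior mean, which absorbs part of the ε-variance — see
`docs/methods.md`).

A command-line interface mirrors the library:
`circaburst simulate | cosinor | fit | loo | cv | decompose | netsim |
run-all` (every stochastic command requires `--seed`).

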