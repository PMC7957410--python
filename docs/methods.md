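# Methods

This note documents the models implemented in `circaburst`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Observation model

The stationary law of the two-state (telegraph) promoter model, in the
regime where bursts are short relative to the mRNA lifetime, is a negative
binomial with burst size `b` (mRNAs per activation event) and burst
frequency `f` (activation rate × mRNA lifetime):

```
p(y | b, f) = Γ(f+y) / (Γ(y+1) Γ(f)) · (1/(1+b))^f · (b/(1+b))^y
```

with mean `bf`, variance `bf + b²f`, Fano factor `1 + b`. `nb_log_pmf`
evaluates this Γ-form directly via log-Γ; sampling uses the equivalent
Gamma–Poisson mixture (Gamma shape `f`, scale `b`), exact for non-integer
`f`. Cells are assumed quasi-stationary: the 24-h modulation is slow
relative to bursting and mRNA turnover, so at each sampling time the
population distribution is a (mixture of) stationary NB laws.

## Harmonic convention

The two-harmonic cosinor is stored internally as

```
m(t) = a0/2 + a1·cos(2πt/24 − φ1) + a2·cos(2πt/12 − φ2)
```

i.e. harmonic 1 is the 24-h fundamental. Printed variants of this
regression sometimes order the 12-h term first; both orderings span the
same function space and produce identical fitted curves, so the package
fixes one convention and uses it everywhere (models, generator, network
`k_on(t)`). Peak phase and peak-to-trough fold change have no closed form
with two harmonics and are evaluated on a 30-s grid over one period.

## Models M1–M4 and priors

All models share `f_ig = γ_g·m_g(t_i)` with `m_g` the cosinor fit to
replicate-mean counts — the rescale `γ_g` keeps the oscillation phase
common across models. Burst size:

- **M1** `b_ig = b_g`; priors half-N(0, 100) on `b_g`, `γ_g` (the
  published prior is N(0, 100); both parameters must be positive for the
  NB to exist, so the implementation truncates at zero, which matches the
  density shape on the admissible domain).
- **M2** `b_ig = b_g·A_i^β_g`, `β_g ~ N(0, 100)` untruncated. Areas are
  normalised to mean 1, so `b_g` stays interpretable as the burst size of
  an average-sized cell.
- **M3** per-cell phase `φ_i ~ von Mises(κ=2)` shifts both harmonics by
  the same offset; a per-gene amplitude rescale `λ_g ~ U(0, 2)` lets the
  single-cell amplitude exceed the population amplitude. All M2-level
  parameters are locked at their M2 posterior means (our reading of the
  published M3 block: everything except `λ_g` and the phases is fixed).
  The M3 objective is multimodal, so the fit is restarted `n_restarts`
  times (default 8, as published) and the run with the highest mean
  log-likelihood is kept.
- **M4** `b_ig = ε_ig·A_i^β_g` with `log ε` bivariate normal
  `(μ_g, σ_g, ρ)`; `μ_g ~ N(0, 100)`, `σ_g ~ half-N(0, 100)`,
  `ρ ~ LKJ(4)` (for a 2×2 correlation, density ∝ (1−ρ²)³). There is no
  separate `b_g`: it is absorbed into `exp(μ_g)`, otherwise the pair
  (`b_g`, `μ_g`) is unidentifiable. The burst frequency `γ_g` (and `β_g`)
  are locked at the M2 posterior means, following the published workflow
  that prevents the frequency from inflating to fit individual cells.

### A consequence of locking worth knowing

On data generated from M4, an M2 fit absorbs part of the ε-overdispersion
into a larger `b` and smaller `γ` (their product, the mean, is preserved).
M4 inherits that biased `γ`, so its recovered `μ_g`/`σ_g`/`ρ` are shifted
relative to the generator even though the fitted distribution and the
model ranking are correct. Tests therefore assert sign recovery of ρ under
the locked workflow, and magnitude recovery only when the true `γ`, `β`
are supplied directly.

## Inference backend

Per-cell latent variables are marginalised deterministically rather than
sampled: the M3 phase by a 64-point uniform grid on (−π, π] weighted by
the von Mises prior, and the M4 burst scale by a 2-D Gauss–Hermite rule
(8 nodes per dimension; at the default σ ≈ 0.5 the 8-node total
log-likelihood differs from a 30-node reference by < 0.1 nat on a
~5 nat·10³ objective). This reduces every model to at most 3 free
parameters per gene, which are sampled with the affine-invariant ensemble
sampler (emcee) using differential-evolution moves — these mix much faster
than the default stretch move on the correlated 5-d M4 posterior. The
contract mirrors standard practice: 4 independent chains × 1000 retained
draws by default, split across walkers after burn-in, with R-hat computed
per parameter (warning above 1.05) and per-draw pointwise log-likelihoods
stored for PSIS-LOO. Marginalising ε is also what makes the pointwise
likelihood the correct cell-level predictive density for LOO: with
explicit latents the "pointwise" density would condition on cell-specific
parameters that a new cell would not share.

## Model selection

PSIS-LOO uses the harmonic-mean importance estimator of the leave-one-out
predictive density with Pareto-smoothed weights (tail fraction 20%,
k-threshold 0.7, via `arviz.psislw`); elpd totals, SEs and high-k counts
are reported in nats. A single-draw posterior collapses the estimator to
the plain log-density, which the tests exploit, and a brute-force
refit-per-cell LOO serves as the oracle on a 20-cell problem (agreement
within 0.5 nats).

Leave-replicate-out CV masks one gene's counts on one replicate slide,
refits (M4 refits its locking M2 on the training data too), and scores the
held-out counts at the posterior mean. Which gene leaves each slide is not
specified in the published description; the package default holds out
every (slide, gene) combination (6 folds for a two-gene, three-slide
table), and a `folds` argument restricts to the K-fold reading. For M4 the
held-out likelihood integrates ε over its log-normal prior marginal with
S Monte-Carlo draws (default S = 1000; S is not stated in the published
method, and doubling S changes the totals by less than their MC error).

## Variance decomposition

For extrinsic variables X = (t, A, ε), sampled independently (time uniform
over the 7 design time points, areas resampled from the supplied vector,
ε log-normal), the law of total variance telescopes into

```
V[Y] = E[V[Y|t,A,ε]] + Σ_j ( V[E[Y|X_1..X_j]] − V[E[Y|X_1..X_{j−1}]] )
```

The attribution of each variable depends on its position in the
conditioning order, so all 3! orders are evaluated — with common random
numbers across orders — and averaged; the across-order spread is reported
as a fraction of the total variance. The intrinsic term uses the exact
conditional moments `E[Y|X] = bf`, `V[Y|X] = bf + b²f`, split into Poisson
(`E[bf]`) and bursting (`E[b²f]`) parts. Conservation is checked against
an independent simulation of the full NB datasets; both sides are
Monte-Carlo estimates, so the check uses the combined (simulation +
bootstrap) standard error.

The pooling curve averages simulated cells in pools of n per time point
and reports the between-time share of the pool-mean variance; it reduces
to the single-cell time fraction at n = 1 and approaches 100% by
n = 1000, which reconciles noisy single cells with clean bulk rhythms.

## Three-gene extension

Only the two measured pairs constrain ρ, so the 3-gene log-ε covariance is
completed by conditional independence of *Nr1d1* and *Bmal1* given *Cry1*
(zero precision-matrix entry), implying
`corr(log ε_N, log ε_B) = ρ_CN·ρ_CB`. Any |ρ| < 1 pair admits a
positive-definite completion (the determinant is
`(1−ρ_CN²)(1−ρ_CB²) > 0`), but the construction validates it anyway. The
mean orbit is computed analytically, `E[Y_g](t) = E[ε]·E[A^β]·γ_g·m_g(t)`,
and the pooled single-cell sample shows the blurring: per-gene CV exceeds
the orbit's relative amplitude for every gene.

## Clock-network simulator

Each gene has a promoter (on/off), mRNA and protein; seven reaction
channels per gene (activation, thinning, deactivation, transcription,
translation, two decays). Promoter activation is inhomogeneous,
`k_on,g(t) = δ·γ_g·m_g(t)` (the burst-frequency curve rescaled by the
degradation rate), and is simulated exactly by thinning: a companion
channel with hazard `U_g − k_on,g(t)` keeps the combined rate at the
constant bound `U_g = γ_g·δ·(a0/2 + |a1| + |a2|)`, a guaranteed bound on
the cosine sum. The event loop draws the waiting time from the total rate,
advances time, re-evaluates the propensities at the post-step time and
then selects the channel — correct here because only the
activation/thinning split is time-dependent and their sum is constant.
`τ ~ exp(1/a0)` is read as exponential with mean 1/a0 (rate a0), the
standard SSA convention. Thinning events increment a counter species only.
The core loop is numba-compiled; ~10⁷ events run in seconds.

Feedback enters through the transcription rate: Hill activation by BMAL1
on *Cry1* and *Nr1d1*, Hill repression of *Bmal1* and *Cry1* by NR1D1, of
*Cry1* by itself, and of *Nr1d1* by CRY1 with a 5-fold weight (the
high-repression regime). Default kinetics (δ = 0.25/h, α_P = 4/h,
P0 = 500, n = 2, k_off = 10/h, α_M per gene) are artifact defaults — the
published parameter table is not available — tuned by simulation to give
mRNA means ≈ 19/19/23 and proteins fluctuating near the Hill thresholds,
where the feedback produces the observed correlation signs
(corr(Nr1d1, Cry1) < 0, corr(Bmal1, Cry1) > 0). One promoter copy per gene
is simulated; the copy number is exposed for tetraploid emulation, and no
factor-of-4 correction is applied to inferred burst frequencies.

## Synthetic-data generator as study conditions

Defaults mirror the study design: 7 time points (17–41 h, 4-h spacing),
450 cells per time point, 3 replicate slides assigned cyclically. Gene
defaults: mean counts 15 (*Cry1*), 24 (*Bmal1*), 21 (*Nr1d1*);
peak-to-trough folds 1.5 / 1.6 / 2.1 with *Bmal1* and *Cry1* in antiphase
and *Nr1d1* between them; area exponents 0.55 / 0.70 / 0.42 (*Cry1*'s is
not reported and is set mid-range); burst sizes 1.5 / 2.0 / 3.0 (*Nr1d1*
largest, *Cry1* smallest, *Bmal1* the highest frequency); σ_g = 0.5 and
ρ = +0.3 (*Bmal1*/*Cry1*) or −0.2 (*Nr1d1*/*Cry1*), inside the observed
per-time-point correlation ranges; total CVs land in 0.5–1. The area
distribution is log-normal with log-sd 0.4 (its empirical form is not
reported; the value reproduces the observed spread) normalised to mean 1.
`γ_g` defaults to `1/b_g` so the cosinor curve is the mean-count curve.

What the generator does **not** emulate: imaging/segmentation noise, probe
detection efficiency, cell-cycle structure, or spatial effects. Passing
the recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to the
real data's unmodelled features.

## Problem sizes in the test suite

The default sampler contract (4 × 1000 draws, full 450-cell design) is
used for real analyses; the test suite exercises the same code paths at
reduced sizes chosen for quick iteration — typically 60–120 cells per time
point, 2 chains × 200–250 draws, 6 CV folds, 5000-cell area-scaling
experiments averaged over 20 seeds, and snapshot populations of ~120 cells
per time point for the network loop. Monte-Carlo tolerances in the tests
(3 SE, or stated absolute bands) were sized to these problem sizes.

## Known limitations

- The ensemble sampler is not HMC; very high posterior correlations would
  mix slowly, though the marginalised models here are low-dimensional and
  diagnosed by R-hat.
- Locked-parameter bias (above) means M4 hyperparameters are calibrated
  against the locked workflow, not the generator, on M4 data.
- M3's marginal likelihood uses a fixed phase grid; extremely large κ
  concentrates the prior between grid nodes unless the grid contains 0
  (odd node counts do).
- The network defaults are one point in a wide feasible region; the
  correlation-sign result is a property of the high-CRY1-repression
  regime, not of a uniquely identified parameter set.
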