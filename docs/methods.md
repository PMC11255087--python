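# Methods

## The model

A deep compartment model (DCM) couples a neural covariate model with a
mechanistic pharmacokinetic core.  For subject $i$ with covariate vector
$x^{(i)}$, a network $\phi$ with weights $w$ predicts the typical PK
parameters

$$\zeta^{(i)} = \phi(x^{(i)}; w), \qquad \zeta = (CL, V_1, Q, V_2),$$

which parameterize a linear two-compartment system in amount space,

$$\frac{dA_1}{dt} = \mathrm{In}(t) + k_{21} A_2 - (k_{10} + k_{12}) A_1,
\qquad \frac{dA_2}{dt} = k_{12} A_1 - k_{21} A_2,$$

with $k_{10} = CL/V_1$, $k_{12} = Q/V_1$, $k_{21} = Q/V_2$.  Doses enter the
central compartment as bolus state jumps ($A_1 \mathrel{+}= D$) or
constant-rate infusions.  The observable is the central concentration
$C_1 = A_1/V_1$, reported in IU/dL (a fixed ×0.1 conversion from IU/L).
Training minimizes the plain sum of squared errors between observed and
model concentrations at each subject's sampling times.

Because the system is linear, it has a closed-form biexponential solution;
the package carries two solution paths.  The numeric path integrates the ODE
with an adaptive stiff-capable solver (LSODA, rtol 1e-6 / atol 1e-8 by
default) and restarts at every event time so boluses are exact
discontinuities.  The analytic path evaluates the eigen-decomposition of the
2×2 rate matrix (with a critically damped branch for coalescing rates and
series fallbacks for vanishing rates) and extends to infusions and multiple
doses by superposition.  The two paths cross-validate each other in the test
suite (max relative error below 1e-5 over random parameter draws).  The
analytic path accepts complex parameters, which training exploits: the
derivative of the concentration with respect to each PK parameter is obtained
by complex-step differentiation, $\partial_j C \approx \mathrm{Im}\,
C(\zeta + i h e_j)/h$ with $h = 10^{-30}$, exact to machine precision because
it involves no subtractive cancellation.  Network gradients are manual
reverse mode; the networks are single-hidden-layer and small enough that a
framework would add more overhead than value, and a NumPy implementation
keeps runs bitwise reproducible from a single seed.

## Architectures

All variants share one hidden layer with the swish activation
$z\,\sigma(z)$ and min–max-scaled inputs; they differ in how the four
outputs are constrained:

* **naive** — softplus outputs: positivity and nothing else.
* **initialized** — naive structure; output weights drawn at scale 1e-2 and
  output biases set to softplus⁻¹(typical value), so the untrained network
  predicts the supplied typical parameters within a few percent.
* **boundary** — outputs mapped through $\zeta_m = lb_m + (ub_m - lb_m)\,
  \sigma(h_m)$ into physiological bounds, default CL ∈ (0, 0.5) L/h,
  V1 ∈ (0.3, 7) L, Q ∈ (0.05, 0.5) L/h, V2 ∈ (0, 2) L.  The sigmoid's flat
  tails are a known weakness (estimates parked in a saturated region receive
  vanishing gradients), so a gentler softsign squashing is available behind
  `use_softsign`, default off.
* **global** — a subset of parameters (default {Q, V2}, the early
  distribution parameters that three post-dose samples cannot identify per
  subject) are free population-level scalars, softplus-parameterized for
  unconstrained optimization and initialized at softplus⁻¹ of configurable
  priors (defaults Q = 0.2 L/h, V2 = 0.8 L — implementation defaults, not
  literature estimates).
* **multibranch** — independent sub-networks over covariate subsets; each
  emits softplus-positive factors and a parameter is the *product* of the
  factors targeting it, mirroring the multiplicative covariate models of
  classical population PK.  A branch over a single one-hot categorical
  covariate is a linear map (one factor per level).  There is no separate
  intercept: the product of factors is the parameter itself.  The output
  bias of every neuron feeding V1 is initialized at 0.5
  (softplus(0.5) ≈ 0.974), preventing initial central-volume collapse and
  the resulting absurd peak predictions.

Hidden-layer weights use uniform fan-in initialization
U(±1/√fan_in) from the run seed.

### Effect curves and the scale-sharing caveat

Each multibranch sub-model can be plotted: the branch factor evaluated over
a covariate grid (co-covariates of a multi-covariate branch held at their
training median) is the learned covariate effect.  Raw factors, however,
carry an arbitrary share of the parameter's overall scale: only the product
of all factors is identified, and gradient descent from a symmetric
initialization splits the common log-scale roughly evenly across branches.
With K branches feeding clearance, an inert covariate's factor therefore
settles near $CL_{\text{typ}}^{1/K}$ (≈ 0.7 for CL ≈ 0.15 L/h and K = 5),
not near 1, even though the covariate has no effect.  For clinical-relevance
reading — the usual "maximal net change below 20 % is insignificant" rule —
`relative_effect_curves` divides each curve by its value at the reference
grid point, which removes the scale share; an unimportant covariate then has
a mean relative effect near 1 across replicates, with replicate-to-replicate
spread revealing how strongly small training sets let the model invent
spurious effects.  Raw factors remain available (and are what
`extract_effect_curves` returns) because their product reconstructs the
parameter exactly.

## Training protocol

Full-batch ADAM (β = 0.9/0.999, eps 1e-8) at learning rate 1e-2 for 500
epochs on the squared-error objective, covariates min–max scaled on the
training fold only (no clipping of unseen values; constant columns map to 0
with a warning).  The synthetic experiments use no validation split and
return the final weights; with `val_fraction > 0` a subject-level split is
held out and the epoch with the lowest validation loss is checkpointed.

Two deliberate protocol notes.  First, the 500-epoch budget leaves the loss
still slowly decreasing; we verified that tripling the budget *increases*
small-sample divergence for every architecture (more epochs mean more
overfitting of the 60 observations of an n = 20 fold), so the shorter budget
is kept for all comparative experiments.  Second, fits that demand true
convergence — the single-subject overfit smoke test (final loss < 1e-2
(IU/dL)²) and the noise-free parameter-recovery check (held-out clearance
correlation r > 0.95) — use 4000 and 1500 epochs respectively.

## The synthetic study generator

The generator emulates a virtual haemophilia-A population; it is the
package's study-conditions oracle, not a re-estimate of any published
cohort:

* **Demographics** (male survey population, emulated so the package builds
  self-contained): age ~ Uniform(2, 80) y; height from a piecewise-linear
  growth curve of age (87 cm at 2 y to 176 cm adult) with 3.5 % Gaussian
  scatter; BMI a shifted lognormal whose floor (13.5→17 kg/m²) and median
  offset (2.5→9 kg/m²) rise with age; weight = BMI·height².  Fat-free mass
  follows the maturation-scaled Al-Sallami-type formula
  FFM = (0.88 + 0.12/(1 + (age/13.4)^(−12.7))) · 9270·W/(6680 + 216·BMI).
* **Ground-truth PK**: typical CL = 0.15·(FFM/56)^0.75 L/h,
  V1 = 3.0·(FFM/56) L, Q = 0.15 L/h, V2 = 0.6 L.  These are plausible FVIII
  values chosen as configurable defaults; they are not the (unpublished)
  parameters of any specific published model, which is why all evaluation is
  pattern- and property-based rather than value-exact.  Individual CL and V1
  are typical·exp(η), η ~ N(0, ω²) with ω_CL = 0.3, ω_V1 = 0.2; Q and V2 are
  fixed across subjects.
* **Design**: one bolus of 50 IU/kg rounded to the nearest 250 IU
  (ties away from zero) at t = 0; three sampling times drawn independently
  from N(4, 2²), N(24, 5²), N(48, 5²) h, redrawn (up to 100 times) below the
  0.25 h truncation and finally clamped, then sorted; additive measurement
  noise N(0, σ = 5 IU/dL), negative observations permitted and flagged.
* **Noise-covariate augmentation**: two Uniform(0, 1) covariates and one
  equiprobable 5-level categorical covariate, independent of everything.

What the generator does **not** emulate: real survey covariate
distributions (correlated height/weight percentile tracking, demographic
skew), assay error structure (the real lower limit of quantification,
proportional error), repeated dosing, or model misspecification — the
fitted compartment structure matches the simulator exactly.  Passing tests
therefore demonstrate the *relative* behaviour of the architectures under
sparse sampling and covariate noise, not absolute predictive accuracy on
clinical data.

## Evaluation

Fitted models are scored against the *noise-free* simulated truth: predicted
and true concentration curves on a five-minute grid from 0 to 72 h (865
points, endpoints inclusive), pooled RMSE over all test subjects and grid
points.  Monte Carlo cross-validation draws a random training subset of the
requested size and tests on the complement; training is replicated with
fresh seeds per split.  Robustness is summarized by the median RMSE, the
divergence rate (share of replicates above 150 % of the median RMSE,
midpoint median convention), and two dispersion statistics: the SD over all
replicates and the SD over split-level medians.  The all-replicate SD of a
heavy-tailed RMSE distribution is dominated by the single worst replicate
(a collapsed-V1 model can predict peaks of 10⁵ IU/dL for an extrapolated
test subject) and is close to uninformative at 30 replicates; the
split-median SD is robust to single explosions and reflects the observation
that divergence is fold-specific.  Both are reported; ordering claims about
stability in the test suite use the split-median SD.

Reduced experiment scale (one CPU): a shared pool of 300 simulated subjects;
10 random splits × 3 training replicates per architecture and size
(n = 20 and n = 120), hidden size 8 for the naive-vs-global comparison;
hidden 32 for the fully connected and 16 per sub-model for the multibranch
networks in the noise-covariate comparison; curve-recovery checks use a
single 120/40 split with 3 replicates.

## Known limitations

* Bolus-and-infusion linear kinetics only; no absorption compartment,
  no nonlinear elimination, at most two compartments.
* No mixed-effects machinery: inter-individual variability exists in the
  simulator but the fitted models predict typical parameters only, so the
  residual unexplained IIV bounds achievable accuracy from below.
* The boundary variant can park parameters in the sigmoid's saturated
  region early in training and recover slowly.
* Effect curves of branches over three or more covariates are evaluated
  along one-dimensional slices and may hide interactions.
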