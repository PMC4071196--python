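# Methods

## Model

### Process-convolution construction

Each observed output (metabolite concentration, signal) is modelled as

    Y_i(t) = Σ_{s ∈ sources(i)} (h_{is} * X_s)(t) + ε_i,
    h_{is}(t) = A_{is} exp(-b_{is} t² / 2),   ε_i ~ N(0, σ_i²) i.i.d.,

where the `X_s` are latent white-noise processes with unit spectral density
(all scale is carried by the kernel amplitudes — the product of source
scale and amplitude is not identifiable, so the source scale is fixed).
Kernels are zero-centred: no temporal offset parameter. The applications
here never require lag structure, and the offset would be an extension, not
a default.

Convolving two Gaussian kernels attached to the same source against the
shared noise gives the closed-form covariance

    cov(Y_i(t), Y_j(t')) = Σ_pairs A_h A_g sqrt(2π/(b_h+b_g))
                           · exp(-½ σ_hg d²),
    σ_hg = b_h b_g/(b_h+b_g),  d = t - t'.

Outputs with no shared source are exactly independent. With one output and
one kernel this reduces to a squared-exponential kernel with variance
`A² sqrt(π/b)` and inverse squared length-scale `b/2`; the unit tests pin
this reduction to 1e-12.

### Derivative processes

Differentiating a convolution GP differentiates the kernel, so the
derivative process `U_i = dY_i/dt` is driven by the same sources and is
jointly Gaussian with every `Y_j`. The needed covariances are derivatives
of the closed form above in `d`:

    cov(U_i(t), Y_j(t')) =  d/dd cov_yy(d)      (odd in d)
    cov(Y_i(t), U_j(t')) = -d/dd cov_yy(d)
    cov(U_i(t), U_j(t')) = -d²/dd² cov_yy(d)    (positive at d = 0)

The sign convention is `d = t - t'` with the derivative on the first
argument; it is frozen and enforced by finite-difference oracle tests
(200 random configurations, absolute error < 1e-5).

### Joint prediction

Observations, latent function values and derivative values at any finite
point sets form one joint Gaussian. Conditioning on the observations
(Cholesky of the observation block) gives means and a full covariance for
`[functions; derivatives]` at the test points in one solve. Marginal
single-output predictions are the corresponding diagonal of the joint and
are computed through the same path. Reported bands are latent-function
bands (no observation-noise term); a flag adds `σ_i²` for data-space
bands. Reported intervals are mean ± 2 posterior sd.

## Hyperparameter inference

All hyperparameters (per-kernel `log A`, `log b`; per-output `log σ`) live
in log space, which enforces positivity without constrained optimization.
Priors are independent Gaussians on the log scale. `PriorSpec.from_data`
centres them on data-derived scales: length-scale a quarter of the observed
time span, per-output prior variance split evenly across that output's
kernels, noise at 10% of the per-output sample standard deviation, all with
unit log-scale width — a standard weakly-informative choice for data of
arbitrary units. Any subset of parameters can be held fixed
(`fixed_mask`), e.g. noise levels known from instrument calibration or, in
simulation studies, set to the generating value.

The MAP estimate uses multistart Nelder–Mead (default 10 starts; first
start at the prior mode, the rest drawn from the priors with a seeded
generator; objective tolerance 1e-8, at most 2000 iterations per start).
The initial simplex is `x0 + 0.25 e_k` rather than scipy's default
multiplicative simplex: a fixed-step simplex makes the search path exactly
equivariant under translations in log space, so rescaling the data (with
correspondingly shifted amplitude/noise priors) rescales the recovered
amplitudes and leaves widths untouched — a property the tests check.

### Hyperparameter uncertainty (Laplace averaging)

Plug-in MAP bands understate uncertainty, and derivative/flux bands are the
most sensitive: in the flux benchmarks the plug-in 2-sd bands covered the
truth at only ~70–90% of grid points because smoothing bias can exceed the
plug-in sd. `posterior_joint_hyperavg` corrects this without MCMC: it
estimates the posterior covariance of the free log-hyperparameters by a
finite-difference Laplace approximation at the MAP (spurious low or
negative curvature directions are floored at the smallest prior precision;
draws falling outside the 99% highest-posterior chi-square region are
rejected as approximation artefacts), computes a plug-in posterior per
accepted draw, and moment-matches the mixture
(`mean = E[mean_k]`, `cov = E[cov_k] + Cov[mean_k]`). Forty draws suffice;
the cost is ~n²/2 likelihood evaluations for the Hessian plus one
conditioning per draw.

## Flux estimation

Given `dx/dt = S v` over the modelled metabolites and optional known
fluxes, the reduced system (columns of unknown fluxes) is analysed once:
a flux is *estimable* iff its coordinate is orthogonal to the null space of
the reduced matrix, in which case its value is the corresponding row of the
pseudoinverse applied to `(dx/dt - S_known v_known)`. Estimable fluxes get
exact Gaussian posteriors (`a'Σ(t)a` from the cross-output joint derivative
covariance at each time); non-estimable fluxes carry an explicit
`underdetermined` status. A minimum-norm solution for those is available
only behind an explicit flag and warns — declining to resolve a
non-identifiable flux is a feature, not a failure. When the reduced system
is overdetermined, redundant equations are checked for compatibility
against the propagated posterior sd (median disagreement above 5 sd raises
an error). Known fluxes tabulated on a different grid raise an error unless
linear interpolation is explicitly enabled.

## Synthetic generators

The generators define the study conditions for all validation. Every
generator returns a 200-point dense truth grid with states, derivatives and
fluxes that satisfy `dx/dt = S v` to integrator accuracy (LSODA,
rtol 1e-8 / atol 1e-10), plus seeded noisy observations.

* **Oscillators** — `A sin(ωt + φ)` with analytic derivatives. Defaults:
  amplitudes (1.0, 0.7), a shared frequency 1.0 rad/time, phases
  (0.0, 0.8), 30 regular samples over [0, 10], noise sd 5% of each
  amplitude. A shared frequency is the regime where a shared latent source
  is informative; the phase shift makes the cross-correlation asymmetric,
  deliberately stressing the symmetric zero-centred kernels.
* **Linear pathway** — saturable kinetics: influx `v1` from a constant
  external substrate (x1 = 2) inhibited by the end product
  (`1/(1+(x3/Ki)^2)`), conversion `v2` activated by x3 (Hill with a 10%
  basal activity so the pathway can start from low x3), first-order efflux
  `v3`. With defaults the system relaxes to a steady state with
  v1 = v2 = v3 (checked to 1%).
* **Branched pathway** — power-law (S-system style) rate laws: constant
  input `v1` into x1; `v2 = a2 x1^0.5 x3^-0.8` (end-product inhibition);
  `v3 = a3 x2^0.75`; branch `v4 = a4 x1^0.5 x2^0.6` (activation by x2; the
  exponent 0 removes the regulation). Only x2 and x3 are "measured", so
  the exported stoichiometry has two balance equations in which v1 and v4
  do not appear — reproducing the intended identifiability structure
  (v2, v3 estimable; v1, v4 not).
* **Nitrogen-assimilation-like chain** — aKG → GLU → GLN with a decaying
  input flux after a nutrient spike (`v1 = 0.2 + 1.5 e^{-t/2}`),
  Michaelis–Menten conversions for the glutamate-dehydrogenase-like step
  and the lumped glutamine-synthetase-like step, and a `mutant_scale`
  factor on the GS-like rate constant emulating a strain with reduced GS
  expression. The 3×3 triangular stoichiometry makes all three fluxes
  estimable.
* ODE noise default: sd = 1% of each output's dynamic range ("low noise"),
  overridable per output.

The ODE parameter values were chosen once to produce a visible transient
and relaxation within the observation window and positive trajectories
throughout; validation is always parameter/flux *recovery* against
self-generated truth, never trajectory matching to an external dataset.
What passing these tests shows is that the covariance calculus, the joint
conditioning and the Gaussian flux propagation are correct and calibrated
*under the model's own assumptions plus smooth ODE truths*; real data add
model-mismatch features the generators do not emulate (non-Gaussian noise,
replicate structure, sampling biases, fast unmodelled dynamics).

## Numerical choices

* Observation-block Cholesky with base jitter `1e-10 · mean(diag)`,
  escalated ×10 to at most `1e-6 · mean(diag)` before a conditioning error
  naming the offending block.
* Posterior variances in `[-1e-10·scale, 0)` are round-off and clipped to
  zero; anything more negative raises, as it indicates a real bug.
* Null-space membership tolerance 1e-10 for flux classification.
* Problem sizes in the validation suite (30–50 observations, 50–60 test
  points, 20 replicates, 20k prior draws) were chosen to make every check
  statistically meaningful while keeping the full suite in the minutes
  range on one CPU.

## Known limitations

* Zero-centred kernels cannot represent lead–lag cross-correlation; a
  kernel offset would be the natural extension.
* MAP + Laplace averaging approximates, but does not replace, full
  posterior sampling of hyperparameters; multimodal posteriors keep only
  the best mode found by the multistart search.
* Dense Cholesky costs O(N³) in the total number of observations; no
  sparse approximation is provided.
* One-dimensional inputs (time) only; non-Gaussian likelihoods and
  higher-order derivatives are out of scope.
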