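# Methods

## Model

The package studies a continuously structured population in which every
individual is tracked by age `a` and size `y`. The bundled, analytically
solvable life history has three ingredients:

* **Size growth with individual heterogeneity** ("internal stochasticity"):
  size follows a geometric Brownian motion,
  `dX_a = b1 X_a da + sigma1 X_a dB_a`, started at the neonate size `x`.
  `b1` is the mean relative growth rate (per unit time), `sigma1` the
  growth volatility (per sqrt time). All neonates are born at size `x`
  (a point-mass neonate distribution).
* **Constant mortality** `mu0` (per unit time).
* **Allometric fertility** `F(y) = f0 * y**rho` with `0 < rho < 1`:
  bigger individuals reproduce more, with diminishing returns. `rho` acts
  as a risk-appetite index: growth gambles pay off only through a concave
  fertility function.

Units are abstract "per unit time" throughout; the bundled parameter sets
(`stochlife/data/*.toml`) are `b1=0.6, sigma1=0.5, x=0.01, mu0=0.1, f0=1,
rho=0.4` for the single-resource study and additionally `b2=0.5,
sigma1=0.8, sigma2=0.005` for the two-resource study.

## Spectral quantities (`stochlife.spectral`)

The renewal (Euler–Lotka) condition for this model is rational: with
`D(r) = r + mu0 - rho*b1 + sigma1^2 rho(1-rho)/2`, the characteristic
function is `psi(r) = f0 x^rho / D(r)`, strictly decreasing from +inf at
its single simple pole `pole = rho(b1 - sigma1^2(1-rho)/2) - mu0` to zero.
Hence a unique real root of `psi(r)=1`:

    r0 = rho*(b1 - sigma1^2 (1-rho)/2) + f0 x^rho - mu0,

the long-term logarithmic growth rate (LLGR) of the population in a
constant environment. `R0 = psi(0)` exists only when `pole < 0`; the
package raises a divergence error otherwise rather than reporting a number
from a divergent lifetime-reproduction integral.

The dominant eigenfunction `w0(a, y)` is the lognormal transition density
of the size process times the discount `exp(-(mu0+r0)a)`; the reproductive
value is `v0(y) = f0 y^rho` — it coincides with the fertility function and
makes the duality pairing `<v0, w0>` exactly one (the age integrand reduces
to `f0 x^rho exp(-f0 x^rho a)`).

The denominator `D(r)` was fixed by substituting the power ansatz
`v = C y^rho` into the adjoint generator symbolically; the derivation is
frozen as a test (`tests/test_symbolic.py`).

Numerical choices:

* Size integrals run in log-size coordinates (the integrand is Gaussian
  there) with Gauss–Legendre nodes on a ±10-standard-deviation window;
  nodes are clipped to keep `exp(z)` inside double range, where the
  Gaussian weight is below `e^-50`.
* Age integrals over `[0, inf)` use panel doubling until the last panel
  contributes less than 1e-10 of the running total; integrable
  `1/sqrt(age)` behavior at zero is removed by the substitution
  `a = s^2` on the first panel.
* The numerical root of `psi(r)=1` brackets from `[pole+1e-6, pole+1]`
  with upper-bound doubling (monotonicity guarantees the bracket) and is
  used only as an oracle for the closed form.
* The Feynman–Kac Monte Carlo oracle simulates exact GBM increments on a
  uniform grid (default `dt = 0.01`) and truncates the horizon where the
  exponential tail is below 1e-7 of the estimate. With `sigma1 = 0` it
  degrades gracefully to a deterministic quadrature.

Degenerate inputs: `sigma1 = 0` is a valid parameter (deterministic
growth) but any operation that needs the size density (eigenfunction
values, pairing quadrature, the deviation term) raises a specific
degenerate-input error instead of returning infinity silently.

## Second-order growth-rate correction (`stochlife.perturbation`)

Environmental ("external") stochasticity is modelled as multiplicative
space–time white noise of amplitude `epsilon` acting on the population
operator. To second order in `epsilon` the mean LLGR is

    llgr(eps) = r0 - (eps^2 / 2) * ||(v0 w0)^2||,

where the deviation term is the double integral over age and size of the
squared product of reproductive value and eigenfunction. For this model
the integral is solvable — Gaussian in log size, then
exponential-times-`1/sqrt(age)` in age:

    ||(v0 w0)^2|| = f0^2 x^(2 rho - 1) / (2 sigma1 sqrt(A)),
    A = b1 + 2 f0 x^rho + sigma1^2 (rho - 3/4).

The closed form is doubly validated: symbolically (frozen in
`tests/test_symbolic.py`) and against an independent adaptive 2-D
quadrature on randomized parameters (1e-6 relative). The convergence
condition `A > 0` is not automatic; it is checked explicitly and a
divergence error with the offending value is raised when violated.

Structural facts asserted by tests: the deviation term does not depend on
`mu0` (mortality cancels through `r0`); it diverges as `sigma1 -> 0` — a
perfectly homogeneous population has no buffer against environmental
noise; and it decreases in `b1` — fast mean growth shortens the risky
juvenile phase.

Because `r0` falls with `sigma1` while the noise buffer rises with it,
each `epsilon > 0` has a unique interior volatility `sigma1*` maximizing
`llgr`. The search uses a 200-point coarse grid on the interval (default
`[0.05, 2.0]`) followed by golden-section refinement to 1e-6, ties broken
toward smaller `sigma1`; volatilities with `A <= 0` are treated as
`-inf`. At `epsilon = 0` the LLGR is monotone decreasing in `sigma1` and
the lower endpoint is returned with a diagnostic.

## Two-resource utilization (`stochlife.control`)

Effort is split between a risky resource R1 `(b1, sigma1)` and a safe one
R2 `(b2 <= b1, sigma2 < sigma1)` through a constant fraction `u` on R2.
Independence of the two Brownian drivers makes the mixture a GBM with
`b_eff(u) = b1(1-u) + b2 u` and
`s2_eff(u) = sigma1^2 (1-u)^2 + sigma2^2 u^2`, so the growth exponent
`lam(u)` is the dominant root of the effective bundle — one formula path,
no transcription of the (garbled in the source material) interior-case
display. `lam` is strictly concave, and clamping its stationary point
gives

    u~ = max{ sigma1^2/(sigma1^2+sigma2^2)
              - (b1-b2)/((sigma1^2+sigma2^2)(1-rho)), 0 }.

`hjb_residual` verifies that the power value function `v(y) = (y/x)^rho`
with `r = lam(u~)` solves the stationary dynamic-programming equation:
the controlled adjoint generator is minimized pointwise in `u` (exact
quadratic minimizer, clamped; endpoints also checked), the residual is
below 1e-8 of the fertility scale, and the minimizing control is constant
across sizes ("stationary control"). Non-power candidate value functions
are accepted and produce an honest (nonzero) residual via central-difference
derivatives.

Under noise the objective becomes `lam(u) - (eps^2/2) dev_norm(u)` with
the deviation term of the u-mixed bundle. The maximizer is found on a
coarse grid (default step 1e-3) with local refinement at 1e-5;
utilizations whose effective variance is below 1e-10 are excluded for
`eps > 0` (their deviation term diverges, consistent with the
`sigma1 -> 0` limit), and ties go to smaller `u` (more use of the risky
resource — arbitrary but fixed). The qualitative consequence reproduced by
the sweep: the interval of fertility exponents supporting a mixed strategy
shrinks monotonically as `epsilon` grows (at the bundled parameters the
mixed count on the 0.01-spaced `rho` grid falls 83 → 71 → 51 → 32 → 16
across `epsilon` in {0, 0.1, 0.3, 0.6, 0.9}).

## Simulators (`stochlife.simulators`)

### Individual-based branching diffusion

Each step of length `dt`: exact GBM size increments; death with
probability `1 - exp(-mu0 dt)`; Poisson births with mean `f0 y^rho dt`,
newborns at size `x`. The estimator is the least-squares slope of
`ln V(t)`, `V = sum_i f0 y_i^rho` (total reproductive value), after a
burn-in (default the first 25% of the horizon). When the population
exceeds `pop_cap` it is uniformly subsampled to half the cap and
`ln(n_before/n_after)` is added to the accumulated log total — the
standard branching-process renormalization keeping `ln V` unbiased in
expectation. Defaults (`dt=0.01`, `t_max=200`, `n0=200`, `pop_cap=2e4`)
keep demographic noise small enough that the pooled 95% interval over
eight seeds covers the closed-form `r0` while one seed runs in ~15 s.
The per-run OLS standard error assumes independent residuals and
understates autocorrelated demographic noise; pooling slopes across seeds
is the supported inference route. Extinction before the burn-in is a
reported diagnostic, not an exception.

### Grid solver for the noisy transport equation

State: the density over (age, log size) on a uniform grid. Per substep
`dt`: (i) Crank–Nicolson step of the constant-coefficient
advection–diffusion operator in log size (log coordinates make the GBM
Fokker–Planck operator constant-coefficient; Dirichlet-zero boundaries on
a window covering the kernel to six standard deviations at every age);
(ii) mortality decay; (iii) deposit of `dt` worth of births into the
single cell containing the neonate log size (the neonate distribution is
a point mass; no smoothing kernel); (iv) multiplicative noise update;
(v) every `delta_a/dt` substeps an exact one-cell age shift (method of
characteristics; `dt` must divide `delta_a`); (vi) renormalization of
the total mass to one, accumulating the log. The LLGR estimate is the
fitted slope of the accumulated log mass.

White noise delta-correlated in (age, size) is realized as iid standard
normals per cell scaled by `sqrt(dt/(delta_a * delta_y))`,
`delta_y = y * delta_z`; the grid is the regularization — there is no
grid-free reference solution for a space–time white-noise equation at
desk scale, so noise statistics are compared with the quadrature deviation
term at fixed grid. The default noise update is the positivity-preserving
geometric form `P *= exp(s xi - s^2/2)`, `s = eps * sigma_cell`: its mean
is exactly the Itô mean and its variance matches to `O(s^2)`. The linear
Euler–Maruyama form `P *= 1 + s xi` (negative cells clipped to zero and
counted, abort above 1% clipped mass per step) is selectable; it was not
made the default because at the neonate cell `sigma_cell = sqrt(dt/
(delta_a * x * delta_z))` is large for any practical step size and
clipping then injects a positive bias directly into the growth rate.
Both updates give statistically indistinguishable growth slopes where
both are stable.

**Validity of the quadratic response.** The second-order formula is an
expansion around `eps = 0`. On the grid, the expansion parameter that
matters is the noise variance a newborn cohort accumulates while crossing
the neonate cell, `eps^2/(x * delta_z)` — independent of the time step.
With `x = 0.01` this reaches order one near `eps ~ 0.05` for any log-size
resolution that still resolves the eigenfunction, and beyond it a genuine
higher-order (mode-coupling) term dominates the fitted `eps^2`
coefficient; the measured coefficient then grows in magnitude as the grid
is refined and is independent of the update scheme. Inside the
perturbative range the package's common-random-number second-difference
estimator (`spde_epsilon2_coefficient`: runs at `eps` and `2 eps` share
noise, so the pathwise second difference cancels the first-order
martingale exactly) reproduces minus half the grid-projected deviation
sum; at `eps = 0.02` on the default coarse grid the estimate is
`-1.34 ± 0.49` against the grid prediction `-1.26` (continuum: `-1.379`).
At larger amplitudes the fitted coefficient reports the grid system's true
response, which is *more* negative than the second-order formula — the
formula is an optimistic bound there, and simulated growth rates should
not be read as estimates of the continuum second-order coefficient outside
the stated range.

### Direct Monte Carlo of the perturbation terms

Starting the population at the dominant eigenfunction, the normalized
first-order term is the projected noise integral
`M(t) = int_0^t ||v0 dB w0||` — a Gaussian martingale whose variance per
unit time equals the deviation term — and the normalized second-order term
is its time-ordered iterated double integral `(M^2 - [M])/2`, with mean
exactly zero. The field is generated cell by cell; the statistics carry no
factor of `eps` (they multiply `eps^m` in the series, and the API takes no
amplitude).

Because `(v0 w0)^2` concentrates like `1/sqrt(age)` near age zero (half
its mass lies below age ~0.9 at the bundled parameters), the noise grid
for this computation grades age quadratically toward zero
(`a_j = a_max (j/n)^2`) and uses `delta_z = 0.05`; cell values are
cell *averages* computed semi-analytically (normal-CDF differences in log
size, Gauss subsampling in age). At the defaults the grid-projected
variance is within ~3% of the continuum deviation term; a uniform grid at
comparable cost is 10–22% low. Cells carrying a negligible fraction
(1e-6 cumulative) of the projected variance are pruned before sampling —
they cannot influence the statistics at that tolerance but dominate the
cost of normal generation. A resolution check compares the grid pairing
with its analytically truncated value and rejects windows that clip the
eigenfunction.

### Seeding

Every stochastic operation takes an explicit integer seed; replicates and
batches derive independent child streams through `SeedSequence.spawn`, so
results are bit-reproducible for a given (seed, configuration) and
replicates are independent.

## What the simulators do and do not emulate

The generators realize exactly the model above: Markovian growth, constant
hazard, size-only fertility, point-mass neonate sizes, and (for the noisy
solver) white environmental noise that perturbs the whole operator. They
do not include density dependence, age-dependent vital rates, parental
effects on offspring state, or colored/non-Markovian environmental noise;
white noise can transiently violate cohort monotonicity (negative
effective mortality), which the continuum model itself allows. Passing
tests therefore certify the internal consistency of the formulas,
solvers and samplers for this model family — not the fidelity of the
model to any particular organism's demography.

## Known limitations

* The `eps^2` correction is second order only; no `eps^4` term is
  computed, and the `sigma1 -> 0` divergence of the deviation term marks
  the breakdown of the truncation, not a physical infinity.
* The grid solver's quadratic response matches the perturbative formula
  only within the amplitude range discussed above.
* Only the dominant characteristic root is treated (for this model the
  root set is a single point); no subdominant-root machinery is provided.
* One-dimensional size only; the multi-state generalization is out of
  scope.
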