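# Methods

## Model and assumptions

The model couples a logistic resource, consumer demography and
replicator dynamics of a binary motility trait on one nondimensional
timescale (encounter rate between cells and resource scaled to 1):

```
dR/dt = R [ r (1 − R/K) − N ]
dN/dt = N [ p̄(x, R) R − d ]
dx/dt = x (1 − x) R [ p_F(R) − p_S(x, R) ]
```

Assumptions worth keeping in mind:

* **Resource-driven aggregation.** A cell is solitary with probability
  `π(R) = a R/K` (clipped to `[0, 1]`), grouped otherwise. The default
  *linear* rule fixes `a = 1`; the *bounded* rule exposes `a ∈ (0, 1]`
  so that some cells remain aggregated even at carrying capacity. The
  bounded rule is implemented as this one-parameter rescaling family —
  an interpretation choice, since only the qualitative requirement
  (solitary probability increasing in `R`, bounded by 1) is pinned
  down.
* **Random group assembly.** Groups sample cells at the population
  composition, so the fast fraction inside groups equals `x`.
* **Extreme payoff separation.** Fast cells earn `p_F = π λ_F` only
  while solitary; slow cells earn `p_S = x (1 − π) λ_S` only inside
  groups, proportionally to the fast fraction they exploit. Both types
  die at the common rate `d`. This is the hardest version of the
  social conflict; it keeps the analysis tractable.
* **Infinite population, deterministic dynamics.** No demographic
  noise, no spatial structure, no explicit group-size distribution.

Parameters (all positive, defaults = the canonical oscillatory set):
`r = 1` (resource growth rate, 1/time), `K = 1` (carrying capacity,
resource units), `d = 1` (death rate, 1/time), `λ_F = 28` and
`λ_S = 16` (dimensionless reproductive efficiencies). `λ_S` doubles as
the evolvable exploitation trait.

## Equilibria and stability

Setting the right-hand side to zero and using payoff equalisation
(`p_F = p_S`), demographic balance (`p̄ R = d`) and resource balance
(`N = r (1 − R/K)`) gives the closed-form interior candidate

```
R̂ = sqrt(d K / (a λ_F)),   x̂ = λ_F π̂ / (λ_S (1 − π̂)),   N̂ = r (1 − R̂/K)
```

with `π̂ = a R̂ / K`. The candidate is polished by a Powell-hybrid root
find on the full system with the analytic Jacobian; the polished root
is authoritative (closed forms are accelerators), and every reported
equilibrium has residual ≤ 1e−10. Existence is the direct admissibility
check `x̂ ∈ (0, 1)`, `0 < R̂ < K`. The commonly quoted inequality
`λ_F K / d > 1 + λ_F / λ_S` is evaluated alongside it: the two
disagree over part of parameter space (the direct condition involves
`sqrt(λ_F K/d)`), so `existence_condition` reports both plus an
agreement flag instead of forcing one.

Stability is classified from the eigenvalues of the analytic Jacobian;
`|leading real part| < 1e−8` is labelled *marginal* so that bisection
brackets at a Hopf point behave predictably. Boundary fixed points
(consumer extinction at `(K, 0, x)` with representatives `x ∈ {0, 1}`
— `x` is arbitrary on the `N = 0` manifold — and the fast-only state
`(R̂, N̂, 1)`) get the same treatment.

The fixed-composition ("neutral") submodel freezes `x` and keeps the
first two equations. Its interior equilibria are roots of
`p̄(x₀, R) R = d` located by a 513-point sign-change scan plus Brent
refinement. At any such root the 2×2 Jacobian has trace `−r R/K < 0`,
and in extensive random sampling the determinant is positive: the
neutral model relaxes to equilibrium and never oscillates, which is
what makes the full model's cycles genuinely *eco-evolutionary*.

## Limit-cycle detection

`find_limit_cycle` integrates with a stiff-capable adaptive solver
(LSODA, `rtol = 1e−10`, `atol = 1e−12` by default — tight because
amplitudes near onset are small) in chunks of 100 time units, recording
upward crossings of `x` through the interior-equilibrium value as a
Poincaré section (the cycle encircles the equilibrium; when no interior
equilibrium exists, the running mean of `x` after a probe run is used).
Convergence requires the last three return times to agree within 1e−6
relative **and** the last three per-cycle `x` amplitudes (from dense
output between crossings) within 1e−3 relative; the amplitude condition
is what makes amplitudes trustworthy close to the Hopf point, where the
period settles long before the orbit does. Defaults cap the transient
at 500 cycles / 30 000 time units; scans that approach the onset
(trait substitution, near-Hopf grids) raise the caps and warm-start
from a neighbouring attractor instead of loosening tolerances.

Decay to a stable equilibrium is detected when the per-cycle amplitude
falls below 1e−8 and is reported as `converged=False` with near-zero
amplitudes and an undefined (NaN) period — not as an error, and period
is never reported as 0 in the stable regime.

On convergence the orbit is re-sampled over exactly one period
(2001 points from the section crossing) for extrema, cycle means,
payoff/birth-rate series, group partitions (`n_fast_alone = N x π` and
analogues, which sum to `N` identically) and phase lags. Peak times use
parabolic sub-sample refinement; lags are reported circularly in
`[0, T)`. A strong self-check holds by construction: the cycle mean of
the per-capita birth rate `b = p̄ R` equals `d` exactly (log N closes
over a period), and the measured value agrees to ~1e−7.

**Generation-time ratios.** "Population growth rate" is ambiguous for
a cycle: the net rate `p̄R − d` averages to exactly zero over a period,
so it cannot define a mean timescale. Both ratios therefore use the
per-capita *birth* rate: `ratio_vs_max_rate = T · max b` and
`ratio_vs_mean_rate = T · ⟨b⟩ = T d` (the identity above), with
per-type analogues (`p_F R`, `p_S R`) also reported.

## Bifurcation analysis

The Hopf point is located by Brent root-finding (a safeguarded
bisection) on the leading eigenvalue real part, to `|Δλ| ≤ 1e−10`,
with an explicit check that the leading pair is complex at the root;
no symbolic characteristic-polynomial condition is used. The Hopf curve
walks a `λ_F` grid, growing a `λ_S` bracket upward from just above the
existence threshold `λ_S > λ_F π̂ / (1 − π̂)` and warm-starting at the
previous critical value; grid points without an interior equilibrium or
a sign change are skipped with a log entry. At `λ_F = 28` (other
parameters canonical) the onset is `λ_S_c ≈ 13.809` with linearised
period `2π/|Im λ| ≈ 5.750`; the computed cycle amplitude above onset
follows the square-root law of a supercritical Hopf (fitted exponent
0.48 over the decade `λ_S − λ_S_c ∈ [0.1, 1]`).

1-D scans report the equilibrium branch everywhere and cycle extrema
and period where the equilibrium is unstable; 2-D sweeps produce
long-format amplitude/period/generation-ratio tables with regimes
`SC` (stable coexistence, amplitude 0, period NaN), `LC`, or `none`
(no interior equilibrium). Sweeps traverse `λ_S` downward so cells near
the Hopf curve inherit warm starts from well-developed cycles. The
library default for heatmaps is whatever grid the caller passes; the
bundled tests and the acceptance script use small grids (≤ 20 points
per axis) sized for desk-scale runtimes.

## Invasion fitness and trait substitution

Mutants differ only in `λ_S`. The five-variable system
`(R, N, x_F, x_Sr, x_Sm)` gives each frequency a replicator term
`x_i R (p_i − p̄)`, which conserves the simplex exactly in continuous
time; integrations renormalise nothing and instead *verify* drift
(< 1e−9 over the runs used). Three estimators:

* **analytic** — `S = d (λ_S − λ_S*) / λ_S*` at the interior
  equilibrium (requires it to exist; raising otherwise is deliberate,
  since below the existence threshold the resident attractor is the
  fast-only state and the formula's derivation fails);
* **cycle average** — `S = (1/T) ∮ R (p_mut − p̄) dt` by composite
  Simpson quadrature on the converged resident cycle. Note an exact
  consequence of the replicator closure `∮ R (p_S − p̄) dt = 0` and the
  demographic closure `∮ (p̄R − d) dt = 0`: the cycle average equals
  `d (λ_S − λ_S*)/λ_S*` *exactly* on any resident cycle, so the
  equilibrium formula extends unchanged into the oscillatory regime
  and the quadrature serves as an independent numerical confirmation
  (observed agreement ~1e−5 relative);
* **direct simulation** — slope of log mutant frequency in the
  five-variable system, started from the resident attractor with the
  mutant at 1e−6 of the slow subpopulation, sampled at integer
  multiples of the resident period (within-cycle oscillation drops out
  of the fit), samples kept only while the frequency stays below 100×
  its initial value. Ten periods (LC) or a 200-time-unit window with
  41 samples (SC) give slopes stable to well under 1%.

The rarity threshold, ceiling and fit window are estimator-stability
choices; no published values exist for them.

`trait_substitution` iterates mutant challenges with a fixed increment
`Δ = 0.1`, using the analytic estimator in SC and the cycle average in
LC, substituting whenever `S > 0` (deterministic substitution; no
mutation-limited waiting times — the slowdown of evolution at high
exploitation is visible in the fitness values themselves, which scale
as `1/λ_S*`: the log–log slope of `S` against `λ_S*` is −1 to
regression round-off). Starting below the onset, the sequence is
strictly increasing, crosses SC→LC exactly once, and never halts in
the scanned range.

## Scenario generator

`canonical_scenarios` pins the study conditions: the canonical
oscillatory set `(1, 1, 1, 28, 16)`; a stable-coexistence companion at
`λ_S = 10` and a near-onset companion at `λ_S = 14` (both
eigenvalue-verified at construction); and a neutral-submodel setup with
`x` frozen at 0.5. `sample_params` draws seeded parameter sets
(`r, K, d` uniform on `[0.5, 2]`, `λ_F` on `[8, 40]`, `λ_S` on
`[2, 30]`) and rejection-filters them into a requested regime via the
eigenvalue check. Default initial conditions are the interior
equilibrium with a 1% multiplicative perturbation along a seeded random
unit vector — deterministic and reproducible.

The generator emulates exactly what the deterministic model describes
and nothing more: no demographic stochasticity, no spatial aggregation
mechanics, no group-size structure, no measurement noise. Passing tests
therefore validate the mathematical analysis of this model, not the
behaviour of real aggregative microbes; in particular, finite
populations would feel the deep `N` minima of high-`λ_S` cycles as
extinction risk, which the ODEs cannot express.

## Numerical choices and degenerate inputs

* LSODA with `rtol 1e−10 / atol 1e−12` everywhere; halving tolerances
  moves detected periods and amplitudes by < 1e−4 relative.
* `π(R)` is clipped at 1 so payoffs stay defined and non-negative under
  transient resource overshoot (`R` slightly above `K`).
* `x ∈ {0, 1}` are exact replicator boundaries (`dx/dt = 0`); the
  `N = 0` manifold is invariant, with `x` reported at representative
  values only.
* Trajectories are validated to stay in the admissible domain within
  1e−6; excursions beyond raise an integration error rather than being
  silently clipped.
* Equilibrium candidates outside the domain (e.g. `x̂ > 1`) are valid
  reports with `exists=False`, never exceptions.

## Problem sizes

Bundled analyses are sized for interactive runs: 20-point resident
grids for the fitness comparison, 9 log-spaced points for the
amplitude-scaling fit, ≤ 10-point 1-D scans, 5×2 sweep cells in tests,
200 random draws for the neutral-stability census. All are
package-level choices; every routine accepts larger grids unchanged.

## Known limitations

* The bounded aggregation rule is one plausible family, not a derived
  form.
* Cycle detection is simulation-based; there is no shooting/collocation
  boundary-value solver, so unstable cycles (none arise here — the
  bifurcation is supercritical) would not be found.
* `hopf_curve` assumes a single stability change along `λ_S` per
  `λ_F`, which holds in the explored region.
* Only `λ_S` evolves; coevolution of `λ_F`, stochastic
  mutation–fixation dynamics and mutant–resident quasi-neutral
  coexistence are out of scope.
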