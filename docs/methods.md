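# Methods

## Model overview and assumptions

`biofilmhedge` models a clonal bacterial lineage alternating between two
phenotypes inside ephemeral habitat patches. The planktonic compartment
*P* grows exponentially at rate *r* (per unit time) and loses cells to the
biofilm compartment *B* at the per-capita colonization rate *c*. In the
simplified (default) model the biofilm neither divides nor disperses:
biofilm cells behave like persisters or spores, a non-dividing
subpopulation fed by vegetative growth. Cell counts are continuous
throughout; there is no demographic stochasticity, no within-patch
resource depletion, and no spatial structure in the compartment model.

The full model (`integrate_full_model`) adds intrinsic biofilm growth
G(B) — linear (G = g, cells/time) or quadratic (G = g·√B, the
surface-limited form for a growing body) — and dispersal at per-capita
rate *d* from biofilm back to plankton. **Assumption:** dispersed cells
re-enter the planktonic compartment (dP/dt gains +dB); an alternative in
which dispersed cells are lost would only weaken the already-small effect
of dispersal at the default d = 0.01.

Fitness across patches is per founding cell:
W(c, r, t) = k_p·e^{(r−c)t} + k_b·[e^{(r−c)t} − 1]·c/(r−c), where k_p and
k_b ∈ [0, 1] are per-cell probabilities of founding the next patch (the
reproductive values of the two cell types). W is a reproductive number:
expected next-patch founders per current founder. The strategy space for
optimization is c ∈ [0, r], boundaries included; values c > r are valid
inputs to the dynamics (the plankton then declines) but are not part of
the strategy space, since beyond c = r additional colonization only
shrinks both compartments' source.

## Parameters

| symbol | meaning | units | default |
|---|---|---|---|
| r | planktonic growth rate | 1/time | 0.06 |
| c | colonization rate (plankton → biofilm) | 1/time | varies |
| t | patch/growth duration | time | 40 |
| P0 | planktonic inoculum | cells | 5·10⁶ (patch runs), 5000 (passaging) |
| k_p, k_b | transmission weights | — | 0.1, 0.6 |
| d | dispersal rate (full model) | 1/time | 0.01 |
| g | biofilm growth coefficient | cells/time (linear); cells^½/time (quadratic) | 4·10⁴ / 10³ |

With the defaults, rt = 2.4 > 2, so the biofilm count has an interior
maximum in c and the optimal allocation is mixed even under strong
biofilm transmission advantage.

## Stochastic environments (the synthetic-data generator)

The passaging simulator draws (r, t, k_p, k_b) independently each passage
from normal distributions with fixed means (µ_r = 0.06, µ_t = 40,
µ_kp = 0.1, µ_kb = 0.6) and a treatment-dependent variance using divisors
100 (low), 9 (mid), and 2.75 (high). Draws are thresholded by clipping to
logical ranges: 0 ≤ k_p, k_b ≤ 1, r > 0 (floor 10⁻⁹), t ≥ 1; t is treated
as continuous.

Two readings of the variance divisor are supported. The default,
`convention="cv"`, takes σ = µ/√divisor (a fixed coefficient of
variation, i.e. σ² = µ²/divisor). Under this reading clipping shifts no
parameter's mean by more than ~3% (the k_b shift, ≈ −2.9% at the high
treatment, is the largest; `mean_shift_report` computes this and the test
suite checks it against the analytic clipped-normal mean). The literal
reading σ² = µ/divisor is exposed as `convention="literal"` for
comparison; it gives r and k_p standard deviations larger than their
means, and clipping then inflates the k_p mean by >30%, so it is not the
default. Clipping (not rejection sampling) is used because resampling
would shift the means further. No correlation structure or temporal
autocorrelation is modelled.

What the generator emulates: serially independent environmental
fluctuation in growth opportunity and transmission success. What it does
not: regime persistence, correlated stresses (a disturbance that lowers
k_p while raising k_b), or density dependence. Passing tests therefore
demonstrate bet-hedging logic under idealized white-noise environments,
not forecasts for any particular natural regime.

## Passaging conventions

Each passage grows the (all-planktonic) founders by the closed forms for
the drawn (r, t), then transmits k_p·P(t) + k_b·B(t) cells as the next
inoculum. Per-passage R0 = founders_out/founders_in equals W of the drawn
environment and is independent of founder count (linearity); founder
trajectories matter only for extinction, flagged when the continuous
count underflows 10⁻³⁰⁰, after which R0 = 0 for the remaining passages.
Geometric mean R0 is defined as 0 whenever any passage's R0 is 0:
extinction is absorbing.

The colonization grid c ∈ (0, 0.2) is applied as an **absolute** rate by
default (`c_mode="absolute"`) and reported against c/µ_r, which then
spans (0, 3.3] and brackets the fixed-environment optimum c*/r ≈ 0.496.
This choice was made after probing the alternative (`c_mode="relative"`,
c scaled by each passage's drawn r, still available in the config): under
the relative reading the mean and geometric-mean response curves on
(0, 0.2] are monotone increasing in every treatment — no interior
geometric-mean maximum exists inside the grid — whereas the absolute
reading produces declining R0 variance and interior geometric-mean peaks,
the signatures the simulation exists to study. Two shape claims do not
reproduce under either reading at the default scale (100 replicates × 10
passages): the *low*-variance average R0 retains a shallow interior hump
near c/µ_r ≈ 0.5 (it is otherwise declining, Spearman ρ ≈ −0.98), and the
*high*-variance average R0 is monotone declining rather than humped. This
follows analytically from E[R0](c) = E[k_p]·E[e^{(r−c)t}] + E[k_b]·
E[(e^{(r−c)t}−1)·c/(r−c)]: the first term is monotone decreasing in c and
is amplified by environmental variance (lognormal-type tail inflation),
so higher variance pushes the mean curve toward monotone decline, while
low variance leaves the deterministic hump visible. The corresponding
acceptance test states the stronger claims and is allowed to fail on
those two sub-checks.

Per-lineage summaries (variance with n−1 denominator, arithmetic mean,
geometric mean of R0 across passages) are aggregated across replicates as
a mean with a normal-approximation 95% CI; a replicate-level bootstrap
was considered and rejected as unnecessary at 100 replicates. Response
curves are characterized by OLS fits of statistic ~ c and ~ c + c²
compared by AIC (full Gaussian log-likelihood convention; the additive
constant is shared so the choice is convention-invariant).

## Numerical choices

- **c = r singularities.** P, B, and W are evaluated by their analytic
  limits (P = P0, B = c·P0·t, W = k_p + k_b·r·t) inside a guard band
  |r − c| < 10⁻¹²·max(r, 1), so the optimizer can probe the pure-biofilm
  boundary exactly.
- **d(P+B)/dc near c = r** is a 0/0 form; for |r − c|·t < 10⁻⁴ it is
  evaluated by the series −r·P0·[t²/2 + (r−c)·t³/3].
- **ODE integration** uses LSODA with rtol 10⁻⁸, atol 10⁻⁶ cells (P spans
  ~7 orders of magnitude); the quadratic biofilm term uses √max(B, 0) so
  G(0) = 0 without numerical failure.
- **Optimization** of W (and of B) uses a dense pre-scan (1024 points for
  W, 512 for B) followed by bounded scalar refinement on the bracketing
  interval. W(c) is observed unimodal on [0, r] in all probed regimes but
  this is not proven, hence the pre-scan; a 10⁵-point brute-force grid
  cross-check runs in the test suite. Optima within 10⁻⁶·r of a boundary
  are classified as that boundary. Flat ties resolve toward larger c. The
  degenerate case k_p = k_b = 0 (identically zero fitness) is classified
  as pure plankton by convention.
- **Regime boundaries** are located by bisection in k_b (to 10⁻⁴) along
  each k_p grid column, using the regime classifier; absent transitions
  return NaN rather than failing.

## Lattice growth simulator

The frontier simulator abstracts nutrient-limited growth arrest to a
purely geometric rule: cells on a square/cubic lattice divide into a free
von-Neumann neighbor only if they lie within `active_depth` taxicab steps
of the exposed front (computed by a distance transform; finite domain
boundaries are walls, not front). Divisions happen in synchronous epochs
of `division_time`, in randomized order, competing for free sites. There
is no nutrient field, EPS mechanics, or pushing — the simulator tests
functional-form claims (exponential → polynomial order = dimensionality →
order decay at each confluence), not any particular biofilm's curve.

Polynomial order is estimated as the OLS slope of log N vs log t on a
window; exponential curves are flagged non-convergent via upward slope
drift between half-windows. Radial order checks seed a compact multicell
cluster (5 cells in 2D, 7 in 3D) rather than a single cell: a lone cell's
start-up lag acts as a time offset that biases the log-log slope upward
over finite windows, while a macroscopic seed starts the front in its
steady regime (front speed ≈ 0.93 sites/epoch at depth 1). Windows for
order estimation use the later half of each run for the same reason.

## Known limitations

- The compartment model ignores within-patch density dependence; W can
  exceed realistic burst sizes for long, rich patches.
- The bet-hedging summaries are sensitive to the tails of the drawn r and
  t; means (though not geometric means) can be dominated by a few
  extreme draws at high variance.
- The lattice simulator's order estimates converge slowly near confluence
  events; windows straddling a confluence yield intermediate orders.
- The evolutionary analysis is a static argmax over c; no
  mutation-selection dynamics of the colonization rate are modelled.
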