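# Methods

## Model

The package simulates one-dimensional overdamped Langevin (Brownian)
dynamics. A process is a pair (U, ε): an external potential U(x) with
force f = −U′, and a temperature ε. In continuous time the SDE is

    dx_t = f(x_t) dt + √(2ε) dW_t.

The *physical* object here, however, is the discrete-time recursion
(explicit Euler–Maruyama, drift at the left endpoint):

    x_i = x_{i−1} + f(x_{i−1}) Δt + √(2εΔt) ξ_i,      ξ_i ~ iid N(0,1),

on a uniform grid of N_t steps of size Δt, T = N_t·Δt. The noise history
{ξ_i} is a property of the thermal reservoir, independent of the system;
a path is a deterministic function of (x_0, {ξ_i}), and this map is a
bijection: `recover_noise` inverts `propagate` algebraically, with no
tolerance beyond floating-point rounding.

The discrete path density gives the Onsager–Machlup (OM) functional

    I = (Δt/4ε) Σ_i ((x_i − x_{i−1})/Δt − f(x_{i−1}))²  =  ½ Σ_i ξ_i²,

so over self-generated paths I is χ²-distributed with mean and variance
N_t/2, independent of the drift — the OM functional carries no
path-specific information and cannot serve as a minimizable
"thermodynamic action". The package therefore deliberately contains no
action-minimization machinery.

## The two change-of-measure constructions

**Common noise.** Two processes with the same (T, Δt, ε) driven by the
same noise history are linked by the bijective map B (recover the noise
under one process, re-propagate under the other, same start point). The
log change of measure is the difference of the two OM functionals; both
equal ½Σξ², so log L = 0 identically and the KL divergence vanishes for
*every* Δt > 0. This is implemented and asserted at 1e−10 absolute.

**Common path.** Evaluating both processes' densities on the same path
leaves, after the divergent kinetic terms cancel, the J functional

    J = (Δt/2ε) Σ_i ( ½ f²(z_{i−1}) − ((z_i − z_{i−1})/Δt) f(z_{i−1}) ),

and D(Q_a‖Q_b) = E_a[J_b − J_a]. The orientation is the standard KL
(expectation under the generating measure of the log of its own density
over the other's); it is the unique sign convention consistent with all
three closed forms below, each of which was re-derived independently
from Gaussian moments before the estimators were written. Itô
integration by parts gives the continuous-time form

    J_CT = (U(z_T) − U(z_0))/(2ε) + (1/2ε) ∫_0^T (½f² − εU″) dt,

with the curvature (Laplacian) term that distinguishes the Itô–Girsanov
action from the discrete OM functional.

Closed-form references implemented and verified by Monte Carlo:

| pair (generating ‖ reference) | divergence |
|---|---|
| free ‖ constant drift c | c²T/(4ε) |
| free ‖ OU(A) | A²T²/4 |
| OU(A) ‖ free | (1/8)(e^{−2AT} − 1 + 2AT) |
| Brownian bridge ‖ OU bridge | (AT/12)(AT − 6) |

The last entry is negative for AT < 6 — a violation of Jensen's
inequality showing the common-path construction is invalid on
endpoint-constrained (bridge) path spaces. The zero crossing is located
by bisection on an independent quadrature of the bridge-variance
integral (1/2ε)∫(½A²·2εt(1−t/T) − εA)dt, not on the factored closed
form, so root and formula cross-check each other.

## Numerical choices

- **Left-point (Itô) Riemann sums everywhere.** The recursion evaluates
  drift at x_{i−1}; a trapezoid rule would introduce a Stratonovich
  correction and silently change the measure.
- **Bridge samplers are exact Gaussian constructions.** The Brownian
  bridge is a free path plus linear correction; the OU bridge uses
  sequential conditioning with the exact OU kernel
  x′ = x·e^{−AΔt} + √((ε/A)(1 − e^{−2AΔt}))·ξ combined with the kernel
  over the remaining time to the pinned endpoint. Both pin endpoints
  exactly and have unbiased marginals; both were validated against the
  joint-Gaussian conditional variance
  Var(x_t | x_0 = x_T = 0) = 2(ε/A)·sinh(At)sinh(A(T−t))/sinh(AT)
  and its A→0 Brownian-bridge limit 2εt(1 − t/T).
- **Tolerance hierarchy.** Exact algebraic identities (bijection, OM/J
  cancellation, unit change of measure, drift shift) at 1e−10…1e−12;
  Monte-Carlo comparisons at 3 standard errors of the mean (estimands
  are means of light-tailed functionals); the `reproduce --quick` mode
  shrinks ensembles 10× and widens to 5 SE.
- **MC validation grid** defaults to Δt = 1e−3, T = 1 with 1e4–2e4
  paths, which keeps discretization bias (O(Δt)) below the MC noise.
- **Degenerate inputs.** Non-finite positions abort propagation with the
  offending step index (stiff potential + large Δt must fail loudly);
  empty ensembles, mismatched grids, and mismatched temperatures raise
  before any computation.
- **RNG.** One integer master seed per operation feeds a PCG64
  generator; ensemble rows are filled in order, so path k is unchanged
  when the ensemble grows. Seeds are recorded in path provenance and in
  every result record.

## Potentials

Built-ins: `zero` (free diffusion), `linear(c)` with U = −cx (constant
drift), `harmonic(A)` with U = Ax²/2 (OU, A > 0), and an asymmetric
`double_well(h, a, w)`. The double well is the smooth quartic
U(x) = h(1 − x²m(x))² with m(x) blending 1/a² (left) into 1/(aw)² (right)
through a tanh of width 0.2a: barrier of height h at x = 0, minima at
zero energy near −a and +aw, the right well w times broader. The blend
keeps U ∈ C^∞, at the cost of shifting the minima by O(1e−4·a); the
specific quartic is a design choice — any smooth, bounded-below
(Kato-class) double well would do. Potentials are one-dimensional
throughout; the `Potential` contract (energy/force/curvature triple)
is what a d-dimensional extension would generalize.

Analytic derivatives are validated against central finite differences
(force: step 1e−5, tolerance 1e−6; curvature: step 1e−4, tolerance 1e−4,
both relative with a unit floor — the wider curvature stencil trades
truncation error for the cancellation error of the second difference).

## Residence-time free energy

For an ergodic trajectory in a two-basin potential, F_B − F_A =
−ε·ln(t_B/t_A) from occupancy times, compared against the Boltzmann
quadrature −ε·ln(∫_B e^{−U/ε}/∫_A e^{−U/ε}). The dividing point defaults
to the numerically located barrier top (the standard dividing surface);
all N_t+1 samples count with full Δt weight, ties to basin A. The error
bar is a block bootstrap (50 blocks, i.e. block length T/50, well above
the hopping correlation time) because occupancy indicators are strongly
autocorrelated. The recovery study runs the double well h=1, a=1, w=2 at
ε = 0.6 — temperature comparable to the barrier, giving a Kramers
hopping rate of roughly 0.17 per unit time — for T = 600 at Δt = 2e−3,
so several hundred crossings support the estimate.

## Spectral drift-independence diagnostic

The claim probed: above a finite frequency cutoff, path Fourier
components are set by the noise alone, because the drift is smooth and
band-limited. Implementation detail that matters: Brownian paths are not
periodic, and a raw FFT leaks the endpoint jump as O(1/k²) power into
*every* bin — enough to mask the effect entirely. Each path therefore
has the straight line through its endpoints subtracted before the FFT.
Two consequences, both asserted: (i) a constant drift is removed exactly
by the detrend (it *is* the bijective shift map, so constant-drift and
free ensembles agree in every bin — the drift-shift equivalence in
frequency space); (ii) a state-dependent drift (OU with A = 5) differs
from free diffusion only in the lowest bins, while bins above the
default cutoff N_t/10 agree within Monte-Carlo error.

## What the synthetic ensembles do and do not show

All inputs are generated internally: Gaussian noise histories, Euler
paths, and exact Gaussian bridges. These are precisely the objects the
theory is about, so the Monte-Carlo checks are genuine tests of the
estimators and samplers, not of data quality. What they cannot show is
anything about real molecular systems: the potentials are 1-D toys, the
dynamics is overdamped with constant diffusion, and no force field,
solvent, or inertial effect is represented. The package's claims are
mathematical — about measures on discrete path space — and the tests
should be read that way.

## Problem sizes

Default validation sizes (chosen so discretization bias stays below the
Monte-Carlo error): 2×10⁴ paths at Δt = 1e−3, T = 1 for the drift/OU
divergences; 10⁴ bridges for the Jensen violation; 10⁴ paths of
N_t = 500 for the OM statistics; 10³ paths at Δt = 1e−4 for the
quadratic variation; one T = 600 trajectory for the free-energy
recovery. `reproduce --quick` divides ensemble sizes by 10.

## Known limitations

- One spatial dimension only (by design; see the Potential contract).
- Explicit Euler only: stiff potentials need small Δt, and the
  propagator fails loudly rather than sub-stepping.
- The common-path MC estimators inherit O(Δt) discretization bias from
  both the Euler paths and the left-point quadrature of J; at the
  default Δt = 1e−3 this is below the 3-SE band, but it is visible if
  ensembles are pushed to ≳10⁶ paths without shrinking Δt.
- The Jensen scan's MC column uses independent bridges per A value;
  adjacent rows are uncorrelated, so the scan is not a smooth curve
  estimator, just a per-point check.
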