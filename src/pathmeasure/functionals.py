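"""Path functionals: Onsager-Machlup, J, Ito-Girsanov action, quadratic variation.

The discrete Onsager-Machlup (OM) functional

    I = (dt / 4 eps) sum_i ((x_i - x_{i-1})/dt - f(x_{i-1}))^2

is the negative log path density (up to normalization) of a discrete
Brownian path; by the noise-recovery identity it equals half the sum of
squared noise variates, so over self-generated paths it is Gaussian with
mean and variance Nt/2, independent of the drift.

The J functional keeps only the force-dependent part of I that survives
the cancellation when two processes are compared on the same path:

    J = (dt / 2 eps) sum_i ( f(z_{i-1})^2 / 2 - ((z_i - z_{i-1})/dt) f(z_{i-1}) ).

Its continuous-time form, obtained by Ito integration by parts, trades the
stochastic integral for a potential boundary term plus a curvature
(Laplacian) correction:

    J_CT = (U(z_T) - U(z_0)) / (2 eps)
           + (1 / 2 eps) * int_0^T ( f^2/2 - eps U'' ) dt.

All time integrals use left-point (Ito) Riemann sums: the discrete
recursion evaluates drift at the left endpoint, and a trapezoid rule would
smuggle in a Stratonovich correction.
"""

from __future__ import annotations

import numpy as np

from .dynamics import Path, ProcessSpec
from .potentials import Potential

__all__ = [
    "om_functional",
    "j_functional",
    "j_continuous",
    "path_potential_G",
    "ig_action",
    "quadratic_variation",
]


def _increments_and_left(path: Path) -> tuple[np.ndarray, np.ndarray]:
    x = path.positions
    if x.size < 2:
        raise ValueError("path must have at least 2 positions")
    return np.diff(x), x[:-1]


def om_functional(process: ProcessSpec, path: Path) -> float:
    """Discrete Onsager-Machlup functional I of ``path`` under ``process``.

    Non-negative; equals (1/2) sum xi_i^2 of the recovered noise history.
    """
    dx, left = _increments_and_left(path)
    dt = path.grid.dt
    eps = process.temperature
    resid = dx / dt - process.potential.force(left)
    return float(dt / (4.0 * eps) * np.sum(resid**2))


def j_functional(process: ProcessSpec, path: Path) -> float:
    """Discrete J functional of ``path`` under ``process``.

    Vanishes identically for zero force; for any two processes a, b on the
    same path, I_a - I_b = J_a - J_b exactly (the kinetic term cancels).
    """
    dx, left = _increments_and_left(path)
    dt = path.grid.dt
    eps = process.temperature
    f = process.potential.force(left)
    return float(1.0 / (2.0 * eps) * np.sum(0.5 * f**2 * dt - dx * f))


def j_continuous(process: ProcessSpec, path: Path) -> float:
    """Continuous-time form of J: boundary energies plus the G-integral.

    J_CT = (U(z_T) - U(z_0))/(2 eps) + (dt / 2 eps) sum_i (f^2/2 - eps U'')
    with the sum a left-point Riemann quadrature of the time integral.
    """
    x = path.positions
    if x.size < 2:
        raise ValueError("path must have at least 2 positions")
    dt = path.grid.dt
    eps = process.temperature
    pot = process.potential
    boundary = (pot.energy(x[-1]) - pot.energy(x[0])) / (2.0 * eps)
    left = x[:-1]
    integrand = 0.5 * pot.force(left) ** 2 - eps * pot.curvature(left)
    return float(boundary + dt / (2.0 * eps) * np.sum(integrand))


def path_potential_G(potential: Potential, eps: float, x) -> np.ndarray | float:
    """The path potential G(x) = f(x)^2 / 2 - eps U''(x).

    The state-dependent part of the Ito-Girsanov action; its maxima, not
    the energy minima, can dominate that action's minimizers.
    """
    out = 0.5 * potential.force(x) ** 2 - eps * potential.curvature(x)
    return float(out) if np.ndim(x) == 0 else out


def ig_action(process: ProcessSpec, path: Path) -> float:
    """Ito-Girsanov action: kinetic term plus the G-integral.

    I_IG = (dt / 2 eps) sum_i ( ((x_i - x_{i-1})/dt)^2 / 2 + G(x_{i-1}) ).
    """
    dx, left = _increments_and_left(path)
    dt = path.grid.dt
    eps = process.temperature
    g = path_potential_G(process.potential, eps, left)
    return float(dt / (2.0 * eps) * np.sum(0.5 * (dx / dt) ** 2 + g))


def quadratic_variation(path: Path) -> float:
    """Sum of squared increments; converges to 2 eps T regardless of drift."""
    dx, _ = _increments_and_left(path)
    return float(np.sum(dx**2))
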