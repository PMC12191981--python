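"""Residence-time thermodynamics and spectral path diagnostics.

For an ergodic trajectory in a two-basin potential, the equivalence of the
microcanonical and canonical ensembles relates basin occupancy times to
the free-energy difference:

    F_B - F_A = -eps * ln(t_B / t_A).

The Boltzmann quadrature reference -eps * ln(Z_B / Z_A), with Z the
configurational integral of exp(-U/eps) over each basin, provides the
independent check.

The spectral diagnostic probes the drift-(in)dependence of path Fourier
components: above a finite frequency cutoff the power spectrum of
Brownian paths is set by the noise alone, while the drift contributes only
to a handful of low-frequency modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .dynamics import Path, positions_matrix
from .potentials import Potential

__all__ = [
    "BasinDefinition",
    "OccupancyResult",
    "find_dividing_point",
    "assign_basins",
    "free_energy_from_residence",
    "boltzmann_reference",
    "block_bootstrap_free_energy",
    "spectral_profile",
]


@dataclass(frozen=True)
class BasinDefinition:
    """Two basins split at the barrier top: A below, B above the divider."""

    dividing_point: float

    def __post_init__(self):
        if not math.isfinite(self.dividing_point):
            raise ValueError("dividing point must be finite")


@dataclass(frozen=True)
class OccupancyResult:
    """Basin occupancy times of one trajectory.

    Every sample (all Nt+1, endpoints included, ties to A) is assigned to
    exactly one basin with full dt weight, so time_A + time_B equals the
    total sampled time (Nt+1) * dt.
    """

    time_A: float
    time_B: float
    n_crossings: int
    delta_F: float | None = None


def find_dividing_point(
    potential: Potential, x_range: tuple[float, float], n_probe: int = 2001
) -> BasinDefinition:
    """Locate the barrier top between the two minima of a double well.

    Coarse grid scan for the two lowest minima, then a bounded 1-D
    maximization of U between them.
    """
    lo, hi = x_range
    xs = np.linspace(lo, hi, n_probe)
    u = potential.energy(xs)
    interior = np.where((u[1:-1] <= u[:-2]) & (u[1:-1] <= u[2:]))[0] + 1
    if interior.size < 2:
        raise ValueError("could not locate two minima in the probe range")
    order = interior[np.argsort(u[interior])][:2]
    a, b = sorted(xs[order])
    res = minimize_scalar(
        lambda x: -potential.energy(np.asarray(x)), bounds=(a, b), method="bounded"
    )
    return BasinDefinition(float(res.x))


def assign_basins(path: Path, basins: BasinDefinition) -> OccupancyResult:
    """Count basin occupancy times and crossings along a trajectory."""
    x = path.positions
    dt = path.grid.dt
    in_B = x > basins.dividing_point  # ties assigned to A
    n_B = int(np.count_nonzero(in_B))
    n_A = x.size - n_B
    crossings = int(np.count_nonzero(np.diff(in_B.astype(np.int8)) != 0))
    return OccupancyResult(time_A=n_A * dt, time_B=n_B * dt, n_crossings=crossings)


def free_energy_from_residence(occ: OccupancyResult, eps: float) -> float:
    """F_B - F_A = -eps * ln(t_B / t_A) from occupancy times."""
    if occ.time_A <= 0 or occ.time_B <= 0:
        raise ValueError(
            "zero occupancy in one basin: trajectory too short for a "
            "residence-time free energy"
        )
    return -eps * math.log(occ.time_B / occ.time_A)


def boltzmann_reference(
    potential: Potential,
    eps: float,
    basins: BasinDefinition,
    x_range: tuple[float, float],
) -> float:
    """Quadrature reference -eps * ln(Z_B / Z_A) from the Boltzmann weight.

    ``x_range`` must cover both basins with negligible weight at its ends.
    """
    lo, hi = x_range
    div = basins.dividing_point
    if not lo < div < hi:
        raise ValueError("integration range must bracket the dividing point")

    def w(x: float) -> float:
        return math.exp(-float(potential.energy(np.asarray(x))) / eps)

    z_a, err_a = quad(w, lo, div, limit=200)
    z_b, err_b = quad(w, div, hi, limit=200)
    if z_a <= 0 or z_b <= 0 or err_a > 1e-8 * z_a + 1e-300 or err_b > 1e-8 * z_b + 1e-300:
        raise ValueError("Boltzmann quadrature did not converge on the given range")
    return -eps * math.log(z_b / z_a)


def block_bootstrap_free_energy(
    path: Path,
    basins: BasinDefinition,
    eps: float,
    n_blocks: int = 50,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Residence-time free energy with a block-bootstrap standard error.

    Occupancy indicators are autocorrelated on the hopping timescale, so
    plain binomial errors are far too small; resampling contiguous blocks
    (default 50, i.e. block length T/50) preserves the correlation
    structure.  Returns (delta_F, bootstrap SE).
    """
    x = path.positions
    in_B = (x > basins.dividing_point).astype(float)
    occ = assign_basins(path, basins)
    delta_f = free_energy_from_residence(occ, eps)

    blocks = np.array_split(in_B, n_blocks)
    frac_b = np.array([b.mean() for b in blocks])
    sizes = np.array([b.size for b in blocks], dtype=float)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n_blocks, size=n_blocks)
        fb = np.average(frac_b[idx], weights=sizes[idx])
        fb = min(max(fb, 1e-12), 1.0 - 1e-12)
        boot[k] = -eps * math.log(fb / (1.0 - fb))
    return delta_f, float(boot.std(ddof=1))


def spectral_profile(paths: Sequence[Path]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble-mean power spectrum of line-detrended positions.

    Each path has the straight line through its endpoints subtracted
    before the FFT: a Brownian path is not periodic, and the endpoint
    jump otherwise leaks O(1/k^2) power into every bin, masking the
    frequency separation the diagnostic is after.  After detrending, a
    state-dependent drift shows up only in the lowest few bins (the
    force is smooth, so its contribution is band-limited), while the
    high-frequency bins are set by the noise alone.  A constant drift is
    removed exactly by the detrend — it is the bijective shift map in
    frequency space — so constant-drift ensembles match the free ones in
    every bin.

    Returns (frequency indices, mean power per bin, SE of the mean).
    """
    pos = positions_matrix(paths)
    n_steps = paths[0].grid.n_steps
    frac = np.arange(n_steps + 1) / n_steps
    trend = pos[:, :1] + (pos[:, -1:] - pos[:, :1]) * frac[None, :]
    detrended = pos - trend
    power = np.abs(np.fft.rfft(detrended, axis=1)) ** 2
    n = power.shape[0]
    mean = power.mean(axis=0)
    se = power.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return np.arange(mean.size), mean, se
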