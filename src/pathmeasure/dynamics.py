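"""Discrete-time Brownian dynamics: noise histories, paths, and bridges.

The physical model is the explicit Euler-Maruyama recursion

    x_i = x_{i-1} + f(x_{i-1}) dt + sqrt(2 eps dt) xi_i,

with iid standard-normal noise ``xi_i`` drawn from a thermal reservoir at
temperature ``eps``.  A path of ``Nt`` steps is fully determined by its
noise history ``{xi_i}`` and start point, and the map between noise
histories and paths is a bijection: ``recover_noise`` inverts
``propagate`` exactly.  Two processes driven by the same noise history are
linked by the bijective map ``map_path`` (same noise, same start point,
different drift).

Bridge samplers draw Brownian and Ornstein-Uhlenbeck paths conditioned on
both endpoints, using exact Gaussian constructions (no rejection, no
discretization bias in the marginals beyond the grid itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .potentials import Potential, make_potential

__all__ = [
    "TimeGrid",
    "ProcessSpec",
    "NoiseHistory",
    "Path",
    "sample_noise",
    "propagate",
    "propagate_ensemble",
    "recover_noise",
    "map_path",
    "ou_exact_step",
    "sample_brownian_bridge",
    "sample_ou_bridge",
    "sample_paths",
    "positions_matrix",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time discretization: ``Nt`` steps of size ``dt``.

    ``positions[i]`` of a path on this grid is at time ``t = i * dt``;
    the total duration ``T = Nt * dt`` is derived, never stored.
    """

    dt: float
    n_steps: int

    def __post_init__(self):
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValueError(f"dt must be positive and finite, got {self.dt}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def times(self) -> np.ndarray:
        """The Nt+1 sample times i*dt, endpoints included."""
        return np.arange(self.n_steps + 1) * self.dt


@dataclass(frozen=True)
class ProcessSpec:
    """A Brownian process: drift from ``potential``, temperature ``eps``."""

    potential: Potential
    temperature: float

    def __post_init__(self):
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def tag(self) -> str:
        params = ",".join(f"{k}={v:g}" for k, v in self.potential.params.items())
        return f"{self.potential.name}({params});eps={self.temperature:g}"


@dataclass(frozen=True)
class NoiseHistory:
    """An Nt-long sequence of standard-normal variates driving one path."""

    values: np.ndarray
    grid: TimeGrid
    seed: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != self.grid.n_steps:
            raise ValueError(
                f"noise history must have length {self.grid.n_steps}, got shape {v.shape}"
            )


@dataclass(frozen=True)
class Path:
    """An (Nt+1)-long position sequence on a time grid.

    ``process`` records the process that generated the path (needed by the
    common-noise map); ``provenance`` records seed and generator name.
    """

    positions: np.ndarray
    grid: TimeGrid
    process: ProcessSpec | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", p)
        if p.ndim != 1 or p.size != self.grid.n_steps + 1:
            raise ValueError(
                f"path must have length {self.grid.n_steps + 1}, got shape {p.shape}"
            )
        if not np.all(np.isfinite(p)):
            raise ValueError("path contains non-finite positions")


def sample_noise(grid: TimeGrid, n_paths: int, seed: int) -> list[NoiseHistory]:
    """Draw ``n_paths`` independent noise histories.

    Reproducible from ``(seed, grid, n_paths)``.  Rows are filled in order
    from a single PCG64 stream, so history ``k`` does not change when
    ``n_paths`` is increased.
    """
    if n_paths < 1:
        raise ValueError(f"n_paths must be >= 1, got {n_paths}")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal((n_paths, grid.n_steps))
    return [NoiseHistory(xi[k], grid, seed=seed) for k in range(n_paths)]


def _propagate_matrix(
    process: ProcessSpec, grid: TimeGrid, xi: np.ndarray, x0
) -> np.ndarray:
    """Euler-Maruyama over a (n_paths, Nt) noise matrix -> (n_paths, Nt+1)."""
    n_paths, n_steps = xi.shape
    force = process.potential.force
    dt = grid.dt
    amp = math.sqrt(2.0 * process.temperature * dt)
    out = np.empty((n_paths, n_steps + 1))
    x = np.broadcast_to(np.asarray(x0, dtype=float), (n_paths,)).copy()
    out[:, 0] = x
    for i in range(n_steps):
        x = x + force(x) * dt + amp * xi[:, i]
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite position at step {i + 1}: "
                f"dt={dt} is unstable for potential '{process.potential.name}'"
            )
        out[:, i + 1] = x
    return out


def propagate(
    process: ProcessSpec, grid: TimeGrid, noise: NoiseHistory, x0: float
) -> Path:
    """Integrate the Euler-Maruyama recursion from ``x0``.

    The drift is evaluated at the left endpoint of each step (explicit
    scheme); aborts with the offending step index if positions blow up.
    """
    if noise.grid != grid:
        raise ValueError("noise history was drawn on a different time grid")
    pos = _propagate_matrix(process, grid, noise.values[None, :], x0)[0]
    return Path(
        pos,
        grid,
        process=process,
        provenance={"generator": "propagate", "seed": noise.seed},
    )


def propagate_ensemble(
    process: ProcessSpec,
    grid: TimeGrid,
    noises: Sequence[NoiseHistory],
    x0: float,
) -> list[Path]:
    """Propagate many noise histories at once (vectorized across paths)."""
    if len(noises) == 0:
        raise ValueError("empty noise ensemble")
    for n in noises:
        if n.grid != grid:
            raise ValueError("noise history was drawn on a different time grid")
    xi = np.stack([n.values for n in noises])
    pos = _propagate_matrix(process, grid, xi, x0)
    return [
        Path(
            pos[k],
            grid,
            process=process,
            provenance={"generator": "propagate", "seed": noises[k].seed, "index": k},
        )
        for k in range(len(noises))
    ]


def sample_paths(
    process: ProcessSpec, grid: TimeGrid, n_paths: int, seed: int, x0: float = 0.0
) -> list[Path]:
    """Draw fresh noise and propagate: the standard ensemble generator.

    Consumes the same noise stream as ``sample_noise`` followed by
    ``propagate_ensemble``, but skips the per-history objects (one matrix
    draw, one matrix propagation).
    """
    if n_paths < 1:
        raise ValueError(f"n_paths must be >= 1, got {n_paths}")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal((n_paths, grid.n_steps))
    pos = _propagate_matrix(process, grid, xi, x0)
    return [
        Path(
            pos[k],
            grid,
            process=process,
            provenance={"generator": "propagate", "seed": seed, "index": k},
        )
        for k in range(n_paths)
    ]


def recover_noise(process: ProcessSpec, path: Path) -> NoiseHistory:
    """Invert Euler-Maruyama: the noise history that generated ``path``.

    xi_i = sqrt(dt / 2 eps) * ((x_i - x_{i-1}) / dt - f(x_{i-1})).
    Exact inverse of :func:`propagate` for the same process.
    """
    x = path.positions
    dt = path.grid.dt
    increments = np.diff(x) / dt
    f = process.potential.force(x[:-1])
    xi = math.sqrt(dt / (2.0 * process.temperature)) * (increments - f)
    return NoiseHistory(xi, path.grid, seed=path.provenance.get("seed"))


def map_path(path: Path, target: ProcessSpec, source: ProcessSpec | None = None) -> Path:
    """The bijective common-noise map between two processes.

    Recovers the noise history of ``path`` under its generating process
    and re-propagates it under ``target`` from the same start point.
    """
    if source is None:
        source = path.process
    if source is None:
        raise ValueError("path carries no generating process; pass `source` explicitly")
    noise = recover_noise(source, path)
    mapped = propagate(target, path.grid, noise, float(path.positions[0]))
    return Path(
        mapped.positions,
        path.grid,
        process=target,
        provenance={**path.provenance, "generator": "map_path"},
    )


def ou_exact_step(x, A: float, eps: float, dt: float, xi):
    """One step of the exact Ornstein-Uhlenbeck transition kernel.

    x' = x e^{-A dt} + sqrt((eps/A)(1 - e^{-2 A dt})) * xi.

    This is the analytic solution of dx = -A x dt + sqrt(2 eps) dW over a
    step of length dt, used by the OU bridge sampler and as a reference
    for Euler-Maruyama convergence tests.
    """
    if A <= 0:
        raise ValueError(f"OU constant A must be positive, got {A}")
    decay = math.exp(-A * dt)
    sd = math.sqrt((eps / A) * (1.0 - math.exp(-2.0 * A * dt)))
    return np.asarray(x) * decay + sd * np.asarray(xi)


def sample_brownian_bridge(
    grid: TimeGrid, eps: float, x0: float, xT: float, n_paths: int, seed: int
) -> list[Path]:
    """Exact Brownian-bridge samples pinned at ``x0`` and ``xT``.

    Construction: a free Brownian path (temperature eps) plus the linear
    correction -(t/T)(W_T - (xT - x0)); endpoints are exact.  The marginal
    variance with x0 = xT = 0 is 2 eps t (1 - t/T).
    """
    if n_paths < 1:
        raise ValueError(f"n_paths must be >= 1, got {n_paths}")
    rng = np.random.default_rng(seed)
    nt = grid.n_steps
    t = grid.times()
    T = grid.duration
    dW = math.sqrt(2.0 * eps * grid.dt) * rng.standard_normal((n_paths, nt))
    W = np.concatenate([np.zeros((n_paths, 1)), np.cumsum(dW, axis=1)], axis=1)
    pos = x0 + W - (t / T)[None, :] * (W[:, -1:] - (xT - x0))
    pos[:, 0] = x0
    pos[:, -1] = xT
    bridge_tag = ProcessSpec(make_potential("zero"), eps)
    return [
        Path(
            pos[k],
            grid,
            process=bridge_tag,
            provenance={"generator": "brownian_bridge", "seed": seed, "index": k},
        )
        for k in range(n_paths)
    ]


def sample_ou_bridge(
    grid: TimeGrid,
    eps: float,
    A: float,
    x0: float,
    xT: float,
    n_paths: int,
    seed: int,
) -> list[Path]:
    """Exact Ornstein-Uhlenbeck bridge samples pinned at ``x0`` and ``xT``.

    Sequential Gaussian conditioning (Doob h-transform of the linear
    process): each step combines the exact OU kernel over dt with the
    exact OU kernel over the remaining time to the pinned endpoint, so
    the bridge marginals are unbiased on the grid.
    """
    if n_paths < 1:
        raise ValueError(f"n_paths must be >= 1, got {n_paths}")
    if A <= 0:
        raise ValueError(f"OU constant A must be positive, got {A}")
    rng = np.random.default_rng(seed)
    nt = grid.n_steps
    dt = grid.dt

    def var(s: float) -> float:
        return (eps / A) * (1.0 - math.exp(-2.0 * A * s))

    pos = np.empty((n_paths, nt + 1))
    pos[:, 0] = x0
    x = np.full(n_paths, float(x0))
    v1 = var(dt)
    decay = math.exp(-A * dt)
    for i in range(1, nt):
        tau_rest = (nt - i) * dt  # time remaining after this step
        d_rest = math.exp(-A * tau_rest)
        v_rest = var(tau_rest)
        # posterior of x_i given x_{i-1} and x_T under the OU law
        prec = 1.0 / v1 + d_rest**2 / v_rest
        v_post = 1.0 / prec
        mean = v_post * (x * decay / v1 + xT * d_rest / v_rest)
        x = mean + math.sqrt(v_post) * rng.standard_normal(n_paths)
        pos[:, i] = x
    pos[:, -1] = xT
    bridge_tag = ProcessSpec(make_potential("harmonic", A=A), eps)
    return [
        Path(
            pos[k],
            grid,
            process=bridge_tag,
            provenance={"generator": "ou_bridge", "seed": seed, "index": k},
        )
        for k in range(n_paths)
    ]


def positions_matrix(paths: Sequence[Path]) -> np.ndarray:
    """Stack an ensemble of paths into an (n_paths, Nt+1) matrix."""
    if len(paths) == 0:
        raise ValueError("empty path ensemble")
    grid = paths[0].grid
    for p in paths:
        if p.grid != grid:
            raise ValueError("paths live on different time grids")
    return np.stack([p.positions for p in paths])
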