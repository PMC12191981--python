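"""One-dimensional external potentials for overdamped Langevin dynamics.

Each potential is a triple of vectorized callables ``(energy, force,
curvature)`` with ``force = -dU/dx`` and ``curvature = d2U/dx2``.  The
built-in family covers the standard analytically tractable cases (free
diffusion, constant drift, Ornstein-Uhlenbeck) plus an asymmetric double
well used for residence-time free-energy estimation.

Energies are measured in units of the temperature parameter epsilon of the
process that uses them; potentials must be smooth and bounded below
(Kato-class regularity) for the path-measure identities to hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "Potential",
    "ConsistencyReport",
    "make_potential",
    "potential_from_spec",
    "check_consistency",
    "BUILTIN_POTENTIALS",
]

ArrayFn = Callable[[np.ndarray], np.ndarray]

# blend width of the double-well asymmetry switch, as a fraction of the
# well position a; small enough that the wells are pure quartics
_DW_BLEND_FRACTION = 0.2

FORCE_TOL = 1e-6
CURVATURE_TOL = 1e-4


@dataclass(frozen=True)
class Potential:
    """An external potential U(x) with its force and curvature.

    Attributes
    ----------
    name : str
        Identifier of the functional family (``zero``, ``linear``,
        ``harmonic``, ``double_well``).
    params : dict
        Parameter name -> value mapping that fully specifies the potential.
    energy, force, curvature : callable
        Vectorized maps position -> U(x), -U'(x), U''(x).
    """

    name: str
    params: Mapping[str, float]
    energy: ArrayFn = field(repr=False)
    force: ArrayFn = field(repr=False)
    curvature: ArrayFn = field(repr=False)

    def spec(self) -> dict:
        """Serializable ``{"name": ..., "params": {...}}`` record."""
        return {"name": self.name, "params": dict(self.params)}


@dataclass(frozen=True)
class ConsistencyReport:
    """Maximum finite-difference deviation of force and curvature."""

    max_force_error: float
    max_curvature_error: float
    force_tol: float = FORCE_TOL
    curvature_tol: float = CURVATURE_TOL

    @property
    def passed(self) -> bool:
        return (
            self.max_force_error < self.force_tol
            and self.max_curvature_error < self.curvature_tol
        )


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def _check_params(params: Mapping[str, float], required: tuple[str, ...], name: str) -> dict:
    missing = set(required) - set(params)
    extra = set(params) - set(required)
    _require(not missing, f"potential '{name}' missing parameters: {sorted(missing)}")
    _require(not extra, f"potential '{name}' got unknown parameters: {sorted(extra)}")
    out = {k: float(params[k]) for k in required}
    for k, v in out.items():
        _require(math.isfinite(v), f"potential '{name}': parameter {k}={v} is not finite")
    return out


def _zero(params: Mapping[str, float]) -> Potential:
    p = _check_params(params, (), "zero")
    return Potential(
        "zero",
        p,
        energy=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        force=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        curvature=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
    )


def _linear(params: Mapping[str, float]) -> Potential:
    # U(x) = -c x, so the force is the constant drift c
    p = _check_params(params, ("c",), "linear")
    c = p["c"]
    return Potential(
        "linear",
        p,
        energy=lambda x: -c * np.asarray(x, dtype=float),
        force=lambda x: np.full_like(np.asarray(x, dtype=float), c),
        curvature=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
    )


def _harmonic(params: Mapping[str, float]) -> Potential:
    # U(x) = A x^2 / 2: the Ornstein-Uhlenbeck restoring potential
    p = _check_params(params, ("A",), "harmonic")
    A = p["A"]
    _require(A > 0, f"harmonic potential requires A > 0, got A={A}")
    return Potential(
        "harmonic",
        p,
        energy=lambda x: 0.5 * A * np.asarray(x, dtype=float) ** 2,
        force=lambda x: -A * np.asarray(x, dtype=float),
        curvature=lambda x: np.full_like(np.asarray(x, dtype=float), A),
    )


def _double_well(params: Mapping[str, float]) -> Potential:
    """Asymmetric quartic double well, smooth everywhere.

    U(x) = h (1 - x^2 m(x))^2 with m(x) interpolating smoothly between
    1/a^2 (left well at -a) and 1/(a w)^2 (right well near +a w), so the
    right well is w times broader.  The tanh blend keeps U in C-infinity,
    the barrier top sits at x = 0 with U(0) = h, and both minima are at
    U = 0.
    """
    p = _check_params(params, ("h", "a", "w"), "double_well")
    h, a, w = p["h"], p["a"], p["w"]
    _require(h > 0, f"double_well requires barrier height h > 0, got {h}")
    _require(a > 0, f"double_well requires well position a > 0, got {a}")
    _require(w > 0, f"double_well requires width factor w > 0, got {w}")
    lam = _DW_BLEND_FRACTION * a
    mL = 1.0 / a**2
    mR = 1.0 / (a * w) ** 2

    def _m(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s = np.tanh(x / lam)
        m = 0.5 * (1.0 - s) * mL + 0.5 * (1.0 + s) * mR
        dm = 0.5 * (mR - mL) * (1.0 - s**2) / lam
        d2m = -(mR - mL) * s * (1.0 - s**2) / lam**2
        return m, dm, d2m

    def energy(x):
        x = np.asarray(x, dtype=float)
        m, _, _ = _m(x)
        return h * (1.0 - x**2 * m) ** 2

    def force(x):
        x = np.asarray(x, dtype=float)
        m, dm, _ = _m(x)
        q = x**2 * m
        dq = 2.0 * x * m + x**2 * dm
        return 2.0 * h * (1.0 - q) * dq

    def curvature(x):
        x = np.asarray(x, dtype=float)
        m, dm, d2m = _m(x)
        q = x**2 * m
        dq = 2.0 * x * m + x**2 * dm
        d2q = 2.0 * m + 4.0 * x * dm + x**2 * d2m
        return 2.0 * h * (dq**2 - (1.0 - q) * d2q)

    return Potential("double_well", p, energy=energy, force=force, curvature=curvature)


BUILTIN_POTENTIALS: dict[str, Callable[[Mapping[str, float]], Potential]] = {
    "zero": _zero,
    "linear": _linear,
    "harmonic": _harmonic,
    "double_well": _double_well,
}


def make_potential(name: str, **params: float) -> Potential:
    """Construct a built-in potential by name.

    Parameters
    ----------
    name : str
        One of ``zero``, ``linear(c)``, ``harmonic(A)``,
        ``double_well(h, a, w)``.
    **params
        The family's parameters; all required, all finite.

    Returns
    -------
    Potential

    Raises
    ------
    ValueError
        Unknown name, missing/extra parameters, or out-of-range values.
    """
    try:
        factory = BUILTIN_POTENTIALS[name]
    except KeyError:
        raise ValueError(
            f"unknown potential '{name}'; available: {sorted(BUILTIN_POTENTIALS)}"
        ) from None
    return factory(params)


def potential_from_spec(spec: Mapping) -> Potential:
    """Build a potential from a ``{"name": ..., "params": {...}}`` record."""
    if "name" not in spec:
        raise ValueError("potential spec must carry a 'name' field")
    return make_potential(spec["name"], **dict(spec.get("params", {})))


def check_consistency(
    potential: Potential,
    grid,
    h_force: float = 1e-5,
    h_curv: float = 1e-4,
) -> ConsistencyReport:
    """Compare analytic force/curvature with central finite differences.

    The error is the absolute deviation divided by ``max(1, |reference|)``
    (relative with a unit floor, so near-zero values are compared
    absolutely).  The curvature stencil uses a wider step than the force
    stencil because the second difference loses more bits to cancellation.
    """
    x = np.asarray(grid, dtype=float)
    if x.size == 0:
        raise ValueError("probe grid must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("probe grid contains non-finite positions")

    f_fd = -(potential.energy(x + h_force) - potential.energy(x - h_force)) / (2 * h_force)
    f_an = potential.force(x)
    force_err = np.abs(f_an - f_fd) / np.maximum(1.0, np.abs(f_fd))

    c_fd = (
        potential.energy(x + h_curv)
        - 2.0 * potential.energy(x)
        + potential.energy(x - h_curv)
    ) / h_curv**2
    c_an = potential.curvature(x)
    curv_err = np.abs(c_an - c_fd) / np.maximum(1.0, np.abs(c_fd))

    return ConsistencyReport(float(force_err.max()), float(curv_err.max()))
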