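"""Torque balance between hydrodynamic drag and a basal torsional spring.

A cilium (rod) whose beating direction initially points perpendicular to an
imposed shear flow (rest angle ``theta = pi/2``) experiences an aligning
hydrodynamic torque ``T(theta)`` and a restoring elastic torque from the
anchoring actin mesh, modelled as a linear torsional spring::

    T_el(theta) = k * (pi/2 - theta)

with non-dimensional stiffness ``k`` in the same units as the hydrodynamic
torque (multiples of ``eta * gammadot * L^3``).  The equilibrium beating
angle ``theta*`` solves ``T(theta*) = T_el(theta*)`` and the resulting
alignment with the flow is ``Phi = cos(theta*)``: ``k = 0`` gives full
alignment (``Phi = 1``), a rigid anchor leaves the cilium at rest
(``Phi = 0``).

Combining the equilibrium solve with a hydrodynamic screening table
``T(theta, rho)`` yields the alignment surface ``Phi(rho, k)``: at any given
stiffness, denser cilia carpets are more strongly screened and align less.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .sbt import ScreeningTable

__all__ = [
    "SpringModel",
    "EquilibriumResult",
    "elastic_torque",
    "equilibrium_angle",
    "phi_surface",
]


@dataclass(frozen=True)
class SpringModel:
    """Linear torsional spring at the cilium base.

    ``stiffness`` is non-dimensional (units of eta*gammadot*L^3 per radian);
    ``rest_angle`` is the unforced beating angle, pi/2 (beating initially
    perpendicular to the flow).
    """

    stiffness: float
    rest_angle: float = np.pi / 2

    def __post_init__(self) -> None:
        if self.stiffness < 0:
            raise ValueError("spring stiffness must be >= 0")


@dataclass(frozen=True)
class EquilibriumResult:
    """Solution of the torque balance at one (hydro curve, stiffness) pair."""

    theta_star: float
    phi: float
    converged: bool
    residual: float


def elastic_torque(theta: float | np.ndarray, spring: SpringModel) -> float | np.ndarray:
    """Restoring torque ``k (rest_angle - theta)`` of the basal spring.

    Zero at the rest angle, maximal when the cilium is fully rotated into
    the flow (theta = 0).
    """
    th = np.asarray(theta, dtype=float)
    # tolerate grid endpoints rounded just past pi/2 (e.g. 1.5708)
    if np.any(th < -1e-6) or np.any(th > np.pi / 2 + 1e-4):
        raise ValueError("theta must lie in [0, pi/2]")
    out = spring.stiffness * (spring.rest_angle - th)
    return float(out) if np.isscalar(theta) else out


def _hydro_interpolant(theta_samples, torque_samples):
    th = np.asarray(theta_samples, dtype=float)
    tq = np.asarray(torque_samples, dtype=float)
    if th.ndim != 1 or th.size < 2 or tq.shape != th.shape:
        raise ValueError("need matched 1-D theta and torque samples")
    if not np.all(np.diff(th) > 0):
        raise ValueError("theta samples must be strictly increasing")
    if th[0] > 1e-9 or abs(tq[0]) > 1e-6:
        raise ValueError("hydro curve must be sampled from theta = 0 with T(0) = 0")
    if np.any(tq < -1e-9):
        raise ValueError("hydrodynamic torque samples must be non-negative")
    # monotone piecewise cubic: no overshoot, hence no spurious crossings
    return PchipInterpolator(th, np.clip(tq, 0.0, None))


def equilibrium_angle(
    theta_samples: np.ndarray,
    torque_samples: np.ndarray,
    spring: SpringModel,
    *,
    xtol: float = 1e-12,
) -> EquilibriumResult:
    """Equilibrium beating angle from a sampled hydrodynamic torque curve.

    The root of ``g(theta) = T_hydro(theta) - k (pi/2 - theta)`` is bracketed
    on a fine grid of the monotone interpolant and polished with Brent's
    method.  ``k = 0`` aligns fully (``theta* = 0``); a spring stiff enough
    that the elastic torque exceeds the hydrodynamic torque everywhere pins
    the cilium at its rest angle (boundary solution, flagged unconverged).
    If several crossings exist the smallest (most aligned) root is returned
    with a warning.
    """
    if spring.stiffness == 0.0:
        return EquilibriumResult(theta_star=0.0, phi=1.0, converged=True, residual=0.0)
    hydro = _hydro_interpolant(theta_samples, torque_samples)
    th_max = float(np.asarray(theta_samples)[-1])

    def g(th):
        return hydro(th) - elastic_torque(th, spring)

    grid = np.linspace(0.0, th_max, 2048)
    vals = g(grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    # g(0) = -k*pi/2 < 0; a crossing to >= 0 is the balance point
    if sign_change.size == 0:
        # elastic torque dominates everywhere: rest-angle boundary solution
        return EquilibriumResult(
            theta_star=th_max,
            phi=float(np.cos(th_max)),
            converged=False,
            residual=float(abs(g(th_max))),
        )
    if sign_change.size > 1:
        warnings.warn(
            f"torque balance has {sign_change.size} crossings; returning the "
            "smallest theta root (hydro curve may be non-monotone)",
            RuntimeWarning,
            stacklevel=2,
        )
    i = sign_change[0]
    root = brentq(g, grid[i], grid[i + 1], xtol=xtol)
    return EquilibriumResult(
        theta_star=float(root),
        phi=float(np.cos(root)),
        converged=True,
        residual=float(abs(g(root))),
    )


def phi_surface(
    screening: ScreeningTable,
    k_grid: np.ndarray | list,
    *,
    denormalize: bool = True,
) -> pd.DataFrame:
    """Alignment surface ``Phi(rho, k)`` from a screening table.

    For every density the hydrodynamic torque curve ``T(theta, rho)`` is
    balanced against springs of each stiffness.  ``denormalize`` rescales the
    normalized table by its isolated-rod reference so that stiffness is
    expressed in physical ``eta*gammadot*L^3`` units; with ``False`` the
    stiffness is in units of ``T_0(pi/2)`` instead.

    Returns a tidy frame with columns ``rho``, ``k``, ``theta_star``,
    ``phi``, ``converged``.
    """
    k_grid = np.asarray(k_grid, dtype=float)
    scale = screening.t0 if denormalize else 1.0
    rows = []
    for j, rho in enumerate(screening.rho_grid):
        torque = screening.normalized_torque[:, j] * scale
        for k in k_grid:
            eq = equilibrium_angle(screening.theta_grid, torque, SpringModel(k))
            rows.append(
                {
                    "rho": float(rho),
                    "k": float(k),
                    "theta_star": eq.theta_star,
                    "phi": eq.phi,
                    "converged": eq.converged,
                }
            )
    return pd.DataFrame(rows)
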