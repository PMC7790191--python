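"""Culture-level statistics: alignment, density, shear stress, dose response.

Given per-cell records from the movie pipeline, this module computes the
quantities a flow-treatment experiment reports:

* the alignment parameter ``Phi = (1/N) sum_i p_i . e`` — the mean projection
  of per-cell beating directions ``p_i`` onto the applied-flow direction
  ``e`` (1 = fully aligned, 0 = random);
* the net cilia-driven flow ``V = (1/N) sum_i v_i . e`` in µm/s;
* ciliated-cell density ``rho_cell = N_box / (N_tot A_box)`` and ciliated
  area fraction ``rho = N_box / N_tot``;
* the shear-stress profile ``tau(x) = 6 eta Q / (h^2 w(x))`` of a tapered
  Hele-Shaw channel (hyperbolic in x, so one chip spans a range of stresses);
* the saturating dose-response fit ``Phi = 1 - exp(-tau / tau_c)`` whose
  critical stress ``tau_c`` characterises how much shear a culture needs
  before its cilia re-orient (``Phi(tau_c) = 1 - 1/e ~ 0.63``).

Stresses are in dyne/cm^2 (1 Pa = 10 dyne/cm^2), the unit this literature
uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .pipeline import CellRecord

__all__ = [
    "AlignmentResult",
    "DensityResult",
    "ChannelGeometry",
    "DoseResponseFit",
    "alignment_parameter",
    "density_metrics",
    "shear_profile",
    "wall_shear_from_flow",
    "fit_dose_response",
    "segment_mean_shear",
    "DEFAULT_VISCOSITY_PA_S",
]

#: Dynamic viscosity of culture medium at 37 C, Pa*s.
DEFAULT_VISCOSITY_PA_S = 0.8e-3

PA_TO_DYNE_CM2 = 10.0


@dataclass(frozen=True)
class AlignmentResult:
    """Alignment parameter and net flow of one group of cell records."""

    phi: float
    n_boxes: int
    net_flow: float  # µm/s, projection of mean flow on the flow axis
    stderr: float | None = None  # across-FOV standard error when grouped
    per_fov_phi: np.ndarray | None = None
    n_excluded: int = 0


@dataclass(frozen=True)
class DensityResult:
    """Ciliated-cell density and ciliated area fraction."""

    rho_cell: float  # cells / mm^2
    rho: float  # area fraction
    n_box: int
    n_tot: int
    a_box_um2: float


@dataclass(frozen=True)
class ChannelGeometry:
    """Tapered Hele-Shaw channel: w(x) = w0 + slope * x, height h.

    Lengths in mm, flow rate Q in mm^3/s, viscosity in Pa*s.  The default
    taper (1 mm entrance widening to 5 mm over 7 mm) spans a five-fold range
    of shear stress along one chip.
    """

    w0: float = 1.0
    slope: float = 4.0 / 7.0
    h: float = 1.0
    length: float = 7.0
    q: float = 1.0
    eta: float = DEFAULT_VISCOSITY_PA_S

    def __post_init__(self) -> None:
        if min(self.w0, self.h, self.length, self.eta) <= 0 or self.slope < 0:
            raise ValueError("channel dimensions and viscosity must be positive")

    @classmethod
    def from_taper_angle(cls, half_angle_deg: float = 15.0, **kwargs) -> "ChannelGeometry":
        """Build from the taper half-angle (each side wall flares by it)."""
        return cls(slope=2.0 * np.tan(np.radians(half_angle_deg)), **kwargs)

    def width(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.w0 + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted critical shear stress of Phi = 1 - exp(-tau / tau_c)."""

    tau_c: float
    ci_low: float
    ci_high: float
    residuals: np.ndarray
    tau: np.ndarray
    phi: np.ndarray
    phi_at_tau_c: float = field(default=1.0 - np.exp(-1.0))

    def predict(self, tau: np.ndarray | float) -> np.ndarray | float:
        return 1.0 - np.exp(-np.asarray(tau, dtype=float) / self.tau_c)


# ---------------------------------------------------------------------------
# alignment and density
# ---------------------------------------------------------------------------

def _directions_velocities(records: list[CellRecord]):
    p = np.array([r.direction for r in records], dtype=float)
    v = np.array([[r.vx_um_s, r.vy_um_s] for r in records], dtype=float)
    return p, v


def alignment_parameter(
    records: list[CellRecord],
    flow_direction: np.ndarray | tuple = (1.0, 0.0),
    *,
    fov_ids: np.ndarray | list | None = None,
    method: str = "mean_projection",
) -> AlignmentResult:
    """Alignment parameter Phi and net flow for a set of cell records.

    Phi is the mean projection of the unit beating directions on the
    (previously applied) flow direction; the net flow is the mean projection
    of the PIV velocity vectors, in µm/s.  Boxes with zero or undefined
    velocity are excluded and counted.  With ``fov_ids`` the quantities are
    computed per field of view and the across-FOV standard error reported.

    ``method="vector_mean"`` instead reports the magnitude of the mean unit
    vector (direction-coherence without a reference axis).
    """
    if method not in ("mean_projection", "vector_mean"):
        raise ValueError("method must be 'mean_projection' or 'vector_mean'")
    e = np.asarray(flow_direction, dtype=float)
    e = e / np.linalg.norm(e)
    if len(records) == 0:
        raise ValueError("need at least one cell record")
    p, v = _directions_velocities(records)
    ok = np.isfinite(p).all(axis=1) & (np.hypot(v[:, 0], v[:, 1]) > 0)
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("no records with a defined beating direction")
    p, v = p[ok], v[ok]

    if method == "vector_mean":
        phi_all = float(np.linalg.norm(p.mean(axis=0)))
    else:
        phi_all = float(np.mean(p @ e))
    net = float(np.mean(v @ e))

    stderr = None
    per_fov = None
    if fov_ids is not None:
        ids = np.asarray(fov_ids)[ok]
        uniq = np.unique(ids)
        per_fov = np.array(
            [
                np.linalg.norm(p[ids == u].mean(axis=0))
                if method == "vector_mean"
                else np.mean(p[ids == u] @ e)
                for u in uniq
            ]
        )
        phi_all = float(per_fov.mean())
        if uniq.size > 1:
            stderr = float(per_fov.std(ddof=1) / np.sqrt(uniq.size))
    return AlignmentResult(
        phi=phi_all,
        n_boxes=int(ok.sum()),
        net_flow=net,
        stderr=stderr,
        per_fov_phi=per_fov,
        n_excluded=n_excluded,
    )


def density_metrics(
    n_box: int, n_tot: int, a_box_um2: float = 7.6 * 7.6
) -> DensityResult:
    """Ciliated-cell density (cells/mm^2) and ciliated area fraction.

    ``rho_cell = N_box / (N_tot * A_box)`` with the box area converted from
    µm^2 to mm^2; ``rho = N_box / N_tot``.
    """
    if n_tot <= 0:
        raise ValueError("total box count must be positive")
    if not (0 <= n_box <= n_tot):
        raise ValueError("need 0 <= n_box <= n_tot")
    rho = n_box / n_tot
    rho_cell = rho / (a_box_um2 * 1e-6)  # boxes/µm^2 -> cells/mm^2
    return DensityResult(
        rho_cell=rho_cell, rho=rho, n_box=n_box, n_tot=n_tot, a_box_um2=a_box_um2
    )


# ---------------------------------------------------------------------------
# shear stress
# ---------------------------------------------------------------------------

def shear_profile(geom: ChannelGeometry, x: float | np.ndarray) -> float | np.ndarray:
    """Wall shear stress tau(x) = 6 eta Q / (h^2 w(x)), dyne/cm^2.

    Hele-Shaw plane-Poiseuille result at the channel floor; hyperbolic decay
    along the taper.  ``x`` in mm within [0, length].
    """
    xv = np.asarray(x, dtype=float)
    if np.any(xv < -1e-12) or np.any(xv > geom.length + 1e-12):
        raise ValueError(f"x must lie within the channel [0, {geom.length}] mm")
    # eta [Pa s] * Q [mm^3/s] / (h^2 w) [mm^3] = Pa
    tau_pa = 6.0 * geom.eta * geom.q / (geom.h**2 * geom.width(xv))
    out = tau_pa * PA_TO_DYNE_CM2
    return float(out) if np.isscalar(x) else out


def segment_mean_shear(
    geom: ChannelGeometry, x_lo: float, x_hi: float, n: int = 256
) -> float:
    """Mean of tau(x) over a channel segment (dyne/cm^2)."""
    if not (0 <= x_lo < x_hi <= geom.length):
        raise ValueError("segment must lie within the channel")
    x = np.linspace(x_lo, x_hi, n)
    return float(np.trapezoid(shear_profile(geom, x), x) / (x_hi - x_lo))


def wall_shear_from_flow(
    v_um_s: float, h_um: float, eta_pa_s: float = DEFAULT_VISCOSITY_PA_S
) -> float:
    """Shear-stress scale eta * V / h of a near-wall flow, dyne/cm^2.

    The canonical worked example: a cilia-driven flow of 50 µm/s measured
    20 µm above the wall in medium of 0.8 mPa*s gives 0.02 dyne/cm^2.
    """
    if h_um <= 0 or eta_pa_s <= 0 or v_um_s < 0:
        raise ValueError("inputs must be positive (V may be zero)")
    tau_pa = eta_pa_s * (v_um_s / h_um)  # µm/s / µm = 1/s
    return tau_pa * PA_TO_DYNE_CM2


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------

def _model(tau, tau_c):
    return 1.0 - np.exp(-tau / tau_c)


def fit_dose_response(
    tau: np.ndarray | list,
    phi: np.ndarray | list,
    *,
    n_boot: int = 500,
    seed: int | None = None,
    ci_level: float = 0.68,
) -> DoseResponseFit:
    """Fit Phi = 1 - exp(-tau/tau_c) and bootstrap a confidence interval.

    Nonlinear least squares for the single parameter ``tau_c``; the CI is a
    percentile bootstrap over resampled (tau, Phi) pairs.  Phi values above
    1 are clipped with a warning (they can arise from PIV noise); at the
    fitted ``tau_c`` the curve passes through 1 - 1/e ~ 0.632.
    """
    tau = np.asarray(tau, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if tau.shape != phi.shape or tau.ndim != 1:
        raise ValueError("tau and phi must be matched 1-D arrays")
    if tau.size < 3:
        raise ValueError("need at least 3 (tau, phi) pairs")
    if np.any(tau <= 0):
        raise ValueError("shear stresses must be positive")
    if np.any(phi > 1.0):
        warnings.warn("Phi values above 1 clipped to 1")
        phi = np.clip(phi, None, 1.0)

    def _fit(t, p):
        popt, _ = curve_fit(
            _model, t, p, p0=[np.median(t)], bounds=(1e-12, np.inf), maxfev=2000
        )
        return float(popt[0])

    try:
        tau_c = _fit(tau, phi)
    except RuntimeError as exc:
        raise RuntimeError(
            f"dose-response fit did not converge on n={tau.size} points: {exc}"
        ) from exc

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, tau.size, size=tau.size)
        try:
            boot[b] = _fit(tau[idx], phi[idx])
        except RuntimeError:
            boot[b] = np.nan
    boot = boot[np.isfinite(boot)]
    if boot.size:
        lo, hi = np.percentile(boot, [50 * (1 - ci_level), 50 * (1 + ci_level)])
    else:  # pragma: no cover - all resamples failing is pathological
        lo = hi = np.nan
    resid = phi - _model(tau, tau_c)
    return DoseResponseFit(
        tau_c=tau_c, ci_low=float(lo), ci_high=float(hi),
        residuals=resid, tau=tau, phi=phi,
    )


def condition_summary(
    frames: dict[object, pd.DataFrame],
    flow_direction: np.ndarray | tuple = (1.0, 0.0),
) -> pd.DataFrame:
    """Per-condition Phi summary from per-FOV cell-record tables.

    ``frames`` maps condition keys (e.g. applied tau) to concatenated
    record DataFrames carrying a ``fov`` column.  Returns one row per
    condition: ``tau, phi_mean, phi_sem, n_fov, n_cells``.
    """
    e = np.asarray(flow_direction, dtype=float)
    e = e / np.linalg.norm(e)
    rows = []
    for key, df in frames.items():
        per_fov = df.groupby("fov").apply(
            lambda g: np.mean(g[["px", "py"]].to_numpy() @ e),
            include_groups=False,
        )
        rows.append(
            {
                "tau": key,
                "phi_mean": float(per_fov.mean()),
                "phi_sem": float(per_fov.std(ddof=1) / np.sqrt(len(per_fov)))
                if len(per_fov) > 1
                else np.nan,
                "n_fov": int(len(per_fov)),
                "n_cells": int(len(df)),
            }
        )
    return pd.DataFrame(rows)
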