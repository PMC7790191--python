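"""Planar cilia beat waveforms and their coarse-grained geometry.

A beat pattern is stored as the tangent-angle profile ``psi(s, t)`` of the
cilium centerline: ``s`` is arclength along the cilium in units of its length
``L`` and ``t`` is the phase within one beat period.  The angle is measured
from the in-plane beating direction (the power-stroke direction, ``e-hat``)
toward the surface normal, so ``psi = 0`` is a cilium lying flat along the
beating direction and ``psi = pi/2`` is a cilium standing upright.

From this representation the module derives the three coarse-graining
quantities used by the rod-array hydrodynamics:

* the mean-tangent tilt angle ``alpha`` (the elevation of the time- and
  arclength-averaged unit tangent),
* the elevation of the base-to-tip chord at the two stroke extremes
  (how far the cilium leans forward in the power stroke and backward in the
  recovery stroke), and
* the top-view area spanned by one beating cilium, used as the per-cilium
  footprint when converting lattice spacings into ciliated area fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BeatPattern",
    "WaveformSummary",
    "reconstruct_centerline",
    "mean_tangent_angle",
    "swept_summary",
    "DEFAULT_FOOTPRINT_WIDTH",
]

#: Lateral footprint of one cilium, in units of L: one body width (the
#: diameter of an r = 0.02 L filament) — the strip the cilium body itself
#: sweeps in top view.  Overridable in :func:`swept_summary`.
DEFAULT_FOOTPRINT_WIDTH = 0.04


@dataclass(frozen=True)
class BeatPattern:
    """Tangent-angle profile ``psi(s, t)`` of a planar beat on an (s, t) grid.

    Parameters
    ----------
    s_grid : array of float
        Arclength fractions in [0, 1], strictly increasing, starting at 0.
    t_grid : array of float
        Phase samples in [0, 1), strictly increasing.
    psi : array of float, shape (len(s_grid), len(t_grid))
        Tangent angle in radians, in (-pi, pi].
    """

    s_grid: np.ndarray
    t_grid: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s_grid, dtype=float)
        t = np.asarray(self.t_grid, dtype=float)
        psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if s.ndim != 1 or s.size == 0:
            raise ValueError("s_grid must be a non-empty 1-D array")
        if t.ndim != 1 or t.size == 0:
            raise ValueError("t_grid must be a non-empty 1-D array")
        if s[0] != 0.0:
            raise ValueError("s_grid must start at 0")
        if s.size > 1 and not np.all(np.diff(s) > 0):
            raise ValueError("s_grid must be strictly increasing")
        if s[-1] > 1.0 + 1e-12:
            raise ValueError("s_grid must lie in [0, 1]")
        if np.any(t < 0.0) or np.any(t >= 1.0):
            raise ValueError("t_grid must lie in [0, 1)")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("t_grid must be strictly increasing")
        if psi.shape != (s.size, t.size):
            raise ValueError(
                f"psi shape {psi.shape} does not match grids ({s.size}, {t.size})"
            )
        if np.any(psi <= -np.pi) or np.any(psi > np.pi):
            raise ValueError("psi must lie in (-pi, pi]")
        object.__setattr__(self, "s_grid", s)
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "psi", psi)
        # The centerline must never dip below the surface the cilium grows from.
        z = _cumulative_coordinate(s, np.sin(psi))
        if np.min(z) < -1e-9:
            raise ValueError("centerline penetrates the surface (z < 0)")

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``s``, ``t``, ``psi_rad``."""
        ss, tt = np.meshgrid(self.s_grid, self.t_grid, indexing="ij")
        return pd.DataFrame(
            {"s": ss.ravel(), "t": tt.ravel(), "psi_rad": self.psi.ravel()}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BeatPattern":
        df = pd.read_csv(path)
        s = np.unique(df["s"].to_numpy())
        t = np.unique(df["t"].to_numpy())
        psi = (
            df.pivot(index="s", columns="t", values="psi_rad")
            .sort_index()
            .to_numpy()
        )
        return cls(s, t, psi)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "s_grid": self.s_grid.tolist(),
            "t_grid": self.t_grid.tolist(),
            "psi": self.psi.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "BeatPattern":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["s_grid"]),
            np.asarray(payload["t_grid"]),
            np.asarray(payload["psi"]),
        )


@dataclass(frozen=True)
class WaveformSummary:
    """Coarse-grained geometry of one beat pattern.

    alpha_tilt : mean-tangent elevation from the beating direction, degrees.
    forward_angle, backward_angle : chord elevation at the power- and
        recovery-stroke extremes, degrees.
    a_top : top-view spanned area in units of L^2.
    """

    alpha_tilt: float
    forward_angle: float
    backward_angle: float
    a_top: float


def _cumulative_coordinate(s: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of one tangent component over the s grid."""
    from scipy.integrate import cumulative_trapezoid

    if s.size == 1:
        return np.zeros_like(np.atleast_2d(comp))
    return cumulative_trapezoid(comp, s, axis=0, initial=0.0)


def _interp_phase(beat: BeatPattern, phase: float) -> np.ndarray:
    """psi(s) at an arbitrary phase, periodic linear interpolation in t."""
    t = beat.t_grid
    if t.size == 1:
        return beat.psi[:, 0]
    # wrap phase into [t0, t0 + 1) and interpolate on the periodic extension
    tp = np.concatenate([t, [t[0] + 1.0]])
    psip = np.concatenate([beat.psi, beat.psi[:, :1]], axis=1)
    ph = t[0] + (phase - t[0]) % 1.0
    idx = np.searchsorted(tp, ph, side="right") - 1
    idx = min(idx, t.size - 1)
    w = (ph - tp[idx]) / (tp[idx + 1] - tp[idx])
    return (1 - w) * psip[:, idx] + w * psip[:, idx + 1]


def reconstruct_centerline(beat: BeatPattern, phase: float) -> np.ndarray:
    """Centerline points (y_along_e, z) at one phase of the beat.

    The centerline is recovered by cumulative quadrature of the unit tangent
    ``(cos psi, sin psi)`` along arclength; the base (s = 0) maps to the
    origin and the total contour length equals 1 by construction.

    Parameters
    ----------
    beat : BeatPattern
    phase : float
        Phase in [0, 1); interpolated periodically between t samples.

    Returns
    -------
    ndarray, shape (len(s_grid), 2)
    """
    if not (0.0 <= phase < 1.0):
        raise ValueError(f"phase must lie in [0, 1), got {phase}")
    psi = _interp_phase(beat, phase)[:, None]
    y = _cumulative_coordinate(beat.s_grid, np.cos(psi))[:, 0]
    z = _cumulative_coordinate(beat.s_grid, np.sin(psi))[:, 0]
    return np.column_stack([y, z])


def mean_tangent_angle(beat: BeatPattern, *, average: str = "vector") -> float:
    """Elevation of the beat-averaged tangent, in degrees.

    The unit tangent ``(cos psi, sin psi)`` is averaged uniformly over
    arclength and phase (trapezoid in ``s``, periodic mean in ``t``) and the
    angle of the resulting mean vector from the beating direction is
    returned.  For ependymal beat patterns this is the tilt ``alpha ~ 53 deg``
    used to orient the rigid rods of the hydrodynamic model.

    ``average="angle"`` instead averages the angle itself; the default vector
    average is the one used throughout the package.
    """
    if average not in ("vector", "angle"):
        raise ValueError("average must be 'vector' or 'angle'")
    s = beat.s_grid
    if average == "angle":
        mean_s = _trapz_mean(beat.psi, s)
        return float(np.degrees(np.mean(mean_s)))
    cy = _trapz_mean(np.cos(beat.psi), s)
    cz = _trapz_mean(np.sin(beat.psi), s)
    vy, vz = np.mean(cy), np.mean(cz)
    return float(np.degrees(np.arctan2(vz, vy)))


def _trapz_mean(a: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Arclength (trapezoid) mean of a, per phase column."""
    if s.size == 1:
        return a[0]
    return np.trapezoid(a, s, axis=0) / (s[-1] - s[0])


def swept_summary(
    beat: BeatPattern, *, footprint_width: float = DEFAULT_FOOTPRINT_WIDTH
) -> WaveformSummary:
    """Stroke-extreme chord angles and the top-view spanned area.

    For every phase the base-to-tip chord is computed; the phases of maximal
    forward reach (largest tip coordinate along the beating direction) and
    maximal backward reach (most negative tip coordinate) define the two
    stroke extremes.  Their chord elevations are reported in degrees, and the
    top-view footprint is::

        a_top = (forward reach + backward reach) * footprint_width

    with the horizontal reach at each extreme taken as ``L cos(elevation)``
    (zero when the cilium never crosses the vertical on that side).
    """
    tips = np.empty((beat.t_grid.size, 2))
    psi = beat.psi
    y = _cumulative_coordinate(beat.s_grid, np.cos(psi))
    z = _cumulative_coordinate(beat.s_grid, np.sin(psi))
    tips[:, 0] = y[-1]
    tips[:, 1] = z[-1]

    i_fwd = int(np.argmax(tips[:, 0]))
    i_back = int(np.argmin(tips[:, 0]))
    fwd_tip, back_tip = tips[i_fwd], tips[i_back]

    def _elev(tip: np.ndarray) -> float:
        if np.hypot(tip[0], tip[1]) == 0.0:
            return 90.0
        return float(np.degrees(np.arctan2(tip[1], abs(tip[0]))))

    forward_angle = _elev(fwd_tip)
    backward_angle = _elev(back_tip)
    fwd_reach = np.cos(np.radians(forward_angle)) if fwd_tip[0] > 1e-12 else 0.0
    back_reach = np.cos(np.radians(backward_angle)) if back_tip[0] < -1e-12 else 0.0
    a_top = (fwd_reach + back_reach) * footprint_width
    alpha = mean_tangent_angle(beat)
    return WaveformSummary(
        alpha_tilt=abs(alpha),
        forward_angle=forward_angle,
        backward_angle=backward_angle,
        a_top=float(a_top),
    )


def min_parallel_spacing(forward_angle_deg: float, backward_angle_deg: float) -> float:
    """Minimum center spacing along the beating direction, units of L.

    The spanned footprints of successive cilia in a row must not overlap, so
    the spacing is the sum of the horizontal reaches at the two stroke
    extremes: ``L (cos(fwd) + cos(back))``.  For the ependymal extremes of
    23 and 18 degrees this is about 1.87 L.
    """
    return float(
        np.cos(np.radians(forward_angle_deg)) + np.cos(np.radians(backward_angle_deg))
    )
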