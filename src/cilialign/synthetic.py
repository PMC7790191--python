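"""Synthetic microscopy data with known ground truth.

Every input the analysis consumes can be generated here with planted
parameters, enabling closed-loop recovery tests:

* ``make_field`` lays out non-overlapping cell-shaped patches with per-cell
  beat frequencies and beating directions (von Mises around a mean axis, so
  the expected alignment parameter is the Bessel ratio ``I1(kappa)/I0(kappa)``);
* ``render_bf_movie`` turns a layout into a bright-field stack whose cell
  pixels oscillate at the planted frequency with random per-pixel phase over
  Gaussian read noise;
* ``render_tracer_movie`` advects fluorescent tracer particles through the
  per-cell flow field (Gaussian kernels oriented along each cell's beating
  direction) with optional Brownian jitter, and renders them as diffraction
  -limited spots;
* ``make_dose_dataset`` draws noisy alignment-versus-shear-stress samples
  from the saturating-exponential dose response;
* ``make_beat_pattern`` builds parametric planar beat waveforms, including
  a family whose stroke-extreme chord angles can be prescribed exactly.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ive

from .beat import BeatPattern
from .pipeline import DEFAULT_PIXEL_SIZE_UM, Movie

__all__ = [
    "SyntheticFieldSpec",
    "SyntheticTracerSpec",
    "FieldLayout",
    "make_field",
    "render_bf_movie",
    "render_tracer_movie",
    "velocity_field",
    "make_dose_dataset",
    "make_beat_pattern",
    "beat_pattern_with_extremes",
    "expected_alignment",
]


def expected_alignment(kappa: float) -> float:
    """Mean resultant length of a von Mises sample: I1(kappa)/I0(kappa).

    This is the expected alignment parameter when beating directions are
    drawn with concentration ``kappa`` around the flow axis.
    """
    if kappa < 0:
        raise ValueError("concentration must be >= 0")
    if kappa == 0:
        return 0.0
    return float(ive(1, kappa) / ive(0, kappa))


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Layout and imaging parameters of one synthetic field of view."""

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM  # µm/px
    n_cells: int = 150
    cell_radius_px: tuple[float, float] = (8.0, 14.0)
    cbf_mean_hz: float = 25.0
    cbf_sd_hz: float = 3.0
    direction_mean_deg: float = 0.0  # mean beating direction (0 = +x)
    kappa: float = 4.0  # von Mises concentration; 0 = uniform
    baseline: float = 1000.0
    amplitude: float = 150.0
    noise_sd: float = 40.0
    frame_rate: float = 160.0
    n_frames: int = 800
    max_overlap_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.kappa < 0 or self.noise_sd < 0:
            raise ValueError("spec parameters out of range")
        if self.cbf_mean_hz >= self.frame_rate / 2:
            raise ValueError("planted CBF must be below Nyquist")


@dataclass(frozen=True)
class SyntheticTracerSpec:
    """Tracer-movie parameters (slow fluorescent acquisition)."""

    n_particles: int = 2500
    particle_diameter_um: float = 1.0
    flow_kernel_px: float = 8.0  # Gaussian width of each cell's flow patch
    speed_um_s: float = 10.0
    frame_rate: float = 10.0
    n_frames: int = 100
    brownian_sd_um: float = 0.05  # per-frame jitter
    baseline: float = 100.0
    peak_intensity: float = 3000.0
    noise_sd: float = 10.0
    seed: int = 0


@dataclass(frozen=True)
class FieldLayout:
    """Ground truth of a synthetic field: geometry plus planted parameters."""

    spec: SyntheticFieldSpec
    centers: np.ndarray       # (n, 2) row, col
    radii: np.ndarray         # (n,)
    cbf_hz: np.ndarray        # (n,)
    direction_rad: np.ndarray  # (n,) planted beating direction angle
    labels: np.ndarray        # (rows, cols) ground-truth cell ids, 0 = bg
    mean_direction: np.ndarray = field(default=None)

    @property
    def n_cells(self) -> int:
        return len(self.radii)


def make_field(spec: SyntheticFieldSpec, max_tries: int = 20000) -> FieldLayout:
    """Sample a reproducible field layout with non-overlapping cells.

    Directions are von Mises around the mean beating direction with
    concentration ``kappa``; frequencies are Gaussian, clipped inside the
    detection band.
    """
    rng = np.random.default_rng(spec.seed)
    nr, nc = spec.shape
    lo, hi = spec.cell_radius_px
    centers, radii = [], []
    tries = 0
    while len(centers) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not pack {spec.n_cells} cells after {max_tries} tries"
            )
        r = rng.uniform(lo, hi)
        c = rng.uniform([r, r], [nr - r, nc - r])
        if centers:
            d = np.linalg.norm(np.asarray(centers) - c, axis=1)
            min_d = (np.asarray(radii) + r) * (1.0 - spec.max_overlap_frac)
            if np.any(d < min_d):
                continue
        centers.append(c)
        radii.append(r)
    centers = np.asarray(centers).reshape(-1, 2)
    radii = np.asarray(radii)

    cbf = rng.normal(spec.cbf_mean_hz, spec.cbf_sd_hz, size=spec.n_cells)
    cbf = np.clip(cbf, 1.5, spec.frame_rate / 2 - 2.0)
    mu = np.radians(spec.direction_mean_deg)
    if spec.kappa == 0:
        ang = rng.uniform(-np.pi, np.pi, size=spec.n_cells) + mu
    else:
        ang = rng.vonmises(mu, spec.kappa, size=spec.n_cells)

    labels = np.zeros(spec.shape, dtype=np.int32)
    rr, cc = np.mgrid[0:nr, 0:nc]
    for i, ((cy, cx), rad) in enumerate(zip(centers, radii), start=1):
        sl = (
            slice(max(int(cy - rad) - 1, 0), min(int(cy + rad) + 2, nr)),
            slice(max(int(cx - rad) - 1, 0), min(int(cx + rad) + 2, nc)),
        )
        inside = (rr[sl] - cy) ** 2 + (cc[sl] - cx) ** 2 <= rad**2
        labels[sl][inside] = i
    return FieldLayout(
        spec=spec,
        centers=centers,
        radii=radii,
        cbf_hz=cbf,
        direction_rad=ang,
        labels=labels,
        mean_direction=np.array([np.cos(mu), np.sin(mu)]),
    )


def render_bf_movie(layout: FieldLayout, *, dtype=np.uint16) -> Movie:
    """Bright-field stack: cell pixels oscillate at their planted CBF.

    Each cell pixel follows ``I(t) = baseline + A sin(2 pi f t + phase)``
    with an independent random phase per pixel (cilia within a cell are not
    phase-locked to the camera), plus Gaussian read noise everywhere.
    """
    spec = layout.spec
    rng = np.random.default_rng(spec.seed + 1)
    nt = spec.n_frames
    t = np.arange(nt, dtype=np.float32) / spec.frame_rate
    stack = rng.standard_normal((nt,) + spec.shape, dtype=np.float32)
    stack *= spec.noise_sd
    stack += spec.baseline

    for i in range(1, layout.n_cells + 1):
        px = np.nonzero(layout.labels == i)
        n_px = px[0].size
        if n_px == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi, size=n_px).astype(np.float32)
        osc = spec.amplitude * np.sin(
            2 * np.pi * layout.cbf_hz[i - 1] * t[:, None] + phase[None, :]
        )
        stack[:, px[0], px[1]] += osc.astype(np.float32)

    stack = np.clip(stack, 0, np.iinfo(dtype).max if np.issubdtype(dtype, np.integer) else None)
    return Movie(stack.astype(dtype), spec.frame_rate, spec.pixel_size)


def velocity_field(
    layout: FieldLayout, tracer: SyntheticTracerSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Planted flow field (µm/s) on the pixel grid.

    Sum over cells of isotropic Gaussian kernels centred on each cell and
    oriented along its beating direction, peaking at ``speed_um_s``.
    """
    nr, nc = layout.spec.shape
    vx = np.zeros((nr, nc))
    vy = np.zeros((nr, nc))
    rr, cc = np.mgrid[0:nr, 0:nc]
    w = tracer.flow_kernel_px
    for (cy, cx), ang in zip(layout.centers, layout.direction_rad):
        g = np.exp(-(((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * w**2)))
        vx += tracer.speed_um_s * np.cos(ang) * g
        vy += tracer.speed_um_s * np.sin(ang) * g
    return vx, vy


def render_tracer_movie(
    layout: FieldLayout,
    tracer: SyntheticTracerSpec,
    *,
    dtype=np.uint16,
    flow: tuple[np.ndarray, np.ndarray] | None = None,
) -> Movie:
    """Fluorescent tracer stack advected by the planted flow field.

    Particles are advected with bilinear samples of the planted velocity
    field plus Brownian jitter, wrap periodically at the frame edges, and
    are rendered as Gaussian spots of the particle's diffraction-limited
    size.  An explicit ``flow`` (vx, vy in µm/s on the pixel grid) overrides
    the per-cell kernel field.
    """
    spec = layout.spec
    rng = np.random.default_rng(tracer.seed + 101)
    nr, nc = spec.shape
    vx, vy = flow if flow is not None else velocity_field(layout, tracer)

    pos = rng.uniform([0, 0], [nr, nc], size=(tracer.n_particles, 2))  # row, col
    dt = 1.0 / tracer.frame_rate
    px = spec.pixel_size
    sigma_px = max(tracer.particle_diameter_um / 2.355 / px, 0.8)
    half = int(np.ceil(4 * sigma_px))
    offs = np.arange(-half, half + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")

    stack = rng.normal(
        tracer.baseline, tracer.noise_sd, size=(tracer.n_frames, nr, nc)
    )
    for f in range(tracer.n_frames):
        _splat(stack[f], pos, tracer.peak_intensity, sigma_px, oy, ox)
        iy = np.clip(pos[:, 0].astype(int), 0, nr - 1)
        ix = np.clip(pos[:, 1].astype(int), 0, nc - 1)
        step_row = vy[iy, ix] * dt / px
        step_col = vx[iy, ix] * dt / px
        jitter = rng.normal(0.0, tracer.brownian_sd_um / px, size=pos.shape)
        pos[:, 0] = (pos[:, 0] + step_row + jitter[:, 0]) % nr
        pos[:, 1] = (pos[:, 1] + step_col + jitter[:, 1]) % nc

    stack = np.clip(stack, 0, np.iinfo(dtype).max if np.issubdtype(dtype, np.integer) else None)
    return Movie(stack.astype(dtype), tracer.frame_rate, spec.pixel_size)


def _splat(frame, pos, peak, sigma, oy, ox):
    """Accumulate Gaussian spots at sub-pixel positions (periodic wrap)."""
    nr, nc = frame.shape
    cy = pos[:, 0]
    cx = pos[:, 1]
    base_y = np.round(cy).astype(int)
    base_x = np.round(cx).astype(int)
    fy = cy - base_y
    fx = cx - base_x
    # (n, k, k) stamp per particle
    dy = oy[None, :, :] - fy[:, None, None]
    dx = ox[None, :, :] - fx[:, None, None]
    stamp = peak * np.exp(-(dy**2 + dx**2) / (2 * sigma**2))
    rows = (base_y[:, None, None] + oy[None, :, :]) % nr
    cols = (base_x[:, None, None] + ox[None, :, :]) % nc
    np.add.at(frame, (rows.ravel(), cols.ravel()), stamp.ravel())


def make_dose_dataset(
    tau_grid: np.ndarray | list,
    tau_c: float,
    noise_sd: float = 0.05,
    n_fov: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy (tau, Phi) samples from Phi = 1 - exp(-tau/tau_c).

    ``n_fov`` replicates per stress level; Gaussian noise, clipped to
    [-1, 1].  Returns a frame with columns ``tau``, ``phi``, ``fov``.
    """
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    tau_grid = np.asarray(tau_grid, dtype=float)
    rng = np.random.default_rng(seed)
    tau = np.repeat(tau_grid, n_fov)
    fov = np.tile(np.arange(n_fov), tau_grid.size)
    phi = 1.0 - np.exp(-tau / tau_c)
    if noise_sd > 0:
        phi = phi + rng.normal(0.0, noise_sd, size=tau.size)
    return pd.DataFrame({"tau": tau, "phi": np.clip(phi, -1.0, 1.0), "fov": fov})


# ---------------------------------------------------------------------------
# parametric beat patterns
# ---------------------------------------------------------------------------

def make_beat_pattern(
    amplitude: float,
    asymmetry: float = 0.0,
    n_s: int = 25,
    n_t: int = 48,
    *,
    rest_tilt_deg: float = 90.0,
    wave: float = 0.0,
) -> BeatPattern:
    """Planar travelling-bend waveform with tunable stroke asymmetry.

    ``psi(s, t) = rest + amplitude cos(2 pi (t - wave s))
                  + asymmetry cos(4 pi (t - wave s))``

    ``amplitude`` sets the stroke sweep, ``asymmetry`` (the first even
    harmonic) biases the power stroke relative to the recovery stroke, and
    ``wave`` is the number of bend wavelengths along the length (0 gives a
    rigidly pivoting rod).  With the default vertical rest angle the
    centerline never penetrates the surface as long as
    ``|amplitude| + |asymmetry| < pi/2``.
    """
    if abs(amplitude) + abs(asymmetry) >= np.pi / 2 and rest_tilt_deg == 90.0:
        raise ValueError("|amplitude| + |asymmetry| must stay below pi/2")
    s = np.linspace(0.0, 1.0, n_s)
    t = np.arange(n_t) / n_t
    ph = 2 * np.pi * (t[None, :] - wave * s[:, None])
    psi = (
        np.radians(rest_tilt_deg)
        + amplitude * np.cos(ph)
        + asymmetry * np.cos(2 * ph)
    )
    return BeatPattern(s, t, psi)


def beat_pattern_with_extremes(
    forward_deg: float = 23.0,
    backward_deg: float = 18.0,
    n_s: int = 25,
    n_t: int = 48,
) -> BeatPattern:
    """Pivoting-rod waveform whose chord extremes hit prescribed angles.

    Solves for the amplitude and first even harmonic of
    :func:`make_beat_pattern` (with ``wave = 0``) so that the base-to-tip
    chord reaches ``forward_deg`` elevation at the power-stroke extreme and
    ``backward_deg`` on the recovery side.  For a rigidly pivoting rod the
    chord elevation equals psi directly, so the two coefficients follow in
    closed form.
    """
    lo = np.radians(forward_deg)          # smallest psi (forward lean)
    hi = np.pi - np.radians(backward_deg)  # largest psi (backward lean)
    amplitude = -(hi - lo) / 2.0  # negative: forward extreme at t = 0
    asymmetry = (hi + lo) / 2.0 - np.pi / 2
    if abs(amplitude) <= 4.0 * abs(asymmetry):
        raise ValueError("targets produce interior stroke extremes; unsupported")
    return make_beat_pattern(amplitude, asymmetry, n_s, n_t)
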