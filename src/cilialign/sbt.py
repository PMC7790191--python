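"""Slender-body Stokes hydrodynamics of tilted rod arrays above a no-slip wall.

Cilia are coarse-grained as static rigid rods of length ``L = 1`` and radius
``r = 0.02``, tilted at the mean-tangent angle (default 53 degrees) toward
their beating direction ``e-hat`` and anchored a small gap above a plane
no-slip wall.  An external shear flow ``u = gammadot * z * g-hat`` forces the
array; the unknown force density along each centerline is found by requiring
the total fluid velocity to vanish on every rod.

Numerics
--------
* Within a rod the velocity induced by its own (piecewise-constant) force
  density is integrated analytically segment by segment, with the radial
  offset ``r`` regularizing the kernel and the circumferential average of the
  Stokeslet taken on the rod surface.  For a straight filament this
  reproduces the slender-body drag coefficients, including the O(1)
  constants, and is stable at any node count.
* Rod-rod coupling uses midpoint-quadrature Stokeslets (closest approach is
  at least four radii, so the omitted finite-radius doublet correction is an
  O((r/d)^2) < 7% effect on the coupling terms only).
* The wall is the exact Blake image system for every Stokeslet, so the
  no-slip condition on z = 0 holds to machine precision.

Torques are reported as the z-component about the vertical axis through each
rod's base, non-dimensionalised by ``eta * gammadot * L^3``; the sign is
positive when the torque rotates the beating direction toward the flow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from .beat import min_parallel_spacing

__all__ = [
    "RodArrayConfig",
    "StokesDiscretization",
    "RodGeometry",
    "ForceDensitySolution",
    "TorqueResult",
    "ScreeningTable",
    "place_rods",
    "ambient_shear",
    "solve_force_density",
    "rod_torque_z",
    "evaluate_velocity",
    "isolated_rod_torque",
    "screening_sweep",
    "lattice_convergence",
    "DEFAULT_D_PAR_MIN",
    "DEFAULT_A_TOP",
]

#: Minimum center spacing along the beating direction: the sum of the
#: horizontal reaches at the 23/18 degree stroke extremes (units of L).
DEFAULT_D_PAR_MIN = min_parallel_spacing(23.0, 18.0)

#: Top-view footprint of one beating cilium, units of L^2: the swept length
#: (sum of the stroke-extreme reaches) times one body width.  With this
#: footprint the perpendicular spacings 0.08..0.40 L map onto ciliated area
#: fractions 0.5 down to 0.1, bracketing the values measured in maturing
#: (~0.09) and mature (~0.17) cultures.
DEFAULT_A_TOP = DEFAULT_D_PAR_MIN * 0.04


@dataclass(frozen=True)
class RodArrayConfig:
    """Geometry of a rectangular lattice of identical tilted rods.

    ``theta`` is the angle between the beating direction ``e-hat`` (the
    direction the rods lean toward, in the x-y plane) and the imposed flow
    direction ``y-hat``; ``theta = 0`` means beating parallel to the flow.
    Spacings are centre-to-centre, in units of the rod length.
    """

    n_rows: int = 9
    n_cols: int = 9
    d_perp: float = 0.08
    d_par: float = DEFAULT_D_PAR_MIN
    tilt_alpha: float = 53.0
    rod_length: float = 1.0
    radius: float = 0.02
    wall_gap: float = 0.05
    theta: float = np.pi / 2

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice counts must be >= 1")
        d_perp_min = 2 * (2 * self.radius)
        if self.n_cols > 1 and self.d_perp < d_perp_min - 1e-12:
            raise ValueError(
                f"d_perp={self.d_perp} below the two-body-width minimum {d_perp_min}"
            )
        d_par_min = DEFAULT_D_PAR_MIN * self.rod_length
        if self.n_rows > 1 and self.d_par < d_par_min - 1e-9:
            raise ValueError(
                f"d_par={self.d_par} below the stroke-extent minimum {d_par_min:.4f}"
            )
        if not (0.0 <= self.theta <= np.pi / 2 + 1e-12):
            raise ValueError("theta must lie in [0, pi/2]")
        if self.radius <= 0 or self.rod_length <= 0 or self.wall_gap < 0:
            raise ValueError("radius/rod_length must be positive, wall_gap >= 0")

    @property
    def n_rods(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RodArrayConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass(frozen=True)
class StokesDiscretization:
    """Numerical parameters of the slender-body solve.

    ``radius_profile`` selects the filament shape the intra-rod kernel is
    integrated over: ``"spheroidal"`` (the canonical slender-body choice,
    radius ``2 r sqrt(s (1 - s))``, giving a uniform drag log along the rod)
    or ``"cylindrical"`` (constant radius; slightly higher end drag).
    """

    segments_per_rod: int = 24
    regularization: float | None = None  # defaults to the rod radius
    shear_rate: float = 1.0
    viscosity: float = 1.0
    radius_profile: str = "spheroidal"

    def __post_init__(self) -> None:
        if self.segments_per_rod < 8:
            raise ValueError("need at least 8 segments per rod")
        if self.regularization is not None and self.regularization <= 0:
            raise ValueError("regularization must be positive")
        if self.radius_profile not in ("spheroidal", "cylindrical"):
            raise ValueError("radius_profile must be 'spheroidal' or 'cylindrical'")


@dataclass(frozen=True)
class RodGeometry:
    """Discretized rod array: base points, shared axis, centerline nodes."""

    config: RodArrayConfig
    bases: np.ndarray      # (N_r, 3)
    axis: np.ndarray       # (3,) unit vector along every rod
    e_hat: np.ndarray      # (3,) in-plane beating direction
    nodes: np.ndarray      # (N_r, M, 3) segment midpoints
    node_s: np.ndarray     # (M,) arclength of midpoints
    seg_edges: np.ndarray  # (M+1,) segment edges in arclength
    wall: bool = True

    @property
    def n_rods(self) -> int:
        return self.bases.shape[0]

    @property
    def segments_per_rod(self) -> int:
        return self.nodes.shape[1]

    @property
    def seg_length(self) -> float:
        return float(self.seg_edges[1] - self.seg_edges[0])


@dataclass(frozen=True)
class ForceDensitySolution:
    """Per-node force densities (force per unit length the rods exert on the
    fluid) together with the geometry and flow they were solved for."""

    geometry: RodGeometry
    discretization: StokesDiscretization
    flow_direction: np.ndarray  # (3,) unit vector of the shear flow
    force_density: np.ndarray   # (N_r, M, 3)
    residual: float


@dataclass(frozen=True)
class TorqueResult:
    """z-torques about each rod base, in units of eta * gammadot * L^3."""

    per_rod_torque_z: np.ndarray
    mean_torque: float
    isolated_reference: float | None = None


@dataclass(frozen=True)
class ScreeningTable:
    """Normalized torque T(theta, rho) / T_0(pi/2) over a density sweep."""

    theta_grid: np.ndarray      # (n_theta,)
    rho_grid: np.ndarray        # (n_rho,) ciliated area fraction
    d_perp_grid: np.ndarray     # (n_rho,)
    normalized_torque: np.ndarray  # (n_theta, n_rho)
    t0: float                   # isolated-rod torque at theta = pi/2
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        th, rh = np.meshgrid(self.theta_grid, self.rho_grid, indexing="ij")
        return pd.DataFrame(
            {
                "theta_rad": th.ravel(),
                "rho": rh.ravel(),
                "torque_normalized": self.normalized_torque.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta_grid": self.theta_grid.tolist(),
            "rho_grid": self.rho_grid.tolist(),
            "d_perp_grid": self.d_perp_grid.tolist(),
            "normalized_torque": self.normalized_torque.tolist(),
            "t0": self.t0,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreeningTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["theta_grid"]),
            np.asarray(payload["rho_grid"]),
            np.asarray(payload["d_perp_grid"]),
            np.asarray(payload["normalized_torque"]),
            payload["t0"],
            payload.get("metadata", {}),
        )

    @classmethod
    def from_csv(cls, path: str | Path, t0: float = np.nan) -> "ScreeningTable":
        df = pd.read_csv(path)
        theta = np.unique(df["theta_rad"])
        rho = np.unique(df["rho"])
        tq = (
            df.pivot(index="theta_rad", columns="rho", values="torque_normalized")
            .sort_index()
            .to_numpy()
        )
        return cls(theta, rho, np.full_like(rho, np.nan), tq, t0)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def place_rods(
    config: RodArrayConfig,
    discretization: StokesDiscretization | None = None,
    *,
    wall: bool = True,
) -> RodGeometry:
    """Build the discretized rod lattice for a configuration.

    The beating direction is ``e-hat = (sin theta, cos theta, 0)`` so that it
    makes the configured angle with the flow direction ``y-hat``.  Rows of
    rods run along ``e-hat`` with spacing ``d_par``; columns run along the
    in-plane perpendicular with spacing ``d_perp``.  The lattice is centred
    on the origin, each rod's axis is ``cos(alpha) e-hat + sin(alpha) z-hat``
    and bases sit at ``z = wall_gap``.
    """
    disc = discretization or StokesDiscretization()
    th, al = config.theta, np.radians(config.tilt_alpha)
    e_hat = np.array([np.sin(th), np.cos(th), 0.0])
    p_hat = np.array([np.cos(th), -np.sin(th), 0.0])  # z-hat x e_hat up to sign
    axis = np.cos(al) * e_hat + np.sin(al) * np.array([0.0, 0.0, 1.0])

    i_par = (np.arange(config.n_rows) - (config.n_rows - 1) / 2) * config.d_par
    j_perp = (np.arange(config.n_cols) - (config.n_cols - 1) / 2) * config.d_perp
    bases = (
        i_par[:, None, None] * e_hat + j_perp[None, :, None] * p_hat
    ).reshape(-1, 3)
    bases[:, 2] = config.wall_gap

    m = disc.segments_per_rod
    edges = np.linspace(0.0, config.rod_length, m + 1)
    node_s = 0.5 * (edges[:-1] + edges[1:])
    nodes = bases[:, None, :] + node_s[None, :, None] * axis[None, None, :]
    return RodGeometry(
        config=config,
        bases=bases,
        axis=axis,
        e_hat=e_hat,
        nodes=nodes,
        node_s=node_s,
        seg_edges=edges,
        wall=wall,
    )


def ambient_shear(
    points: np.ndarray,
    shear_rate: float = 1.0,
    flow_direction: np.ndarray | tuple = (0.0, 1.0, 0.0),
) -> np.ndarray:
    """Linear shear flow ``u = gammadot * z * g-hat`` above a no-slip wall."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(pts[:, 2] < -1e-12):
        raise ValueError("ambient shear is defined for z >= 0 only")
    g = np.asarray(flow_direction, dtype=float)
    g = g / np.linalg.norm(g)
    u = shear_rate * pts[:, 2:3] * g[None, :]
    return u if np.asarray(points).ndim > 1 else u[0]


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _stokeslet(r_vec: np.ndarray) -> np.ndarray:
    """Free-space Stokeslet S_ij = delta_ij/R + R_i R_j / R^3, batched."""
    r = np.linalg.norm(r_vec, axis=-1)
    r = np.where(r == 0, np.inf, r)
    eye = np.eye(3)
    return (
        eye / r[..., None, None]
        + r_vec[..., :, None] * r_vec[..., None, :] / r[..., None, None] ** 3
    )


def _blake_image(targets: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Image part of the Blake tensor: G_blake - S_free.

    ``targets``: (N, 3) evaluation points; ``sources``: (Q, 3) Stokeslet
    locations at height h = z_source above the wall z = 0.  Returns
    (N, Q, 3, 3) such that adding the free-space Stokeslet gives a velocity
    field that vanishes exactly on the wall.
    """
    h = sources[:, 2]
    mirror = sources.copy()
    mirror[:, 2] = -h
    rv = targets[:, None, :] - mirror[None, :, :]  # R = x - y*
    r = np.linalg.norm(rv, axis=-1)
    r3 = r**3
    r5 = r**5
    eye = np.eye(3)

    out = -_stokeslet(rv)

    # potential-dipole part: PD_ij = delta_ij/R^3 - 3 R_i R_j / R^5
    pd = (
        eye / r3[..., None, None]
        - 3.0 * rv[..., :, None] * rv[..., None, :] / r5[..., None, None]
    )
    # Stokeslet-doublet part:
    # SD_ij = -delta_i3 R_j/R^3 + delta_ij R_3/R^3 + delta_j3 R_i/R^3
    #         - 3 R_i R_3 R_j / R^5
    sd = np.zeros_like(pd)
    sd += eye * (rv[..., 2] / r3)[..., None, None]
    sd[..., 2, :] += -rv / r3[..., None]
    sd[..., :, 2] += rv / r3[..., None]
    sd += -3.0 * rv[..., :, None] * rv[..., None, :] * (rv[..., 2] / r5)[..., None, None]

    beta = np.array([1.0, 1.0, -1.0])
    hh = h[None, :, None, None]
    out += 2.0 * hh * (hh * pd - sd) * beta[None, None, None, :]
    return out


def _intra_rod_block(geom: RodGeometry, disc: StokesDiscretization) -> np.ndarray:
    """(3M, 3M) operator: velocity on a rod from its own force density.

    The Stokeslet is integrated exactly over each straight segment at the
    surface of the evaluation node (radial offset = regularization radius,
    circumferentially averaged), which regularizes the self term and
    reproduces the slender-body drag logs for a straight rod.
    """
    a = geom.axis
    r0 = disc.regularization if disc.regularization is not None else geom.config.radius
    s = geom.node_s
    e = geom.seg_edges
    length = geom.config.rod_length
    m = s.size

    # radius at each evaluation node: spheroidal taper or constant
    sn = s / length
    if disc.radius_profile == "spheroidal":
        r = 2.0 * r0 * np.sqrt(np.clip(sn * (1.0 - sn), 1e-12, None))
    else:
        r = np.full(m, r0)
    r = r[:, None]  # broadcast over source segments

    # signed offsets of segment edges relative to each evaluation node
    p = e[None, :-1] - s[:, None]  # (M, M) lower edge
    q = e[None, 1:] - s[:, None]   # upper edge

    def asinh(x):
        return np.arcsinh(x / r)

    def sq(x):
        return x / np.sqrt(x**2 + r**2)

    i1 = asinh(q) - asinh(p)
    i3 = (sq(q) - sq(p)) / r**2
    i3s2 = (asinh(q) - sq(q)) - (asinh(p) - sq(p))

    c_par = i1 + i3s2                 # coefficient of t t . f
    c_perp = i1 + 0.5 * r**2 * i3     # coefficient of (I - t t) . f

    tt = np.outer(a, a)
    pp = np.eye(3) - tt
    block = (
        c_par[:, :, None, None] * tt[None, None, :, :]
        + c_perp[:, :, None, None] * pp[None, None, :, :]
    )
    return block.transpose(0, 2, 1, 3).reshape(3 * m, 3 * m)


def _assemble_matrix(geom: RodGeometry, disc: StokesDiscretization) -> np.ndarray:
    """Dense operator A with  8 pi eta u(x_a) = [A f]_a  on all nodes."""
    nrod, m = geom.n_rods, geom.segments_per_rod
    n = nrod * m
    x = geom.nodes.reshape(n, 3)
    w = geom.seg_length

    a_mat = _stokeslet(x[:, None, :] - x[None, :, :])
    # same-rod interactions are handled by the analytic intra-rod operator
    rod_id = np.repeat(np.arange(nrod), m)
    same = rod_id[:, None] == rod_id[None, :]
    a_mat[same] = 0.0
    if geom.wall:
        a_mat += _blake_image(x, x)
    a_mat *= w
    a_mat = a_mat.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)

    intra = _intra_rod_block(geom, disc)
    for p_ in range(nrod):
        sl = slice(3 * m * p_, 3 * m * (p_ + 1))
        a_mat[sl, sl] += intra
    return a_mat


# ---------------------------------------------------------------------------
# solve and post-process
# ---------------------------------------------------------------------------

def solve_force_density(
    geometry: RodGeometry,
    discretization: StokesDiscretization | None = None,
    *,
    flow_direction: np.ndarray | tuple = (0.0, 1.0, 0.0),
) -> ForceDensitySolution:
    """Force density on every rod such that the rods are rigid and static.

    Solves ``u_ambient(x_a) + u_induced[f](x_a) = 0`` on all centerline
    nodes.  ``flow_direction`` is the (in-plane) direction of the imposed
    shear flow, ``y-hat`` by default.
    """
    disc = discretization or StokesDiscretization()
    if geometry.segments_per_rod != disc.segments_per_rod:
        raise ValueError("geometry was discretized with a different node count")
    a_mat = _assemble_matrix(geometry, disc)
    sol, res = _solve_rhs(a_mat, geometry, disc, np.asarray(flow_direction, float))
    return ForceDensitySolution(
        geometry=geometry,
        discretization=disc,
        flow_direction=np.asarray(flow_direction, float),
        force_density=sol,
        residual=res,
    )


def _solve_rhs(a_mat, geometry, disc, flow_direction):
    n = geometry.n_rods * geometry.segments_per_rod
    x = geometry.nodes.reshape(n, 3)
    u_inf = ambient_shear(x, disc.shear_rate, flow_direction)
    rhs = -8.0 * np.pi * disc.viscosity * u_inf.ravel()
    try:
        f = np.linalg.solve(a_mat, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise RuntimeError(f"slender-body system is singular: {exc}") from exc
    res = float(np.linalg.norm(a_mat @ f - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if res > 1e-8:
        raise RuntimeError(f"slender-body solve did not converge, residual {res:.2e}")
    return f.reshape(geometry.n_rods, geometry.segments_per_rod, 3), res


def rod_torque_z(
    solution: ForceDensitySolution, *, aligning_sign: bool = True
) -> TorqueResult:
    """z-torque about each rod's base, non-dimensionalised by eta*gammadot*L^3.

    The torque exerted by the fluid on a rod is minus the integral of the
    force density the rod exerts on the fluid.  With ``aligning_sign`` the
    sign is flipped so that a torque rotating the beating direction toward
    the flow is positive regardless of which side of the flow it leans.
    """
    geom = solution.geometry
    disc = solution.discretization
    w = geom.seg_length
    arm = geom.nodes - geom.bases[:, None, :]
    tq = -np.cross(arm, solution.force_density)[:, :, 2].sum(axis=1) * w
    scale = disc.viscosity * disc.shear_rate * geom.config.rod_length**3
    tq = tq / scale
    if aligning_sign:
        g = solution.flow_direction
        sense = np.sign(np.cross(geom.e_hat, g)[2])
        if sense != 0:
            tq = tq * sense
    return TorqueResult(per_rod_torque_z=tq, mean_torque=float(np.mean(tq)))


def evaluate_velocity(
    points: np.ndarray, solution: ForceDensitySolution
) -> np.ndarray:
    """Total fluid velocity at field points away from the rods.

    Ambient shear plus the point-quadrature Stokeslet (and Blake image)
    field of the solved force densities.  On the wall plane this vanishes to
    machine precision when the wall is enabled.
    """
    geom, disc = solution.geometry, solution.discretization
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = geom.n_rods * geom.segments_per_rod
    src = geom.nodes.reshape(n, 3)
    fq = solution.force_density.reshape(n, 3) * geom.seg_length

    kern = _stokeslet(pts[:, None, :] - src[None, :, :])
    if geom.wall:
        kern = kern + _blake_image(pts, src)
    u = np.einsum("pqij,qj->pi", kern, fq) / (8.0 * np.pi * disc.viscosity)
    u += ambient_shear(pts, disc.shear_rate, solution.flow_direction)
    return u if np.asarray(points).ndim > 1 else u[0]


def isolated_rod_torque(
    tilt_alpha: float = 53.0,
    theta: float = np.pi / 2,
    discretization: StokesDiscretization | None = None,
    *,
    wall: bool = True,
    config: RodArrayConfig | None = None,
) -> float:
    """Aligning z-torque on a single isolated rod (units eta*gammadot*L^3)."""
    disc = discretization or StokesDiscretization()
    cfg = config or RodArrayConfig(n_rows=1, n_cols=1, tilt_alpha=tilt_alpha, theta=theta)
    geom = place_rods(cfg, disc, wall=wall)
    sol = solve_force_density(geom, disc)
    return rod_torque_z(sol).mean_torque


# ---------------------------------------------------------------------------
# screening sweep
# ---------------------------------------------------------------------------

def screening_sweep(
    d_perp_list: np.ndarray | list | None = None,
    theta_grid: np.ndarray | list | None = None,
    config: RodArrayConfig | None = None,
    discretization: StokesDiscretization | None = None,
    *,
    a_top: float = DEFAULT_A_TOP,
) -> ScreeningTable:
    """Normalized screening table T(theta, rho) / T_0(pi/2).

    For each perpendicular spacing the lattice (held with its beating
    direction fixed) is solved once and re-used for every flow angle, since
    rotating the flow only changes the right-hand side.  The ciliated area
    fraction is ``rho = a_top / (d_par * d_perp)``; with the default
    footprint, minimum spacing corresponds to ``rho = 1``.
    """
    if d_perp_list is None:
        d_perp_list = [0.08, 0.16, 0.24, 0.32, 0.40]
    if theta_grid is None:
        theta_grid = np.linspace(0.0, np.pi / 2, 7)
    d_perp_list = np.asarray(d_perp_list, dtype=float)
    theta_grid = np.asarray(theta_grid, dtype=float)
    base = config or RodArrayConfig()
    disc = discretization or StokesDiscretization()

    t0 = isolated_rod_torque(base.tilt_alpha, np.pi / 2, disc)

    rho = a_top / (base.d_par * d_perp_list)
    torque = np.empty((theta_grid.size, d_perp_list.size))
    for j, dp in enumerate(d_perp_list):
        cfg = replace(base, d_perp=float(dp), theta=np.pi / 2)  # e_hat = x_hat
        geom = place_rods(cfg, disc)
        a_mat = _assemble_matrix(geom, disc)
        lu = lu_factor(a_mat)
        for i, th in enumerate(theta_grid):
            g = np.array([np.cos(th), np.sin(th), 0.0])  # angle th from e_hat
            n = geom.n_rods * geom.segments_per_rod
            u_inf = ambient_shear(geom.nodes.reshape(n, 3), disc.shear_rate, g)
            rhs = -8.0 * np.pi * disc.viscosity * u_inf.ravel()
            f = lu_solve(lu, rhs).reshape(geom.n_rods, geom.segments_per_rod, 3)
            sol = ForceDensitySolution(geom, disc, g, f, 0.0)
            torque[i, j] = rod_torque_z(sol).mean_torque

    return ScreeningTable(
        theta_grid=theta_grid,
        rho_grid=rho,
        d_perp_grid=d_perp_list,
        normalized_torque=torque / t0,
        t0=t0,
        metadata={
            "n_rows": base.n_rows,
            "n_cols": base.n_cols,
            "segments_per_rod": disc.segments_per_rod,
            "d_par": base.d_par,
            "a_top": a_top,
            "tilt_alpha": base.tilt_alpha,
        },
    )


def lattice_convergence(
    sizes: list[int],
    d_perp: float = 0.16,
    discretization: StokesDiscretization | None = None,
) -> pd.DataFrame:
    """Mean rod torque at theta = pi/2 versus square lattice size.

    Utility for choosing the lattice extent: the all-rod average torque
    approaches its large-array limit as the lattice grows.
    """
    disc = discretization or StokesDiscretization()
    rows = []
    for nside in sizes:
        cfg = RodArrayConfig(n_rows=nside, n_cols=nside, d_perp=d_perp)
        geom = place_rods(cfg, disc)
        sol = solve_force_density(geom, disc)
        rows.append({"n_side": nside, "mean_torque": rod_torque_z(sol).mean_torque})
    return pd.DataFrame(rows)
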