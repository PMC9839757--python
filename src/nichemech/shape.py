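"""Constant-volume force-balance shape of a vertically compressed adherent cell.

The uncompressed cell is modelled as a hemisphere of radius ``r0`` resting on
its substrate.  When a rigid plate limits the cell height to ``H < r0`` the
cell keeps its volume and its cortex, carrying a uniform Laplace tension,
adopts the classic squeezed-droplet geometry:

* a flat contact disc against the plate (both principal curvatures zero,
  normal force carried by the plate),
* an axisymmetric free surface of constant mean curvature
  ``c_m + c_h = dP/T`` (Young-Laplace), leaving the plate tangentially at the
  contact-disc edge and meeting the substrate at the 90 degree contact angle
  of the uncompressed hemisphere,
* an enclosed volume equal to the uncompressed value ``(2/3) pi r0^3``.

Two scalars close the problem: the contact-disc radius and the Laplace mean
curvature.  Both are found by a root solve on the shooting map of the
tangent-angle/arclength equations

    d rho / ds = cos(psi),  dz / ds = -sin(psi),
    d psi / ds = h - sin(psi) / rho,

where ``psi`` is the tangent angle of the meridian and ``h`` the (constant)
mean curvature.  The solve is performed in units of ``r0`` — the geometry is
exactly scale invariant — and rescaled afterwards.

Directional cortical tensions are then read off the free surface through the
curvature closure ``T ~ k / c``: the azimuthal (overall) tension is ``k``
divided by the meridional curvature ``c_m`` and the axial tension is ``k``
divided by the hoop curvature ``c_h``.  The hoop curvature vanishes at the
tangential departure from the plate, so the *arithmetic* surface mean of
``k/c_h`` diverges logarithmically with resolution; the package therefore
summarises both tensions by the area-weighted geometric (log-domain) mean,
which is finite, parameter free and coincides with the arithmetic mean on the
uniform uncompressed hemisphere.  Arithmetic (with a one-grid-cell collar at
the contact line) and harmonic means are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import ConvergenceError, NumericalValidityError

__all__ = [
    "GeometryParams",
    "ShapeSolution",
    "TensionSummary",
    "solve_compressed_shape",
    "compute_volume",
    "surface_average_tension",
    "tension_vs_strain",
]

DEFAULT_DTHETA = np.pi / 1000

# warm-start table for the 2-unknown root solve, in units of r0:
# strain -> (contact radius, mean curvature)
_GUESS_STRAIN = np.array([0.0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.54, 0.60, 0.70])
_GUESS_RC = np.array([0.0, 0.138, 0.215, 0.350, 0.484, 0.628, 0.794, 0.870, 0.997, 1.27])
_GUESS_H = np.array([2.0, 2.003, 2.009, 2.046, 2.112, 2.213, 2.362, 2.439, 2.582, 2.93])


@dataclass(frozen=True)
class GeometryParams:
    """Geometry and numerics of the compressed-shape problem.

    Parameters
    ----------
    r0 : float
        Uncompressed hemisphere radius in micrometres.
    height : float
        Imposed apex height ``H`` in micrometres, ``0 < H <= r0``.
    dtheta : float
        Angular increment of the reporting grid (radians); also the angular
        collar excluded from the secondary arithmetic tension mean at the
        contact line.  Default ``pi/1000``.
    volume_tol : float
        Accepted relative volume error of a converged shape.  Default 1%.
    """

    r0: float
    height: float
    dtheta: float = DEFAULT_DTHETA
    volume_tol: float = 0.01

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        if not 0 < self.height <= self.r0:
            raise ValueError(
                f"height must satisfy 0 < H <= r0, got H={self.height}, r0={self.r0}"
            )
        if self.dtheta <= 0:
            raise ValueError("dtheta must be positive")
        if self.volume_tol <= 0:
            raise ValueError("volume_tol must be positive")

    @property
    def strain(self) -> float:
        """Compressive strain ``(r0 - H)/r0``."""
        return (self.r0 - self.height) / self.r0


@dataclass
class ShapeSolution:
    """Converged compressed-cell surface.

    ``theta`` spans ``[0, pi/2]`` (0 = apex axis).  Nodes with
    ``theta <= theta_contact`` lie on the flat plate-contact disc where both
    curvature fields are zero and the tension closure does not apply; the
    free surface starts at ``theta_contact``.
    """

    params: GeometryParams
    theta: np.ndarray
    radius: np.ndarray          # local radius R(theta), um
    curv_azimuthal: np.ndarray  # meridional curvature c1 (1/um); 0 on the disc
    curv_axial: np.ndarray      # hoop curvature c2 (1/um); 0 on the disc
    volume: float               # enclosed volume, um^3
    pressure_scale: float       # Laplace mean curvature dP/T, 1/um
    spreading_radius: float     # basal radius, um
    contact_radius: float       # plate-contact disc radius, um
    theta_contact: float        # polar angle of the contact-disc edge
    # dense free-surface trace used for quadratures (arclength parametrised)
    _free: dict = field(default_factory=dict, repr=False)

    @property
    def strain(self) -> float:
        return self.params.strain

    @property
    def volume_error(self) -> float:
        v0 = 2 / 3 * np.pi * self.params.r0 ** 3
        return abs(self.volume - v0) / v0


@dataclass(frozen=True)
class TensionSummary:
    """Surface-averaged directional tension of one compressed shape.

    Tensions are in units of the (unknown) closure constant ``k`` times
    micrometres; ``*_rel`` values are normalised by the uncompressed
    hemisphere value ``k * r0`` and are the quantities of the model's
    tension-vs-strain prediction.  The primary summary is the area-weighted
    geometric mean of ``k/c`` over the free surface; ``alternatives`` holds
    the arithmetic (contact-line collar of one ``dtheta``) and harmonic
    variants.
    """

    strain: float
    t_overall: float
    t_axial: float
    t_overall_rel: float
    t_axial_rel: float
    alternatives: dict = field(default_factory=dict)


def _shoot(rc: float, h: float, height: float, dense: bool = False):
    """Integrate the free-surface equations from the contact-disc edge.

    Works in units of r0.  Returns the solve_ivp result; integration stops
    when the tangent angle reaches pi/2 (perpendicular substrate contact).
    """

    def rhs(s, y):
        rho, z, psi, vol, area = y
        sp = np.sin(psi)
        return [np.cos(psi), -sp, h - sp / rho, np.pi * rho * rho * sp, 2 * np.pi * rho]

    def at_substrate(s, y):
        return y[2] - np.pi / 2

    at_substrate.terminal = True
    at_substrate.direction = 1
    return solve_ivp(
        rhs,
        [0.0, 60.0],
        [rc, height, 1e-9, 0.0, 0.0],
        events=at_substrate,
        rtol=1e-10,
        atol=1e-12,
        dense_output=dense,
        max_step=0.01,
    )


def _solve_normalized(strain: float):
    """Solve for (contact radius, mean curvature) in units of r0."""
    height = 1.0 - strain
    v0 = 2 / 3 * np.pi

    def residuals(x):
        rc, h = x
        if rc <= 0 or h <= 0:
            return [10.0, 10.0]
        sol = _shoot(rc, h, height)
        if not sol.t_events[0].size:
            return [10.0, 10.0]
        rho, z, psi, vol, area = sol.y[:, -1]
        # any z left below the last point closes as a cylinder
        return [z / height, (vol + np.pi * rho * rho * z - v0) / v0]

    guess = (
        float(np.interp(strain, _GUESS_STRAIN, _GUESS_RC)),
        float(np.interp(strain, _GUESS_STRAIN, _GUESS_H)),
    )
    res = root(residuals, guess, method="hybr", tol=1e-12)
    final = residuals(res.x)
    if not res.success or max(abs(f) for f in final) > 1e-8:
        raise ConvergenceError(
            f"compressed-shape solve failed at strain {strain:.4f}",
            residuals={"substrate_height": final[0], "volume": final[1]},
        )
    return float(res.x[0]), float(res.x[1])


def _hemisphere_solution(params: GeometryParams) -> ShapeSolution:
    theta = np.arange(0.0, np.pi / 2 + 0.5 * params.dtheta, params.dtheta)
    r0 = params.r0
    radius = np.full_like(theta, r0)
    curv = np.full_like(theta, 1.0 / r0)
    s = np.linspace(0, np.pi / 2 * r0, 2001)
    free = {
        "s": s,
        "rho": r0 * np.sin(s / r0),
        "cm": np.full_like(s, 1.0 / r0),
        "ch": np.full_like(s, 1.0 / r0),
        "theta": s / r0,
    }
    return ShapeSolution(
        params=params,
        theta=theta,
        radius=radius,
        curv_azimuthal=curv.copy(),
        curv_axial=curv.copy(),
        volume=2 / 3 * np.pi * r0 ** 3,
        pressure_scale=2.0 / r0,
        spreading_radius=r0,
        contact_radius=0.0,
        theta_contact=0.0,
        _free=free,
    )


def solve_compressed_shape(params: GeometryParams) -> ShapeSolution:
    """Solve the constant-volume force balance for one imposed height.

    Returns a :class:`ShapeSolution` whose free surface satisfies the uniform
    tension Young-Laplace balance to solver tolerance, with
    ``R(theta=0) = H``, a symmetric apex, and the volume matched to the
    uncompressed hemisphere (checked against ``params.volume_tol``).

    Raises
    ------
    ConvergenceError
        If the two-parameter root solve does not converge; the final
        height/volume residuals are attached.
    """
    strain = params.strain
    if strain < 1e-9:
        return _hemisphere_solution(params)

    rc_n, h_n = _solve_normalized(strain)
    r0 = params.r0
    height = params.height

    sol = _shoot(rc_n, h_n, 1.0 - strain, dense=True)
    s_end = sol.t_events[0][0]
    s = np.linspace(0.0, s_end, 4001)
    rho, z, psi, vol_n, area_n = sol.sol(s)
    # clamp terminal round-off
    z = np.clip(z, 0.0, None)
    cm = h_n - np.sin(psi) / rho
    ch = np.sin(psi) / rho
    theta_free = np.arctan2(rho, z)
    theta_c = np.arctan2(rc_n, 1.0 - strain)

    volume = (vol_n[-1] + np.pi * rho[-1] ** 2 * z[-1]) * r0 ** 3
    v0 = 2 / 3 * np.pi * r0 ** 3
    if abs(volume - v0) / v0 > params.volume_tol:
        raise ConvergenceError(
            f"volume error {abs(volume - v0) / v0:.3e} exceeds tolerance",
            residuals={"volume": (volume - v0) / v0},
        )

    theta = np.arange(0.0, np.pi / 2 + 0.5 * params.dtheta, params.dtheta)
    on_disc = theta <= theta_c
    radius = np.empty_like(theta)
    c1 = np.zeros_like(theta)
    c2 = np.zeros_like(theta)
    radius[on_disc] = height / np.cos(theta[on_disc])
    r_free = np.sqrt(rho ** 2 + z ** 2) * r0
    tf = theta[~on_disc]
    radius[~on_disc] = np.interp(tf, theta_free, r_free)
    c1[~on_disc] = np.interp(tf, theta_free, cm) / r0
    c2[~on_disc] = np.interp(tf, theta_free, ch) / r0

    free = {
        "s": s * r0,
        "rho": rho * r0,
        "cm": cm / r0,
        "ch": ch / r0,
        "theta": theta_free,
    }
    return ShapeSolution(
        params=params,
        theta=theta,
        radius=radius,
        curv_azimuthal=c1,
        curv_axial=c2,
        volume=volume,
        pressure_scale=h_n / r0,
        spreading_radius=rho[-1] * r0,
        contact_radius=rc_n * r0,
        theta_contact=theta_c,
        _free=free,
    )


def compute_volume(theta: np.ndarray, radius: np.ndarray) -> float:
    """Enclosed volume of an axisymmetric surface given as ``R(theta)``.

    Uses the axisymmetric volume integral
    ``V = pi * int R^2 sin^2(theta) (R sin(theta) - R' cos(theta)) dtheta``
    with second-order (trapezoidal) quadrature and central-difference ``R'``.
    For constant ``R = r0`` this is the hemisphere closed form
    ``(2/3) pi r0^3`` up to quadrature error.
    """
    theta = np.asarray(theta, dtype=float)
    radius = np.asarray(radius, dtype=float)
    if theta.shape != radius.shape or theta.ndim != 1:
        raise ValueError("theta and radius must be 1-D arrays of equal length")
    if theta.size < 2 or np.any(np.diff(theta) <= 0):
        raise ValueError("theta grid must be strictly increasing")
    rp = np.gradient(radius, theta)
    st = np.sin(theta)
    integrand = radius ** 2 * st ** 2 * (radius * st - rp * np.cos(theta))
    return float(np.pi * np.trapezoid(integrand, theta))


def _weighted_stats(values, weights, x):
    w = np.trapezoid(weights, x)
    return (
        float(np.exp(np.trapezoid(weights * np.log(values), x) / w)),  # geometric
        float(w / np.trapezoid(weights / values, x)),                  # harmonic (of values)
    )


def surface_average_tension(sol: ShapeSolution) -> TensionSummary:
    """Surface-averaged azimuthal (overall) and axial tension of a shape.

    Averages ``k/c`` (k set to 1) over the free surface with area weights.
    Primary summary: geometric mean (see module docstring).  Alternatives:
    ``arithmetic`` (collar of one ``dtheta`` excluded at the contact line,
    where the axial integrand has an integrable-log divergence) and
    ``harmonic`` (reciprocal of the mean curvature component).
    """
    free = sol._free
    s, rho, cm, ch = free["s"], free["rho"], free["cm"], free["ch"]
    if np.any(cm <= 0) or np.any(ch <= 0):
        raise NumericalValidityError("non-positive curvature on the free surface")
    r0 = sol.params.r0
    ref = r0  # hemisphere tension k*r0 with k = 1

    geo_ov, harm_ov = _weighted_stats(1.0 / cm, rho, s)
    geo_ax, harm_ax = _weighted_stats(1.0 / ch, rho, s)

    collar = free["theta"] >= free["theta"][0] + sol.params.dtheta
    if collar.sum() > 2:
        w = np.trapezoid(rho[collar], s[collar])
        arith_ov = float(np.trapezoid((rho / cm)[collar], s[collar]) / w)
        arith_ax = float(np.trapezoid((rho / ch)[collar], s[collar]) / w)
    else:  # pragma: no cover - only for pathological grids
        arith_ov = geo_ov
        arith_ax = geo_ax

    return TensionSummary(
        strain=sol.strain,
        t_overall=geo_ov,
        t_axial=geo_ax,
        t_overall_rel=geo_ov / ref,
        t_axial_rel=geo_ax / ref,
        alternatives={
            "arithmetic": (arith_ov / ref, arith_ax / ref),
            "harmonic": (harm_ov / ref, harm_ax / ref),
        },
    )


def tension_vs_strain(r0, strains, params: GeometryParams | None = None):
    """Tension summaries along a sweep of compressive strains.

    Parameters
    ----------
    r0 : float
        Uncompressed hemisphere radius (um).
    strains : sequence of float
        Compressive strains in ``[0, 1)``, sorted ascending.
    params : GeometryParams, optional
        Template for ``dtheta`` / ``volume_tol`` (its ``height`` is ignored).

    Returns
    -------
    list of (TensionSummary | ConvergenceError)
        One entry per strain; a failed point carries its error instead of
        aborting the sweep.
    """
    strains = list(strains)
    if any(not 0 <= e < 1 for e in strains):
        raise ValueError("strains must lie in [0, 1)")
    if any(b < a for a, b in zip(strains, strains[1:])):
        raise ValueError("strains must be sorted ascending")
    dtheta = params.dtheta if params is not None else DEFAULT_DTHETA
    vtol = params.volume_tol if params is not None else 0.01
    out = []
    for eps in strains:
        p = GeometryParams(r0=r0, height=r0 * (1 - eps), dtheta=dtheta, volume_tol=vtol)
        try:
            out.append(surface_average_tension(solve_compressed_shape(p)))
        except ConvergenceError as err:
            out.append(err)
    return out
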