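"""Small-indentation AFM model: universal force curve and pressure fitting.

A spread cell is modelled, as in the shape module, as a hemispherical cap of
spreading radius ``r0`` at uniform cortical tension ``T`` and excess pressure
``dP`` (Laplace: ``T = dP r0 / 2``).  A cantilever indents the apex by a
depth ``H <= 0.10 r0`` (small-strain regime).  The indented surface is
expanded in a four-term Fourier series of the polar angle,

    R(theta) = r0 + a1 cos(theta) + a2 cos(2 theta)
                  + b1 sin(theta) + b2 sin(2 theta),

with the adhesion condition ``R(pi/2) = r0`` (eliminates ``b1 = a2``) and the
indented-apex condition ``R(0) = r0 - H`` (eliminates ``a1 = -H - a2``).
Volume conservation is enforced through a Lagrange multiplier density
``lam``; on the free surface the force balance reads

    dP / (c1 + c2) - T - lam * 2 R^2 sin(theta) = 0,

where ``2 pi R^2 sin(theta)`` is the functional derivative of the enclosed
volume with respect to ``R`` (the spreading-radius scale of ``dA/dR`` is
absorbed into ``lam``).  The remaining coefficients are fixed by solving the
volume constraint exactly for ``a2`` and choosing ``b2`` to make ``lam``
as uniform as possible (least-squares form of ``d lam / d theta = 0``).

The cantilever feedback force per unit contact area is

    F = (dP + lam V / A) - T (c1 + c2) |_contact,

evaluated at the edge of the contact patch near the apex.  Writing
``P' = dP + lam V / A`` makes ``F / P'`` a universal function of the
indentation strain ``H / r0``: every measured strain-stress curve should
collapse onto it after dividing the stress by the cell's ``P'``.  Fitting
that single scaling constant to a measured curve therefore estimates ``P'``
and, through the cell length scale ``L ~ r0``, the overall cortical tension
``T_overall ~ P' L``.

All solves are carried out in units of ``r0`` (the problem is exactly scale
invariant), with ``dP = 1``; fitted pressures are in the units of the
supplied stresses (Pa for real data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import NicheMechError

__all__ = [
    "IndentationGeometry",
    "TheoreticalForceCurve",
    "PressureFit",
    "IndentationCurve",
    "solve_indented_shape",
    "theoretical_force_curve",
    "fit_pressure_scale",
]

MAX_STRAIN = 0.10
#: polar angle of the contact-patch edge used to evaluate the feedback force;
#: ~ sqrt(1 um^2 / pi) on a typical ~8 um cell (the nominal cantilever-cell
#: contact area is 1 um^2)
DEFAULT_CONTACT_ANGLE = 0.07
#: lower edge of the window on which d lam / d theta = 0 is imposed (keeps
#: clear of the contact patch)
DEFAULT_FIT_WINDOW = 0.2

_THETA_VOL = np.linspace(1e-5, np.pi / 2, 801)
_NFIT = 200


@dataclass(frozen=True)
class IndentationGeometry:
    """Solved indented cap: Fourier coefficients and volume multiplier."""

    r0: float
    depth: float
    a1: float
    a2: float
    b1: float
    b2: float
    lam: float            # volume Lagrange multiplier density (dP = 1 units)
    lam_spread: float     # residual nonuniformity of lam (std over the window)
    apical_area: float    # free-surface area, um^2
    volume: float         # enclosed volume, um^3

    @property
    def strain(self) -> float:
        return self.depth / self.r0

    def profile(self, theta):
        """Radius, first and second theta-derivative of the indented surface."""
        t = np.asarray(theta, dtype=float)
        c, s = np.cos(t), np.sin(t)
        c2t, s2t = np.cos(2 * t), np.sin(2 * t)
        r = self.r0 + self.a1 * c + self.a2 * c2t + self.b1 * s + self.b2 * s2t
        rp = -self.a1 * s - 2 * self.a2 * s2t + self.b1 * c + 2 * self.b2 * c2t
        rpp = -self.a1 * c - 4 * self.a2 * c2t - self.b1 * s - 4 * self.b2 * s2t
        return r, rp, rpp


@dataclass(frozen=True)
class TheoreticalForceCurve:
    """Universal indentation-strain versus ``F/P'`` curve."""

    strain: np.ndarray
    f_over_p: np.ndarray


@dataclass(frozen=True)
class PressureFit:
    """Fitted effective pressure of one measured indentation curve."""

    p_prime: float        # P' = dP + lam V / A, in stress units of the input
    residual: float       # RMS fitting residual, same units
    t_overall_est: float  # P' * L
    length_scale: float   # L (defaults to r0), um


@dataclass(frozen=True)
class IndentationCurve:
    """A measured (or simulated) indentation strain-stress curve."""

    strain: np.ndarray
    stress: np.ndarray
    cell_id: str = ""

    def __post_init__(self):
        s = np.asarray(self.strain, dtype=float)
        if s.ndim != 1 or s.shape != np.shape(self.stress):
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if np.any(np.diff(s) <= 0):
            raise ValueError("strains must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.strain)


def _curvature_sum(t, r, rp, rpp):
    c1 = (2 * rp ** 2 + r ** 2 - r * rpp) / (r ** 2 + rp ** 2) ** 1.5
    c2 = (1 - (rp / r) / np.tan(t)) / np.sqrt(r ** 2 + rp ** 2)
    return c1 + c2


def _profile_n(t, strain, a2, b2):
    """Normalised (r0=1) indented profile for free coefficients (a2, b2)."""
    a1 = -strain - a2
    b1 = a2
    c, s = np.cos(t), np.sin(t)
    c2t, s2t = np.cos(2 * t), np.sin(2 * t)
    r = 1.0 + a1 * c + a2 * c2t + b1 * s + b2 * s2t
    rp = -a1 * s - 2 * a2 * s2t + b1 * c + 2 * b2 * c2t
    rpp = -a1 * c - 4 * a2 * c2t - b1 * s - 4 * b2 * s2t
    return r, rp, rpp


def _volume_n(strain, a2, b2):
    t = _THETA_VOL
    r, rp, _ = _profile_n(t, strain, a2, b2)
    st = np.sin(t)
    return np.pi * np.trapezoid(r ** 2 * st ** 2 * (r * st - rp * np.cos(t)), t)


def _area_n(strain, a2, b2):
    t = _THETA_VOL
    r, rp, _ = _profile_n(t, strain, a2, b2)
    return 2 * np.pi * np.trapezoid(r * np.sin(t) * np.sqrt(r ** 2 + rp ** 2), t)


def _a2_from_volume(strain, b2):
    v0 = 2 / 3 * np.pi
    f = lambda a2: _volume_n(strain, a2, b2) - v0
    grid = np.linspace(-0.5, 0.5, 51)
    vals = np.array([f(a) for a in grid])
    sign = np.where(vals[:-1] * vals[1:] < 0)[0]
    if not sign.size:
        raise NicheMechError("volume constraint has no root for these coefficients")
    i = sign[np.argmin(np.abs(grid[sign]))]
    return brentq(f, grid[i], grid[i + 1], xtol=1e-14)


def _lambda_profile(strain, a2, b2, fit_window):
    t = np.linspace(fit_window, np.pi / 2 - 1e-6, _NFIT)
    r, rp, rpp = _profile_n(t, strain, a2, b2)
    csum = _curvature_sum(t, r, rp, rpp)
    tension = 0.5  # dP * r0 / 2 with dP = r0 = 1
    return (1.0 / csum - tension) / (2 * r ** 2 * np.sin(t))


def _solve_normalized(strain, fit_window=DEFAULT_FIT_WINDOW):
    """Free coefficients (a2, b2) and lambda, in units of r0 with dP = 1."""
    if strain == 0.0:
        return 0.0, 0.0, 0.0, 0.0

    def objective(b2):
        try:
            a2 = _a2_from_volume(strain, b2)
        except NicheMechError:
            return np.inf
        return float(np.var(_lambda_profile(strain, a2, b2, fit_window)))

    bmax = max(2.0 * strain, 1e-3)
    # coarse bracketing then Brent: the landscape is smooth and unimodal
    grid = np.linspace(-bmax, bmax, 21)
    vals = np.array([objective(b) for b in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    b2 = float(res.x)
    a2 = _a2_from_volume(strain, b2)
    lam = _lambda_profile(strain, a2, b2, fit_window)
    return a2, b2, float(lam.mean()), float(lam.std())


def solve_indented_shape(r0: float, depth: float,
                         fit_window: float = DEFAULT_FIT_WINDOW) -> IndentationGeometry:
    """Solve the indented cap for one indentation depth.

    Raises ``ValueError`` outside the small-strain regime
    (``0 <= depth <= 0.10 r0``).
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if not 0 <= depth <= MAX_STRAIN * r0 + 1e-12:
        raise ValueError(
            f"indentation depth {depth} outside small-strain regime (<= {MAX_STRAIN} r0)"
        )
    strain = depth / r0
    a2, b2, lam, lam_sd = _solve_normalized(strain, fit_window)
    vol = _volume_n(strain, a2, b2) * r0 ** 3
    area = _area_n(strain, a2, b2) * r0 ** 2
    return IndentationGeometry(
        r0=r0,
        depth=depth,
        a1=(-strain - a2) * r0,
        a2=a2 * r0,
        b1=a2 * r0,
        b2=b2 * r0,
        lam=lam / r0,           # dP=1 units: lam scales as 1/length
        lam_spread=lam_sd / r0,
        apical_area=area,
        volume=vol,
    )


def _f_over_p_normalized(strain, contact_angle, fit_window):
    if strain == 0.0:
        return 0.0
    a2, b2, lam, _ = _solve_normalized(strain, fit_window)
    v = _volume_n(strain, a2, b2)
    a = _area_n(strain, a2, b2)
    t = np.array([contact_angle])
    r, rp, rpp = _profile_n(t, strain, a2, b2)
    csum = _curvature_sum(t, r, rp, rpp)[0]
    p_prime = 1.0 + lam * v / a
    force = p_prime - 0.5 * csum  # T (c1+c2) with T = 1/2
    return force / p_prime


@lru_cache(maxsize=32)
def _curve_cached(strain_max, n_points, contact_angle, fit_window):
    strains = np.linspace(0.0, strain_max, n_points)
    f = np.array([_f_over_p_normalized(s, contact_angle, fit_window) for s in strains])
    return strains, f


def theoretical_force_curve(strain_max: float = MAX_STRAIN, n_points: int = 50,
                            contact_angle: float = DEFAULT_CONTACT_ANGLE,
                            fit_window: float = DEFAULT_FIT_WINDOW) -> TheoreticalForceCurve:
    """Universal strain versus ``F/P'`` curve on ``[0, strain_max]``.

    The curve starts at 0 (Laplace equilibrium of the un-indented cap) and is
    non-decreasing over the small-strain regime.  It is independent of both
    ``r0`` and the actual pressure: those enter only as scale factors of a
    measured curve.
    """
    if not 0 < strain_max <= MAX_STRAIN + 1e-12:
        raise ValueError(f"strain_max must lie in (0, {MAX_STRAIN}]")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    strains, f = _curve_cached(float(strain_max), int(n_points),
                               float(contact_angle), float(fit_window))
    return TheoreticalForceCurve(strain=strains.copy(), f_over_p=f.copy())


def fit_pressure_scale(curve: IndentationCurve, r0: float,
                       theory: TheoreticalForceCurve | None = None,
                       length_scale: float | None = None) -> PressureFit:
    """Least-squares scaling of the universal curve onto a measured one.

    ``p_prime`` is the scalar minimising ``sum (stress - p * f(strain))^2``;
    the overall-tension estimate is ``p_prime * L`` with ``L = r0`` unless
    overridden.  All measured strains must lie in the small-strain regime and
    at least 10 points are required.
    """
    strain = np.asarray(curve.strain, dtype=float)
    stress = np.asarray(curve.stress, dtype=float)
    if len(strain) < 10:
        raise ValueError("need at least 10 indentation points")
    if strain.min() < 0 or strain.max() > MAX_STRAIN + 1e-12:
        raise ValueError("measured strains outside the small-strain regime")
    if not np.any(stress):
        raise NicheMechError("all-zero stresses: degenerate fit")
    if theory is None:
        theory = theoretical_force_curve(strain_max=MAX_STRAIN, n_points=50)
    f = np.interp(strain, theory.strain, theory.f_over_p)
    denom = float(f @ f)
    if denom == 0.0:
        raise NicheMechError("theoretical curve vanishes on the measured strains")
    p = float(f @ stress) / denom
    rms = float(np.sqrt(np.mean((stress - p * f) ** 2)))
    L = r0 if length_scale is None else length_scale
    return PressureFit(p_prime=p, residual=rms, t_overall_est=p * L, length_scale=L)
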