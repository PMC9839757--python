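"""Independent oracle implementations used only by the test suite.

Each oracle reaches the quantity under test by a different route than the
package (different parametrisation, different principle), so agreement is a
genuine cross-check rather than a tautology.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2


def droplet_profile_by_area_minimization(r0, height, n=120):
    """Compressed-cell profile as a constrained area minimisation.

    The cortex area of the axisymmetric graph z(rho) is minimised subject to
    the enclosed volume (shell integral) matching the uncompressed
    hemisphere and to the plate obstacle 0 <= z <= height.  This is the
    variational statement of the uniform-tension squeezed-droplet problem;
    the package solves the same problem by shooting on the Young-Laplace
    equations.

    Returns (rho, z) arrays of the minimising profile.
    """
    v0 = 2 / 3 * np.pi * r0 ** 3
    x = np.linspace(0.0, 1.0, n + 1)  # rho = x * rho_end

    def unpack(p):
        z = np.concatenate([p[:-1], [0.0]])
        rho_end = p[-1]
        return z, rho_end

    def area(p):
        z, rho_end = unpack(p)
        rho = x * rho_end
        dr = np.diff(rho)
        dzs = np.diff(z)
        rmid = 0.5 * (rho[1:] + rho[:-1])
        return 2 * np.pi * np.sum(rmid * np.sqrt(dr ** 2 + dzs ** 2))

    def volume(p):
        z, rho_end = unpack(p)
        rho = x * rho_end
        dr = np.diff(rho)
        rmid = 0.5 * (rho[1:] + rho[:-1])
        zmid = 0.5 * (z[1:] + z[:-1])
        return 2 * np.pi * np.sum(rmid * zmid * dr)

    # initial guess: ellipse-like cap of the right height
    rho_end0 = max(np.sqrt(r0 ** 3 / height), r0)
    z0 = height * np.sqrt(np.clip(1 - x ** 2, 0.0, 1.0))
    p0 = np.concatenate([z0[:-1], [rho_end0]])
    bounds = [(0.0, height)] * n + [(0.3 * r0, 4 * r0)]
    res = minimize(area, p0, method="SLSQP", bounds=bounds,
                   constraints=[{"type": "eq", "fun": lambda p: (volume(p) - v0) / v0}],
                   options={"maxiter": 600, "ftol": 1e-12})
    z, rho_end = unpack(res.x)
    return x * rho_end, z


def cmh_statistic_brute_force(tables):
    """Direct evaluation of the Cochran-Mantel-Haenszel sums.

    statistic = (sum_k (a_k - E_k))^2 / sum_k V_k with the standard
    hypergeometric mean and variance per stratum; p from the 1-df
    chi-square upper tail.
    """
    num = 0.0
    den = 0.0
    for t in np.asarray(tables, dtype=float):
        a = t[0, 0]
        n1, n2 = t[0].sum(), t[1].sum()
        m1, m2 = t[:, 0].sum(), t[:, 1].sum()
        T = t.sum()
        num += a - n1 * m1 / T
        den += n1 * n2 * m1 * m2 / (T ** 2 * (T - 1))
    stat = num ** 2 / den
    return stat, float(chi2.sf(stat, 1))


def afm_coefficients_grid_search(strain, n_grid=81, span=0.35):
    """Dense-grid search for the indented-cap Fourier coefficients.

    Minimises the nonuniformity of the volume multiplier with the volume
    constraint as a heavy quadratic penalty over an (a2, b2) grid, followed
    by one local refinement — an independent route to the same optimum the
    package reaches by exact volume elimination plus 1-D minimisation.
    """
    from nichemech.afm import _lambda_profile, _volume_n, DEFAULT_FIT_WINDOW

    v0 = 2 / 3 * np.pi

    def objective(a2, b2):
        lam = _lambda_profile(strain, a2, b2, DEFAULT_FIT_WINDOW)
        dv = (_volume_n(strain, a2, b2) - v0) / v0
        return np.var(lam) + 1e4 * dv ** 2

    grid = np.linspace(-span, span, n_grid)
    best = None
    for a2 in grid:
        for b2 in grid:
            val = objective(a2, b2)
            if best is None or val < best[0]:
                best = (val, a2, b2)
    _, a2, b2 = best
    res = minimize(lambda p: objective(*p), [a2, b2], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    return res.x


def hemisphere_stack_volume(radius, dz):
    """Cap-area closed form summed slice by slice (rectangle rule)."""
    centers = np.arange(dz / 2, radius, dz)
    return float(np.sum(np.pi * (radius ** 2 - centers ** 2)) * dz)
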