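"""Compiled steady-state solver for the EGF-driven MAPK cascade.

The ABC sampler evaluates tens of thousands of parameter vectors, each
needing one steady-state solve per stimulation condition.  This module
carries a numba-compiled implicit-Euler integrator with Newton polishing
for the three-species cascade, mathematically equivalent to the generic
:mod:`mrafit.steady_state` route (asserted in the test suite) but one to
two orders of magnitude faster.

Parameter vectors follow the order of
:data:`mrafit.ode_models.MAPK_EGF_PARAM_NAMES`; totals are
``(RAF_TOT, MEK_TOT, ERK_TOT)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mapk_rate", "mapk_jacobian", "mapk_steady_state", "mapk_distance_batch"]


@njit(cache=True)
def mapk_rate(x, p, tot, egf):
    """Rate vector of the EGF-driven cascade; ``p`` in canonical order."""
    kf1, Kmf1, Vm1, Km1 = p[0], p[1], p[2], p[3]
    kf2, Kmf2, Vm2, Km2 = p[4], p[5], p[6], p[7]
    kf3, Kmf3, Vm3, Km3 = p[8], p[9], p[10], p[11]
    kr1, Kmr1, kr2, Kmr2 = p[12], p[13], p[14], p[15]
    araf, amek, aerk = x[0], x[1], x[2]
    iraf = tot[0] - araf
    imek = tot[1] - amek
    ierk = tot[2] - aerk
    out = np.empty(3)
    out[0] = (kf1 * iraf * egf / (Kmf1 + iraf)
              - kr1 * araf * aerk / (Kmr1 + araf)
              - Vm1 * araf / (Km1 + araf))
    out[1] = (kf2 * imek * araf / (Kmf2 + imek)
              - kr2 * amek * aerk / (Kmr2 + amek)
              - Vm2 * amek / (Km2 + amek))
    out[2] = (kf3 * ierk * amek / (Kmf3 + ierk)
              - Vm3 * aerk / (Km3 + aerk))
    return out


@njit(cache=True)
def mapk_jacobian(x, p, tot, egf):
    """Analytic Jacobian of :func:`mapk_rate`."""
    kf1, Kmf1, Vm1, Km1 = p[0], p[1], p[2], p[3]
    kf2, Kmf2, Vm2, Km2 = p[4], p[5], p[6], p[7]
    kf3, Kmf3, Vm3, Km3 = p[8], p[9], p[10], p[11]
    kr1, Kmr1, kr2, Kmr2 = p[12], p[13], p[14], p[15]
    araf, amek, aerk = x[0], x[1], x[2]
    iraf = tot[0] - araf
    imek = tot[1] - amek
    ierk = tot[2] - aerk
    j = np.zeros((3, 3))
    j[0, 0] = (-kf1 * egf * Kmf1 / (Kmf1 + iraf) ** 2
               - kr1 * aerk * Kmr1 / (Kmr1 + araf) ** 2
               - Vm1 * Km1 / (Km1 + araf) ** 2)
    j[0, 2] = -kr1 * araf / (Kmr1 + araf)
    j[1, 0] = kf2 * imek / (Kmf2 + imek)
    j[1, 1] = (-kf2 * araf * Kmf2 / (Kmf2 + imek) ** 2
               - kr2 * aerk * Kmr2 / (Kmr2 + amek) ** 2
               - Vm2 * Km2 / (Km2 + amek) ** 2)
    j[1, 2] = -kr2 * amek / (Kmr2 + amek)
    j[2, 1] = kf3 * ierk / (Kmf3 + ierk)
    j[2, 2] = (-kf3 * amek * Kmf3 / (Kmf3 + ierk) ** 2
               - Vm3 * Km3 / (Km3 + aerk) ** 2)
    return j


@njit(cache=True)
def _newton_polish(x, p, tot, egf, tol):
    """Damped Newton on the rate equations; returns (x, residual, ok)."""
    y = x.copy()
    f = mapk_rate(y, p, tot, egf)
    res = np.max(np.abs(f))
    for _ in range(60):
        if res < tol:
            return y, res, True
        j = mapk_jacobian(y, p, tot, egf)
        step = np.linalg.solve(j, -f)
        lam = 1.0
        improved = False
        for _ in range(12):
            y_new = y + lam * step
            ok_box = True
            for i in range(3):
                if y_new[i] < -1e-9 or y_new[i] > tot[i] + 1e-9:
                    ok_box = False
            if ok_box:
                f_new = mapk_rate(y_new, p, tot, egf)
                res_new = np.max(np.abs(f_new))
                if np.isfinite(res_new) and res_new < res:
                    y, f, res = y_new, f_new, res_new
                    improved = True
                    break
            lam *= 0.5
        if not improved:
            break
    return y, res, res < tol


@njit(cache=True)
def mapk_steady_state(p, tot, egf, tol=1e-9, burn_in=300.0, max_burn_in=4800.0):
    """Integrate-then-polish steady-state search (implicit Euler burn-in).

    Adaptive implicit Euler (L-stable, safe on stiff random parameter
    draws) runs to the burn-in horizon, then damped Newton polishes the
    endpoint.  If the polished root fails the residual or box test, the
    horizon doubles up to ``max_burn_in``.  Returns ``(x, residual, ok)``.
    """
    x = np.zeros(3)
    t = 0.0
    h = 1e-3
    horizon = burn_in
    eye = np.eye(3)
    steps = 0
    max_steps = 4000  # ~10x a typical solve; pathological draws fail fast
    while horizon <= max_burn_in:
        while t < horizon:
            steps += 1
            if steps > max_steps:
                return x, np.inf, False
            # implicit Euler step: solve y - x - h f(y) = 0 by Newton
            y = x.copy()
            converged = False
            for _ in range(8):
                f = mapk_rate(y, p, tot, egf)
                g = y - x - h * f
                if np.max(np.abs(g)) < 1e-10 + 1e-8 * np.max(np.abs(y)):
                    converged = True
                    break
                a = eye - h * mapk_jacobian(y, p, tot, egf)
                dy = np.linalg.solve(a, -g)
                y = y + dy
                if not np.all(np.isfinite(y)):
                    break
            if converged and np.all(np.isfinite(y)):
                for i in range(3):
                    if y[i] < 0.0:
                        y[i] = 0.0
                    elif y[i] > tot[i]:
                        y[i] = tot[i]
                x = y
                t += h
                h = min(h * 1.7, 200.0)
            else:
                h *= 0.25
                if h < 1e-13:
                    return x, np.inf, False
        xp, res, ok = _newton_polish(x, p, tot, egf, tol)
        if ok:
            inside = True
            for i in range(3):
                if xp[i] < -1e-9 or xp[i] > tot[i] + 1e-9:
                    inside = False
            if inside:
                for i in range(3):
                    if xp[i] < 0.0:
                        xp[i] = 0.0
                    elif xp[i] > tot[i]:
                        xp[i] = tot[i]
                return xp, res, True
        horizon *= 2.0
    res = np.max(np.abs(mapk_rate(x, p, tot, egf)))
    return x, res, res < tol


@njit(cache=True)
def _stable_routh_hurwitz(j):
    """All eigenvalues of a 3x3 matrix have negative real part.

    Routh-Hurwitz on the characteristic cubic l^3 + a2 l^2 + a1 l + a0:
    stable iff a2 > 0, a0 > 0 and a2*a1 > a0.
    """
    tr = j[0, 0] + j[1, 1] + j[2, 2]
    m01 = j[0, 0] * j[1, 1] - j[0, 1] * j[1, 0]
    m02 = j[0, 0] * j[2, 2] - j[0, 2] * j[2, 0]
    m12 = j[1, 1] * j[2, 2] - j[1, 2] * j[2, 1]
    det = (j[0, 0] * (j[1, 1] * j[2, 2] - j[1, 2] * j[2, 1])
           - j[0, 1] * (j[1, 0] * j[2, 2] - j[1, 2] * j[2, 0])
           + j[0, 2] * (j[1, 0] * j[2, 1] - j[1, 1] * j[2, 0]))
    a2 = -tr
    a1 = m01 + m02 + m12
    a0 = -det
    return a2 > 0.0 and a0 > 0.0 and a2 * a1 > a0


@njit(cache=True)
def mapk_distance_batch(thetas, tot, doses, ref_idx,
                        obs_off, inv_n_r, obs_rho, inv_n_rho,
                        tol, burn_in, max_burn_in):
    """Feature distance for a batch of parameter vectors.

    For each particle: one steady-state solve per dose, scaled-Jacobian
    local response coefficients, ligand response ratios against the
    reference dose, then the normalised-Euclidean block distance against
    the observed features.  Unstable, degenerate or non-convergent
    particles score ``inf``.  ``obs_off`` is (n_doses, 6) with off-diagonal
    entries in row-major order; ``inv_n_rho[ref_idx]`` must be 0.
    """
    n = thetas.shape[0]
    nd = doses.size
    out = np.empty(n)
    states = np.empty((nd, 3))
    off = np.empty(6)
    for m in range(n):
        theta = thetas[m]
        bad = False
        for q in range(16):
            if not np.isfinite(theta[q]) or theta[q] <= 0.0:
                bad = True
        d = 0.0
        if not bad:
            for j in range(nd):
                x, _, ok = mapk_steady_state(theta, tot, doses[j], tol,
                                             burn_in, max_burn_in)
                if not ok or x[0] <= 0.0 or x[1] <= 0.0 or x[2] <= 0.0:
                    bad = True
                    break
                jac = mapk_jacobian(x, theta, tot, doses[j])
                if (jac[0, 0] == 0.0 or jac[1, 1] == 0.0 or jac[2, 2] == 0.0
                        or not _stable_routh_hurwitz(jac)):
                    bad = True
                    break
                k = 0
                for r_i in range(3):
                    for c_i in range(3):
                        if r_i != c_i:
                            off[k] = (-jac[r_i, c_i] * x[c_i]
                                      / (jac[r_i, r_i] * x[r_i]))
                            k += 1
                acc = 0.0
                for k in range(6):
                    acc += (off[k] - obs_off[j, k]) ** 2
                d += np.sqrt(acc) * inv_n_r[j]
                states[j, 0] = x[0]
                states[j, 1] = x[1]
                states[j, 2] = x[2]
        if bad:
            out[m] = np.inf
            continue
        for j in range(nd):
            if j != ref_idx:
                acc = 0.0
                for s in range(3):
                    acc += (states[j, s] / states[ref_idx, s] - obs_rho[j, s]) ** 2
                d += np.sqrt(acc) * inv_n_rho[j]
        out[m] = d
    return out
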