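"""Steady states, Jacobians and model-side local response coefficients.

The link between an ODE model and steady-state perturbation data is the
scaled Jacobian: at a stable steady state ``x*`` with Jacobian
``J = df/dx``, the local response coefficient of node ``j`` on node ``i`` is

    r_ij = -J_ij * x_j / (J_ii * x_i),    r_ii = -1.

Computing ``r`` therefore needs a single steady-state solve per condition
and no simulated perturbations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .ode_models import RateModel

__all__ = [
    "SteadyState",
    "LocalResponseMatrix",
    "find_steady_state",
    "numerical_jacobian",
    "model_lrc",
    "SteadyStateError",
    "DegenerateStateError",
]

log = logging.getLogger(__name__)


class SteadyStateError(RuntimeError):
    """Steady-state search failed to converge."""


class DegenerateStateError(ValueError):
    """Steady state cannot yield LRCs (zero concentration or zero diagonal)."""


@dataclass
class SteadyState:
    """A steady state with its residual and convergence/stability flags."""

    state: np.ndarray
    residual_norm: float
    converged: bool
    stable: bool = True

    def __iter__(self):
        return iter(self.state)


@dataclass
class LocalResponseMatrix:
    """N x N matrix of local response coefficients; diagonal fixed at -1."""

    r: np.ndarray
    condition: str = ""
    species: tuple = ()

    def offdiagonal(self) -> np.ndarray:
        """Off-diagonal entries flattened row-major (the informative part)."""
        n = self.r.shape[0]
        return self.r[~np.eye(n, dtype=bool)]


def numerical_jacobian(model: RateModel, x: np.ndarray, t: float = 0.0) -> np.ndarray:
    """Central finite-difference Jacobian ``J_ij = df_i/dx_j``.

    Step per column: ``h_j = max(1e-6 * |x_j|, 1e-8)``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("state must be finite")
    n = x.size
    jac = np.empty((n, n))
    for j in range(n):
        h = max(1e-6 * abs(x[j]), 1e-8)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        fp, fm = model.rate(xp, t), model.rate(xm, t)
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            bad = model.species_names[j]
            raise ValueError(f"non-finite rate when probing species {bad!r}")
        jac[:, j] = (np.asarray(fp) - np.asarray(fm)) / (2 * h)
    return jac


def _jacobian(model: RateModel, x: np.ndarray, t: float = 0.0) -> np.ndarray:
    if model.jacobian is not None:
        return np.asarray(model.jacobian(x, t))
    return numerical_jacobian(model, x, t)


def find_steady_state(
    model: RateModel,
    x0: np.ndarray | None = None,
    tol: float = 1e-9,
    burn_in: float = 500.0,
    max_burn_in: float = 64000.0,
    check_stability: bool = True,
) -> SteadyState:
    """Find a stable steady state by integrate-then-polish.

    The ODE is integrated from ``x0`` (default: the starved all-zero state)
    for a burn-in horizon, then the endpoint is polished with a Newton-type
    root solver.  Integrating first keeps the search on the attractor
    actually reached from ``x0`` and away from unstable fixed points.  If
    the polished root drifts out of the physical box or fails the residual
    test, the burn-in horizon is doubled (up to ``max_burn_in``) and the
    search repeated.

    Returns a :class:`SteadyState`; ``converged`` is False rather than an
    exception being raised, so samplers can treat failures as rejections.
    """
    if not model.autonomous:
        raise SteadyStateError("model is non-autonomous; no steady state exists")
    n = model.n_species
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    if np.any(x0 < -1e-12) or np.any(x0 > model.totals + 1e-12):
        raise ValueError("initial state must lie within [0, totals]")

    dfun = (lambda y, t: model.jacobian(y, t)) if model.jacobian is not None else None

    horizon = burn_in
    x_end = x0
    while horizon <= max_burn_in:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.ODEintWarning)
            try:
                traj, info = integrate.odeint(
                    model.rate, x_end, (0.0, horizon), Dfun=dfun,
                    rtol=1e-7, atol=1e-9, mxstep=10000, full_output=True)
            except Exception:
                return SteadyState(np.full(n, np.nan), np.inf, converged=False, stable=False)
        if info["message"] != "Integration successful." or not np.all(np.isfinite(traj[-1])):
            return SteadyState(np.full(n, np.nan), np.inf, converged=False, stable=False)
        x_end = np.clip(traj[-1], 0.0, model.totals)

        polished = _polish(model, x_end)
        if polished is not None:
            resid = float(np.max(np.abs(model.rate(polished, 0.0))))
            in_box = np.all(polished >= -1e-9) and np.all(polished <= model.totals + 1e-9)
            if resid < tol and in_box:
                polished = np.clip(polished, 0.0, model.totals)
                stable = True
                if check_stability:
                    eigs = np.linalg.eigvals(_jacobian(model, polished))
                    stable = bool(np.all(eigs.real < 0))
                    if not stable:
                        warnings.warn(
                            "steady state has non-negative Jacobian eigenvalues "
                            "(marginal or unstable fixed point)", RuntimeWarning)
                return SteadyState(polished, resid, converged=True, stable=stable)
        horizon *= 2.0
    resid = float(np.max(np.abs(model.rate(x_end, 0.0))))
    return SteadyState(x_end, resid, converged=resid < tol, stable=False)


def _polish(model: RateModel, x: np.ndarray) -> np.ndarray | None:
    f = lambda y: model.rate(y, 0.0)
    jac = (lambda y: model.jacobian(y, 0.0)) if model.jacobian is not None else None
    try:
        sol = optimize.root(f, x, jac=jac, method="hybr", options={"xtol": 1e-12})
    except Exception:
        return None
    return sol.x if sol.success else None


def model_lrc(model: RateModel, ss: SteadyState, condition: str = "") -> LocalResponseMatrix:
    """Local response coefficients from the steady-state Jacobian.

    ``r_ij = -J_ij x_j / (J_ii x_i)`` with the diagonal set to -1 exactly.
    Requires a converged steady state with strictly positive concentrations
    and nonzero Jacobian diagonal; degenerate states are rejected.
    """
    if not ss.converged:
        raise DegenerateStateError("steady state did not converge")
    x = np.asarray(ss.state, dtype=float)
    if np.any(x <= 0):
        bad = [s for s, xi in zip(model.species_names, x) if xi <= 0]
        raise DegenerateStateError(f"zero steady-state concentration for {bad}")
    jac = _jacobian(model, x)
    diag = np.diag(jac)
    if np.any(diag == 0):
        raise DegenerateStateError("zero diagonal Jacobian entry; LRCs undefined")
    r = -jac * x[np.newaxis, :] / (diag[:, np.newaxis] * x[:, np.newaxis])
    np.fill_diagonal(r, -1.0)
    return LocalResponseMatrix(r=r, condition=condition, species=tuple(model.species_names))
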