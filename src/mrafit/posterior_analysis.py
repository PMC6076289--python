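"""Posterior-predictive simulation and scoring.

Every sampled parameter vector defines one model; the weighted ensemble is
summarised feature-wise (mean, standard error) or pooled.  In the pooled
single-cell reading, each particle is one cell, so the spread of a readout
across the ensemble is a cell-population distribution — no extra noise is
injected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import integrate, optimize, stats

from . import steady_state
from .abc_smc import ParticleEnsemble
from .objective import ResponseSet
from .ode_models import RateModel

__all__ = [
    "PosteriorPrediction",
    "predict_features",
    "ssq_fit_error",
    "ssq_experiment",
    "dose_response",
    "washout_timecourse",
    "modality_analysis",
    "fit_sigmoid",
]

log = logging.getLogger(__name__)

#: Ensemble percentiles bounding a 67% interval.
CI67 = (16.5, 83.5)


@dataclass
class PosteriorPrediction:
    """Weighted ensemble summaries of response features.

    ``lrc_mean``/``lrc_se`` map condition labels to N x N arrays (diagonals
    -1 with zero spread); ``ratio_mean``/``ratio_se`` map conditions to
    per-species vectors.  ``n_failed`` counts particles whose model could
    not be evaluated (excluded from the averages).
    """

    lrc_mean: dict = field(default_factory=dict)
    lrc_se: dict = field(default_factory=dict)
    ratio_mean: dict = field(default_factory=dict)
    ratio_se: dict = field(default_factory=dict)
    species: tuple = ()
    n_used: int = 0
    n_failed: int = 0

    def as_response_set(self) -> ResponseSet:
        return ResponseSet(lrc=self.lrc_mean, ratios=self.ratio_mean)


def _weighted_mean_se(values: np.ndarray, weights: np.ndarray):
    """Weighted mean and its standard error (weighted sd over sqrt(ESS))."""
    w = weights / weights.sum()
    mean = np.tensordot(w, values, axes=1)
    var = np.tensordot(w, (values - mean) ** 2, axes=1)
    ess = 1.0 / np.sum(w**2)
    return mean, np.sqrt(var / ess)


def predict_features(
    ensemble: ParticleEnsemble,
    model_builder: Callable[[np.ndarray, float], RateModel],
    conditions: Sequence[tuple[str, float]],
    reference: str | None = None,
    weighted: bool = True,
) -> PosteriorPrediction:
    """Per-particle LRCs and ligand ratios, summarised across the ensemble.

    ``conditions`` is a sequence of ``(label, dose)`` pairs; ratios are
    taken against ``reference`` (default: the first condition).  Particles
    failing steady-state evaluation at any condition are excluded, with the
    count reported.  With ``weighted=False`` the final population is
    averaged plainly — the ensemble-of-models reading in which every
    sampled parameter set counts once — which is far more stable when the
    importance weights are degenerate.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    conditions = list(conditions)
    if not conditions:
        raise ValueError("at least one condition is required")
    if not weighted:
        ensemble = ParticleEnsemble(
            ensemble.stage, ensemble.particles,
            np.full(len(ensemble), 1.0 / len(ensemble)),
            ensemble.distances, ensemble.epsilon, ensemble.names)
    reference = reference or conditions[0][0]
    labels = [label for label, _ in conditions]
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among conditions {labels}")

    lrc_samples = {label: [] for label in labels}
    level_samples = {label: [] for label in labels}
    ok_weights = []
    n_failed = 0
    species: tuple = ()
    for theta, w in zip(ensemble.particles, ensemble.weights):
        per_cond = {}
        try:
            for label, dose in conditions:
                model = model_builder(theta, dose)
                ss = steady_state.find_steady_state(model)
                if not ss.converged:
                    raise steady_state.SteadyStateError(label)
                per_cond[label] = (steady_state.model_lrc(model, ss).r, ss.state)
                species = tuple(model.species_names)
        except (steady_state.SteadyStateError, steady_state.DegenerateStateError, ValueError):
            n_failed += 1
            continue
        for label, (r, x) in per_cond.items():
            lrc_samples[label].append(r)
            level_samples[label].append(x)
        ok_weights.append(w)
    if not ok_weights:
        raise RuntimeError("every particle failed steady-state evaluation")
    if n_failed:
        log.info("predict_features: %d/%d particles excluded", n_failed, len(ensemble))

    w = np.asarray(ok_weights)
    pred = PosteriorPrediction(species=species, n_used=len(w), n_failed=n_failed)
    ref_levels = np.asarray(level_samples[reference])
    for label in labels:
        r = np.asarray(lrc_samples[label])
        mean, se = _weighted_mean_se(r, w)
        np.fill_diagonal(mean, -1.0)
        np.fill_diagonal(se, 0.0)
        pred.lrc_mean[label], pred.lrc_se[label] = mean, se
        if label != reference:
            rho = np.asarray(level_samples[label]) / ref_levels
            pred.ratio_mean[label], pred.ratio_se[label] = _weighted_mean_se(rho, w)
    return pred


def ssq_fit_error(observed: ResponseSet, predicted: ResponseSet) -> float:
    """Sum of squared differences over off-diagonal LRCs and ligand ratios."""
    obs = observed.feature_vector()
    try:
        sim_parts = [predicted.lrc_array(c) for c in sorted(observed.lrc)]
        sim_rho = [np.asarray(predicted.ratios[c], dtype=float)
                   for c in sorted(observed.ratios)]
    except KeyError as exc:
        raise ValueError(f"predicted set is missing condition {exc}") from None
    off = [r[~np.eye(r.shape[0], dtype=bool)] for r in sim_parts]
    sim = np.concatenate(off + sim_rho) if (off or sim_rho) else np.empty(0)
    if sim.shape != obs.shape:
        raise ValueError(f"feature shape mismatch: {sim.shape} vs {obs.shape}")
    return float(np.sum((obs - sim) ** 2))


def ssq_experiment(
    dataset,
    seed: int,
    prior_median: float = 2.3,
    totals=None,
    **fit_kwargs,
) -> tuple[float, "object"]:
    """Fit the cascade to a dataset and score the posterior-mean fit error.

    Runs the full protocol (data features -> adaptive-weight ABC-SMC ->
    posterior-predictive features) and returns ``(ssq, smc_result)`` where
    ``ssq`` is the sum of squared differences between the data-derived
    features and the ensemble-average predicted features.  This is the
    prior-robustness experiment: rerun with different ``prior_median``
    values and compare the fit errors.
    """
    from . import abc_smc
    from .ode_models import MAPK_EGF_PARAM_NAMES, build_mapk_egf_model

    prior = abc_smc.PriorSpec(MAPK_EGF_PARAM_NAMES, medians=prior_median)
    result, observed = abc_smc.fit_mapk_sspr(dataset, seed, prior=prior,
                                             totals=totals, **fit_kwargs)

    def builder(theta, dose):
        return build_mapk_egf_model(dict(zip(MAPK_EGF_PARAM_NAMES, theta)),
                                    totals, egf=dose)

    conditions = [(lab, float(lab.split("_")[1])) for lab in sorted(observed.lrc)]
    conditions.sort(key=lambda c: c[1])
    pred = predict_features(result.ensemble, builder, conditions, weighted=False)
    return ssq_fit_error(observed, pred.as_response_set()), result


def _readout_at_time(model: RateModel, t: float, x0: np.ndarray) -> np.ndarray:
    fun = lambda tt, y: model.rate(y, tt)
    sol = integrate.solve_ivp(fun, (0.0, t), x0, method="LSODA",
                              rtol=1e-8, atol=1e-10, t_eval=(t,))
    if not sol.success:
        raise steady_state.SteadyStateError("time-course integration failed")
    return sol.y[:, -1]


def dose_response(
    ensemble: ParticleEnsemble,
    model_builder: Callable[[np.ndarray, float], RateModel],
    doses: Sequence[float],
    readout_species: str = "aERK",
    readout_time: float | None = None,
    percentiles: tuple[float, float] = CI67,
):
    """Ensemble dose-response curve of one readout species.

    For each dose and particle, the readout is the steady-state level
    (``readout_time is None``) or the level at ``readout_time`` after
    stimulation from the starved state.  Returns a DataFrame with the
    weighted mean, standard error and ensemble percentile band per dose,
    plus the matrix of per-particle readouts.
    """
    import pandas as pd

    if any(d < 0 for d in doses):
        raise ValueError("doses must be nonnegative")
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    readouts = np.full((len(ensemble), len(doses)), np.nan)
    for i, theta in enumerate(ensemble.particles):
        for j, dose in enumerate(doses):
            try:
                model = model_builder(theta, dose)
                idx = model.species_index(readout_species)
                x0 = np.zeros(model.n_species)
                if readout_time is None:
                    ss = steady_state.find_steady_state(model, x0)
                    if not ss.converged:
                        continue
                    readouts[i, j] = ss.state[idx]
                else:
                    readouts[i, j] = _readout_at_time(model, readout_time, x0)[idx]
            except (steady_state.SteadyStateError, ValueError):
                continue
    ok = ~np.any(np.isnan(readouts), axis=1)
    if not ok.any():
        raise RuntimeError("every particle failed dose-response evaluation")
    vals, w = readouts[ok], ensemble.weights[ok]
    mean, se = _weighted_mean_se(vals, w)
    lo, hi = np.percentile(vals, percentiles, axis=0)
    frame = pd.DataFrame({"dose": list(doses), "mean": mean, "se": se,
                          "lo": lo, "hi": hi})
    return frame, vals


def washout_timecourse(
    ensemble: ParticleEnsemble,
    model_builder: Callable[[np.ndarray, float], RateModel],
    dose: float,
    neutralize_at: float,
    t_grid: Sequence[float],
    readout_species: str = "aERK",
):
    """Ligand wash-out: stimulate, then force the ligand to zero.

    The model runs with the full dose until ``neutralize_at`` (antibody
    neutralisation of the growth factor), after which the same particle's
    zero-dose model continues from the reached state, keeping the
    trajectory continuous at the switch.  Returns ``(t_grid, mean, se)`` of
    the readout across the ensemble.
    """
    if neutralize_at < 0:
        raise ValueError("neutralize_at must be nonnegative")
    t_grid = np.asarray(t_grid, dtype=float)
    curves = np.full((len(ensemble), t_grid.size), np.nan)
    for i, theta in enumerate(ensemble.particles):
        try:
            on = model_builder(theta, dose)
            off = model_builder(theta, 0.0)
            idx = on.species_index(readout_species)
            curves[i] = _piecewise_course(on, off, neutralize_at, t_grid)[:, idx]
        except (steady_state.SteadyStateError, ValueError):
            continue
    ok = ~np.any(np.isnan(curves), axis=1)
    if not ok.any():
        raise RuntimeError("every particle failed wash-out evaluation")
    mean, se = _weighted_mean_se(curves[ok], ensemble.weights[ok])
    return t_grid, mean, se


def _piecewise_course(on: RateModel, off: RateModel, t_switch, t_grid) -> np.ndarray:
    x0 = np.zeros(on.n_species)
    out = np.empty((t_grid.size, on.n_species))
    pre = t_grid[t_grid <= t_switch]
    post = t_grid[t_grid > t_switch]
    state = x0
    if t_switch > 0:
        eval_pts = np.unique(np.append(pre, t_switch))
        sol = integrate.solve_ivp(lambda t, y: on.rate(y, t), (0.0, t_switch), x0,
                                  method="LSODA", rtol=1e-8, atol=1e-10, t_eval=eval_pts)
        if not sol.success:
            raise steady_state.SteadyStateError("pre-washout integration failed")
        for t in pre:
            out[np.searchsorted(t_grid, t)] = sol.y[:, np.searchsorted(sol.t, t)]
        state = sol.y[:, -1]
    else:
        if pre.size:
            out[: pre.size] = x0
    if post.size:
        sol = integrate.solve_ivp(lambda t, y: off.rate(y, t), (t_switch, post[-1]), state,
                                  method="LSODA", rtol=1e-8, atol=1e-10, t_eval=post)
        if not sol.success:
            raise steady_state.SteadyStateError("post-washout integration failed")
        out[t_grid.size - post.size:] = sol.y.T
    return out


def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def modality_analysis(
    readouts: np.ndarray,
    min_readouts: int = 50,
    grid_size: int = 512,
) -> dict:
    """Is an ensemble readout distribution unimodal or bimodal?

    A Gaussian kernel density estimate (Silverman bandwidth) of the pooled
    readouts is fitted, by least squares on the density curve, with a one-
    and a two-component Gaussian mixture; the component count with the
    smaller fitting SSQ is selected.  The reported number of modes is the
    number of local maxima of the selected mixture density, so two heavily
    overlapping components still count as one mode.

    Returns a dict with ``n_modes``, ``modes`` (locations), ``components``
    (weight, mean, sd per component), ``ssq`` for both fits, and the KDE
    grid/density.
    """
    x = np.asarray(readouts, dtype=float).ravel()
    if x.size < min_readouts:
        raise ValueError(f"need at least {min_readouts} readouts, got {x.size}")
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise ValueError("degenerate readouts: zero variance, density undefined")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    pad = 3 * x.std()
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    density = kde(grid)

    mu, sd = x.mean(), x.std()

    def fit_k(k: int):
        if k == 1:
            def resid(p):
                return _gauss(grid, p[0], abs(p[1]) + 1e-12) - density
            p0 = [mu, sd]
        else:
            lo, hi = np.percentile(x, [25, 75])
            def resid(p):
                w = 1.0 / (1.0 + np.exp(-p[0]))  # logistic keeps weights in (0, 1)
                return (w * _gauss(grid, p[1], abs(p[2]) + 1e-12)
                        + (1 - w) * _gauss(grid, p[3], abs(p[4]) + 1e-12) - density)
            p0 = [0.0, lo, sd / 2, hi, sd / 2]
        sol = optimize.least_squares(resid, p0, max_nfev=2000)
        return sol

    fits = {k: fit_k(k) for k in (1, 2)}
    ssq = {k: float(np.sum(fits[k].fun**2)) for k in (1, 2)}
    best = 1 if ssq[1] <= ssq[2] else 2
    p = fits[best].x
    if best == 1:
        components = [(1.0, p[0], abs(p[1]))]
    else:
        w = 1.0 / (1.0 + np.exp(-p[0]))
        components = [(w, p[1], abs(p[2])), (1 - w, p[3], abs(p[4]))]
    mix = sum(wk * _gauss(grid, mk, sk) for wk, mk, sk in components)
    interior = (mix[1:-1] > mix[:-2]) & (mix[1:-1] >= mix[2:])
    modes = grid[1:-1][interior]
    return {
        "n_modes": int(min(len(modes), 2)) or 1,
        "modes": modes.tolist(),
        "components": components,
        "ssq": ssq,
        "selected_components": best,
        "grid": grid,
        "density": density,
    }


def fit_sigmoid(doses: np.ndarray, response: np.ndarray):
    """Four-parameter logistic fit of a dose-response curve.

    ``y = bottom + (top - bottom) / (1 + (ec50 / dose)^hill)`` fitted by
    least squares on the raw scale.  Returns ``(params, ssq)`` with params
    ``(bottom, top, log_ec50, hill)``.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("sigmoid fit requires positive doses")
    ld = np.log(doses)

    def model(p):
        bottom, top, log_ec50, hill = p
        return bottom + (top - bottom) / (1.0 + np.exp(-hill * (ld - log_ec50)))

    p0 = [y.min(), y.max(), np.median(ld), 1.0]
    sol = optimize.least_squares(lambda p: model(p) - y, p0, max_nfev=5000)
    return sol.x, float(np.sum(sol.fun**2))
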