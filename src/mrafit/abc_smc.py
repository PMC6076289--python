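"""Adaptive-weight ABC sequential Monte Carlo over ODE model parameters.

Likelihood-free posterior sampling: particles are drawn from the prior,
scored by a distance between data-derived and model-derived response
features, and filtered through a monotonically decreasing sequence of
acceptance thresholds.  At each stage ancestors are resampled with
probability proportional to their importance weight times a Gaussian
closeness kernel of their distance, perturbed by a component-wise Gaussian
proposal in log-parameter space, and re-weighted by the standard
prior-over-mixture-proposal importance ratio.

Evaluating a particle needs one steady-state solve per stimulation
condition (the scaled-Jacobian route), never a simulated perturbation, which
is what makes the sampler affordable on perturbation-rich datasets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from . import mra, steady_state
from .objective import ResponseSet, overall_distance
from .ode_models import MAPK_EGF_PARAM_NAMES, build_mapk_egf_model

__all__ = [
    "PriorSpec",
    "GaussianPrior",
    "ParticleEnsemble",
    "SMCSettings",
    "SMCResult",
    "sample_prior",
    "initial_stage",
    "smc_stage",
    "epsilon_schedule",
    "run_abc_smc",
    "make_mapk_lrc_evaluator",
    "observed_responses",
    "fit_mapk_sspr",
    "AcceptanceStallError",
    "ScheduleExhaustedError",
]

log = logging.getLogger(__name__)


class AcceptanceStallError(RuntimeError):
    """The acceptance rate fell below the configured floor."""


class ScheduleExhaustedError(RuntimeError):
    """Accepted distances are degenerate; no smaller threshold exists."""


class PriorSpec:
    """Independent log-normal priors over named positive parameters.

    Each parameter has a natural-scale median ``m`` and a log-scale standard
    deviation ``s``: ``log(theta) ~ Normal(log m, s^2)``.  With
    ``log_scale_location=True`` the stated location is used directly on the
    log scale instead (``log(theta) ~ Normal(m, s^2)``).

    Proposals operate in the latent (log) space, which preserves positivity.
    """

    def __init__(
        self,
        names: Sequence[str],
        medians: float | Sequence[float] | Mapping[str, float] = 2.3,
        log_sds: float | Sequence[float] | Mapping[str, float] = 2.0,
        log_scale_location: bool = False,
    ):
        self.names = list(names)
        p = len(self.names)
        self.medians = _broadcast(medians, self.names, "median")
        self.log_sds = _broadcast(log_sds, self.names, "log sd")
        if np.any(self.medians <= 0):
            raise ValueError("prior medians must be strictly positive")
        if np.any(self.log_sds <= 0):
            raise ValueError("prior log-scale sds must be strictly positive")
        self.log_scale_location = bool(log_scale_location)
        self._mu = self.medians if log_scale_location else np.log(self.medians)

    @property
    def n_parameters(self) -> int:
        return len(self.names)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(self._mu, self.log_sds, size=(n, self.n_parameters)))

    def to_latent(self, theta: np.ndarray) -> np.ndarray:
        return np.log(theta)

    def from_latent(self, z: np.ndarray) -> np.ndarray:
        return np.exp(z)

    def latent_logpdf(self, z: np.ndarray) -> np.ndarray:
        """Log prior density of the latent (log-parameter) vector(s)."""
        z = np.atleast_2d(z)
        resid = (z - self._mu) / self.log_sds
        return (-0.5 * np.sum(resid**2, axis=1)
                - np.sum(np.log(self.log_sds)) - 0.5 * z.shape[1] * np.log(2 * np.pi))


class GaussianPrior(PriorSpec):
    """Independent Gaussian priors on unconstrained parameters.

    Latent space is the parameter space itself; used for toy calibration
    problems (e.g. conjugate Gaussian checks) rather than rate constants.
    """

    def __init__(self, names, means, sds):
        self.names = list(names)
        self.medians = _broadcast(means, self.names, "mean")
        self.log_sds = _broadcast(sds, self.names, "sd")
        if np.any(self.log_sds <= 0):
            raise ValueError("prior sds must be strictly positive")
        self.log_scale_location = False
        self._mu = self.medians

    def sample(self, rng, n):
        return rng.normal(self._mu, self.log_sds, size=(n, self.n_parameters))

    def to_latent(self, theta):
        return np.asarray(theta, dtype=float)

    def from_latent(self, z):
        return np.asarray(z, dtype=float)


def _broadcast(value, names, what) -> np.ndarray:
    if isinstance(value, Mapping):
        missing = [n for n in names if n not in value]
        if missing:
            raise ValueError(f"missing prior {what} for {missing}")
        return np.array([float(value[n]) for n in names])
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(len(names), float(arr))
    if arr.shape != (len(names),):
        raise ValueError(f"prior {what} length {arr.shape} does not match {len(names)} names")
    return arr


def sample_prior(prior: PriorSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. parameter vectors from the prior, reproducibly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return prior.sample(np.random.default_rng(seed), n)


@dataclass
class ParticleEnsemble:
    """Weighted particles of one SMC stage."""

    stage: int
    particles: np.ndarray          # (n, p), natural scale
    weights: np.ndarray            # normalised, sums to 1
    distances: np.ndarray
    epsilon: float
    names: tuple = ()
    n_evaluations: int = 0

    def __post_init__(self):
        self.particles = np.atleast_2d(np.asarray(self.particles, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"weights must be normalised (sum={total})")

    def __len__(self) -> int:
        return self.particles.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return len(self) / self.n_evaluations if self.n_evaluations else float("nan")

    def effective_sample_size(self) -> float:
        return 1.0 / float(np.sum(self.weights**2))

    def weighted_mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.particles, columns=self.names or None)
        df.insert(0, "stage", self.stage)
        df.insert(1, "weight", self.weights)
        df.insert(2, "distance", self.distances)
        df.insert(3, "epsilon", self.epsilon)
        return df


@dataclass
class SMCSettings:
    """Sampler configuration.

    ``alpha`` sets the threshold schedule: the next epsilon is the alpha
    quantile of the previous stage's accepted distances.  The run stops at
    ``max_stages``, when the stage acceptance rate drops below
    ``min_acceptance``, when ``target_epsilon`` is reached, or when the
    accepted distances degenerate.
    """

    n_particles: int = 1000
    n_batch: int = 100
    alpha: float = 0.5
    max_stages: int = 10
    initial_epsilon: float = float("inf")
    initial_pool: int | None = None
    target_epsilon: float | None = None
    min_acceptance: float = 1e-3
    acceptance_floor: float = 1e-4
    max_evaluations_per_stage: int = 2_000_000
    n_jobs: int = 1


def _evaluate(evaluator, thetas: np.ndarray, n_jobs: int) -> np.ndarray:
    """Evaluate a batch of particles; result is independent of n_jobs."""
    if hasattr(evaluator, "batch") and n_jobs == 1:
        out = evaluator.batch(thetas)
    elif n_jobs == 1:
        out = [evaluator(theta) for theta in thetas]
    else:
        out = Parallel(n_jobs=n_jobs)(delayed(evaluator)(theta) for theta in thetas)
    d = np.asarray(out, dtype=float)
    d[~np.isfinite(d)] = np.inf
    return d


def initial_stage(
    prior: PriorSpec,
    evaluator: Callable[[np.ndarray], float],
    epsilon: float,
    n_particles: int,
    n_batch: int = 100,
    seed: int = 0,
    acceptance_floor: float = 1e-4,
    max_evaluations: int = 2_000_000,
    n_jobs: int = 1,
    pool: int | None = None,
) -> ParticleEnsemble:
    """Stage 1: rejection sampling from the prior at threshold ``epsilon``.

    Particles are drawn and evaluated in batches of ``n_batch``; exactly
    ``n_particles`` accepted draws (in draw order) are kept, each with
    weight ``1/n_particles``.  Results do not depend on the worker count.

    With ``pool`` set, stage 1 is instead classic quantile-threshold
    rejection sampling: ``pool`` prior draws are evaluated and the best
    ``n_particles`` kept, with the first threshold defined by the worst
    kept distance.  This buys a much lower starting threshold for a known,
    fixed evaluation budget.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rng = np.random.default_rng([seed, 1])
    if pool is not None:
        if pool < n_particles:
            raise ValueError("initial pool must be at least n_particles")
        thetas = prior.sample(rng, pool)
        d = _evaluate(evaluator, thetas, n_jobs)
        d = np.where(d < epsilon, d, np.inf)
        if np.isfinite(d).sum() < n_particles:
            raise AcceptanceStallError(
                f"initial pool of {pool} contains only {int(np.isfinite(d).sum())} "
                f"evaluable draws below epsilon={epsilon}")
        order = np.argsort(d, kind="stable")[:n_particles]
        eps1 = float(d[order[-1]]) * (1 + 1e-12)
        weights = np.full(n_particles, 1.0 / n_particles)
        return ParticleEnsemble(1, thetas[order], weights, d[order], eps1,
                                tuple(prior.names), pool)
    kept_theta, kept_d = [], []
    n_eval = 0
    while len(kept_theta) < n_particles:
        thetas = prior.sample(rng, n_batch)
        d = _evaluate(evaluator, thetas, n_jobs)
        n_eval += n_batch
        ok = np.flatnonzero(d < epsilon)
        for i in ok:
            kept_theta.append(thetas[i])
            kept_d.append(d[i])
        if n_eval >= max_evaluations:
            raise AcceptanceStallError(
                f"initial stage: {len(kept_theta)}/{n_particles} accepted "
                f"after {n_eval} evaluations")
        if n_eval >= 50 * n_batch and len(kept_theta) / n_eval < acceptance_floor:
            raise AcceptanceStallError(
                f"initial stage acceptance rate {len(kept_theta)/n_eval:.2e} "
                f"below floor {acceptance_floor:.0e} at epsilon={epsilon}")
    particles = np.array(kept_theta[:n_particles])
    distances = np.array(kept_d[:n_particles])
    weights = np.full(n_particles, 1.0 / n_particles)
    return ParticleEnsemble(1, particles, weights, distances, float(epsilon),
                            tuple(prior.names), n_eval)


# acceptance-rate band of the stage-level step-size control
_SCALE_UP_ABOVE = 0.25
_SCALE_DOWN_BELOW = 0.08


def _kc_bandwidth(prev_epsilon: float, next_epsilon: float) -> float:
    """Bandwidth of the Gaussian closeness kernel used for resampling.

    Sharpened to a small fraction of the stage's target threshold so that
    ancestors already satisfying the next threshold dominate the resampling
    (with the previous threshold as bandwidth the kernel is nearly flat
    over the accepted population and the sampler measurably stalls on
    high-dimensional kinetic posteriors).
    """
    return next_epsilon / 30.0


def _proposal_cov(prior: PriorSpec, prev: ParticleEnsemble) -> np.ndarray:
    """Global proposal covariance: twice the latent population covariance.

    Used when a caller supplies no kernel and the local-covariance scheme
    is disabled.  Computed from the accepted population without importance
    weights, which keeps the kernel well-conditioned when weights
    degenerate.
    """
    z = prior.to_latent(prev.particles)
    cov = 2.0 * np.cov(z, rowvar=False)
    cov = np.atleast_2d(cov)
    # regularise: keep the kernel from collapsing in any direction
    jitter = max(1e-4, 1e-6 * float(np.trace(cov)) / cov.shape[0])
    return cov + jitter * np.eye(cov.shape[0])


class _GaussianKernel:
    """Shared multivariate Gaussian perturbation kernel (one covariance)."""

    def __init__(self, cov: np.ndarray, centers: np.ndarray):
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        if cov.ndim == 2 and cov.shape[0] == cov.shape[1] and cov.shape[0] > 1:
            self.cov = cov
        else:  # a vector of per-component sds
            scales = np.asarray(cov, dtype=float).ravel()
            self.cov = np.diag(scales**2)
        self.centers = centers
        self._chol = np.linalg.cholesky(self.cov)
        self._log_norm = (np.sum(np.log(np.diag(self._chol)))
                          + 0.5 * self.cov.shape[0] * np.log(2 * np.pi))

    def sample(self, rng: np.random.Generator, idx: np.ndarray,
               scale: float = 1.0) -> np.ndarray:
        picked = self.centers[idx]
        noise = rng.standard_normal(picked.shape) @ self._chol.T
        return picked + scale * noise

    def log_mixture(self, x: np.ndarray, log_weights: np.ndarray,
                    scales: np.ndarray) -> np.ndarray:
        """log sum_j w_j q(x_i | center_j, scale_i) for each row i."""
        dim = self.centers.shape[1]
        diff = x[:, None, :] - self.centers[None, :, :]
        flat = diff.reshape(-1, dim)
        y = solve_triangular(self._chol, flat.T, lower=True).T
        maha = np.sum(y**2, axis=1).reshape(diff.shape[:2])
        return logsumexp(-0.5 * maha / scales[:, None] ** 2 - self._log_norm
                         - dim * np.log(scales)[:, None] + log_weights[None, :],
                         axis=1)


class _LocalGaussianKernels:
    """Per-ancestor Gaussian kernels with locally adapted shape and drift.

    Ancestor ``i`` proposes from a Gaussian centred at a point drifted
    halfway towards the mean of its ``k`` nearest next-threshold survivors,
    with covariance built from those survivors around the ancestor
    (a local variant of the optimal-covariance kernel).  The kernel is
    therefore oriented along the locally surviving ridge and biased towards
    regions that already fit better, which is what lets a small population
    keep contracting on strongly correlated posteriors.

    ``sample``/``log_mixture`` take a global scale multiplier so the stage
    loop can adapt the step size to its observed acceptance rate while the
    importance weights remain exact (each particle records the scale it was
    proposed with).
    """

    def __init__(self, centers: np.ndarray, survivors: np.ndarray,
                 survivor_weights: np.ndarray, k_local: int = 40,
                 drift: float = 0.5):
        self.centers = centers
        n, dim = centers.shape
        n_surv = survivors.shape[0]
        k = min(k_local, n_surv)
        jitter = 1e-8 + 1e-4 * float(np.mean(np.var(survivors, axis=0)))
        self._chols = np.empty((n, dim, dim))
        self._log_norms = np.empty(n)
        self._means = np.empty_like(centers)
        half_log2pi = 0.5 * dim * np.log(2 * np.pi)
        eye = np.eye(dim)
        for i in range(n):
            if k < n_surv:
                d2 = np.sum((survivors - centers[i]) ** 2, axis=1)
                local = survivors[np.argpartition(d2, k - 1)[:k]]
            else:
                local = survivors
            self._means[i] = centers[i] + drift * (local.mean(axis=0) - centers[i])
            diff = local - centers[i]
            cov = diff.T @ diff / len(local) + jitter * eye
            chol = np.linalg.cholesky(cov)
            self._chols[i] = chol
            self._log_norms[i] = np.sum(np.log(np.diag(chol))) + half_log2pi

    def sample(self, rng: np.random.Generator, idx: np.ndarray,
               scale: float = 1.0) -> np.ndarray:
        noise = rng.standard_normal((idx.size, self.centers.shape[1]))
        return self._means[idx] + scale * np.einsum(
            "kij,kj->ki", self._chols[idx], noise)

    def log_mixture(self, x: np.ndarray, log_weights: np.ndarray,
                    scales: np.ndarray) -> np.ndarray:
        """log sum_j w_j q(x_i | ancestor j, scale_i) for each row i."""
        dim = self.centers.shape[1]
        out = np.empty((x.shape[0], self._means.shape[0]))
        for j in range(self._means.shape[0]):
            y = solve_triangular(self._chols[j], (x - self._means[j]).T,
                                 lower=True).T
            out[:, j] = (-0.5 * np.sum(y**2, axis=1) / scales**2
                         - self._log_norms[j] - dim * np.log(scales))
        return logsumexp(out + log_weights[None, :], axis=1)


def smc_stage(
    prev: ParticleEnsemble,
    epsilon: float,
    evaluator: Callable[[np.ndarray], float],
    prior: PriorSpec,
    kernel_scales: np.ndarray | None = None,
    seed: int = 0,
    n_batch: int = 100,
    acceptance_floor: float = 1e-4,
    max_evaluations: int = 2_000_000,
    n_jobs: int = 1,
) -> ParticleEnsemble:
    """One importance-resample / perturb / filter stage.

    Ancestors are drawn with probability proportional to ``weight * K_c``
    where ``K_c`` is a Gaussian kernel of the ancestor's distance with
    bandwidth equal to the previous threshold (closer fits are favoured —
    the adaptive-weight refinement of plain SMC resampling).  Proposals are
    multivariate Gaussian in latent (log) space with covariance twice the
    population covariance, so they track the correlated parameter ridges of
    over-parameterised kinetic models; ``kernel_scales`` overrides this with
    a fixed covariance matrix (or a vector of per-component sds).  Accepted
    particles are re-weighted by prior density over the weighted mixture of
    proposal densities and normalised.
    """
    if not epsilon < prev.epsilon:
        raise ValueError(f"thresholds must decrease: {epsilon} >= {prev.epsilon}")
    rng = np.random.default_rng([seed, prev.stage + 1])
    z_prev = prior.to_latent(prev.particles)
    if kernel_scales is not None:
        kernel = _GaussianKernel(kernel_scales, z_prev)
    else:
        survivors = prev.distances <= epsilon
        if survivors.sum() >= 2:
            kernel = _LocalGaussianKernels(z_prev, z_prev[survivors],
                                           prev.weights[survivors])
        else:
            kernel = _GaussianKernel(_proposal_cov(prior, prev), z_prev)

    bandwidth = _kc_bandwidth(prev.epsilon, epsilon)
    if np.isfinite(bandwidth):
        kc = np.exp(-0.5 * (prev.distances / bandwidth) ** 2)
    else:
        kc = np.ones(len(prev))
    p_select = prev.weights * kc
    total = p_select.sum()
    if total <= 0:
        raise AcceptanceStallError("all resampling probabilities vanished")
    p_select = p_select / total

    n_particles = len(prev)
    kept_z, kept_d, kept_s = [], [], []
    n_eval = 0
    scale = 1.0
    while len(kept_z) < n_particles:
        idx = rng.choice(n_particles, size=n_batch, p=p_select)
        z_new = kernel.sample(rng, idx, scale)
        thetas = prior.from_latent(z_new)
        d = _evaluate(evaluator, thetas, n_jobs)
        n_eval += n_batch
        hits = np.flatnonzero(d < epsilon)
        for i in hits:
            kept_z.append(z_new[i])
            kept_d.append(d[i])
            kept_s.append(scale)
        # 1/5-success-style step-size control: grow the kernel while
        # acceptance is easy, shrink it when proposals overshoot (fixed
        # user-supplied kernels are honoured as given)
        if kernel_scales is None:
            rate = hits.size / n_batch
            if rate > _SCALE_UP_ABOVE:
                scale = min(scale * 1.4, 10.0)
            elif rate < _SCALE_DOWN_BELOW:
                scale = max(scale * 0.75, 0.02)
        if n_eval >= max_evaluations or (
                n_eval >= 50 * n_batch and len(kept_z) / n_eval < acceptance_floor):
            raise AcceptanceStallError(
                f"stage {prev.stage + 1}: acceptance stalled "
                f"({len(kept_z)}/{n_eval} at epsilon={epsilon:.4g})")
    z_acc = np.array(kept_z[:n_particles])
    distances = np.array(kept_d[:n_particles])

    # omega^{tk} ∝ P(theta^{tk}) / sum_j p_j q(theta^{tk} | theta^{t-1,j}),
    # where p_j ∝ omega_j K_c(d_j) are the probabilities actually used to
    # select ancestors: the mixture must reflect the closeness-kernel
    # selection or the importance weights are biased (verified against a
    # conjugate Gaussian toy).
    log_prior = prior.latent_logpdf(z_acc)
    with np.errstate(divide="ignore"):
        log_p_select = np.log(p_select)
    log_denom = kernel.log_mixture(z_acc, log_p_select,
                                   np.array(kept_s[:n_particles]))
    log_w = log_prior - log_denom
    weights = np.exp(log_w - logsumexp(log_w))
    return ParticleEnsemble(prev.stage + 1, prior.from_latent(z_acc), weights,
                            distances, float(epsilon), tuple(prior.names), n_eval)


def epsilon_schedule(prev_distances: np.ndarray, alpha: float = 0.5) -> float:
    """Next threshold: the ``alpha`` quantile of the previous accepted distances."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    d = np.asarray(prev_distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances to schedule from")
    if np.ptp(d) == 0:
        raise ScheduleExhaustedError("accepted distances are degenerate; schedule exhausted")
    return float(np.quantile(d, alpha))


@dataclass
class SMCResult:
    """Final posterior ensemble plus the per-stage history and run manifest."""

    ensemble: ParticleEnsemble
    history: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.concat([e.to_dataframe() for e in self.history], ignore_index=True)


def run_abc_smc(
    prior: PriorSpec,
    evaluator: Callable[[np.ndarray], float],
    settings: SMCSettings | None = None,
    seed: int = 0,
    resume_from: Sequence[ParticleEnsemble] = (),
) -> SMCResult:
    """Run the full threshold sequence and return the posterior ensemble.

    Stage-level randomness is derived from ``(seed, stage)``, so a run
    resumed from a persisted stage (``resume_from``) reproduces the original
    run exactly under the same seed.
    """
    s = settings or SMCSettings()
    history: list[ParticleEnsemble] = list(resume_from)
    stop_reason = "max_stages"
    if not history:
        ens = initial_stage(prior, evaluator, s.initial_epsilon, s.n_particles,
                            s.n_batch, seed, s.acceptance_floor,
                            s.max_evaluations_per_stage, s.n_jobs,
                            pool=s.initial_pool)
        history.append(ens)
        log.info("stage 1: epsilon=%.4g, acceptance=%.3f, median d=%.4g",
                 ens.epsilon, ens.acceptance_rate, np.median(ens.distances))
    while history[-1].stage < s.max_stages:
        prev = history[-1]
        if s.target_epsilon is not None and prev.epsilon <= s.target_epsilon:
            stop_reason = "target_epsilon"
            break
        try:
            eps = epsilon_schedule(prev.distances, s.alpha)
        except ScheduleExhaustedError:
            stop_reason = "degenerate_distances"
            break
        if not eps < prev.epsilon:
            stop_reason = "threshold_stalled"
            break
        try:
            ens = smc_stage(prev, eps, evaluator, prior, None, seed, s.n_batch,
                            s.acceptance_floor, s.max_evaluations_per_stage, s.n_jobs)
        except AcceptanceStallError:
            stop_reason = "acceptance_stall"
            break
        history.append(ens)
        log.info("stage %d: epsilon=%.4g, acceptance=%.3f, median d=%.4g, ESS=%.0f",
                 ens.stage, ens.epsilon, ens.acceptance_rate,
                 np.median(ens.distances), ens.effective_sample_size())
        if ens.acceptance_rate < s.min_acceptance:
            stop_reason = "min_acceptance"
            break
    manifest = {
        "seed": int(seed),
        "n_particles": s.n_particles,
        "alpha": s.alpha,
        "stages": len(history),
        "stop_reason": stop_reason,
        "epsilons": [e.epsilon for e in history],
        "acceptance_rates": [e.acceptance_rate for e in history],
        "total_evaluations": int(sum(e.n_evaluations for e in history)),
    }
    return SMCResult(ensemble=history[-1], history=history, manifest=manifest)


def make_mapk_lrc_evaluator(
    observed: ResponseSet,
    doses: Sequence[float] = (0.1, 1.0, 2.0, 5.0),
    totals: Mapping[str, float] | None = None,
    reference_dose: float | None = None,
    model_builder: Callable[[np.ndarray, float], object] | None = None,
    condition_label: Callable[[float], str] | None = None,
) -> Callable[[np.ndarray], float]:
    """Distance evaluator for the EGF-driven cascade over several doses.

    For a parameter vector (ordered as ``MAPK_EGF_PARAM_NAMES``) the model's
    steady state is solved once per dose; local response coefficients come
    from the scaled Jacobian and ligand response ratios from the unperturbed
    steady levels against the lowest (reference) dose.  No perturbation is
    ever simulated.  Particles whose model has no stable steady state at
    some dose, or a degenerate one, score ``inf`` and are rejected.
    """
    doses = list(doses)
    reference = min(doses) if reference_dose is None else reference_dose
    label = condition_label or (lambda dose: f"EGF_{dose:g}")
    if model_builder is None:
        return _fast_mapk_evaluator(observed, doses, totals, reference, label)

    def evaluator(theta: np.ndarray) -> float:
        import warnings

        lrc: dict[str, np.ndarray] = {}
        levels: dict[str, np.ndarray] = {}
        try:
            for dose in doses:
                model = model_builder(theta, dose)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    # modest burn-in cap: particles with glacial relaxation are
                    # rejected rather than integrated indefinitely
                    ss = steady_state.find_steady_state(
                        model, burn_in=300.0, max_burn_in=4800.0)
                if not (ss.converged and ss.stable):
                    return float("inf")
                lrc[label(dose)] = steady_state.model_lrc(model, ss).r
                levels[label(dose)] = ss.state
        except (steady_state.SteadyStateError, steady_state.DegenerateStateError,
                ValueError, FloatingPointError):
            return float("inf")
        ratios = {label(d): levels[label(d)] / levels[label(reference)]
                  for d in doses if d != reference}
        simulated = ResponseSet(lrc=lrc, ratios=ratios)
        try:
            return overall_distance(observed, simulated)
        except ValueError:
            return float("inf")

    return evaluator


def _fast_mapk_evaluator(observed, doses, totals, reference, label):
    """Compiled-solver evaluator for the built-in EGF cascade.

    Same mathematics as the generic route (steady state -> scaled Jacobian
    -> normalised feature distance), specialised to the three-species model
    via :mod:`mrafit._fast_mapk`; equivalence is asserted in the tests.
    The returned callable scores one particle; its ``batch`` attribute
    scores an (n, 16) array in one compiled call.
    """
    from ._fast_mapk import mapk_distance_batch
    from .ode_models import DEFAULT_TOTALS

    tot_map = dict(DEFAULT_TOTALS)
    if totals is not None:
        tot_map.update(totals)
    tot = np.array([tot_map["RAF_TOT"], tot_map["MEK_TOT"], tot_map["ERK_TOT"]])
    labels = [label(d) for d in doses]
    off_mask = ~np.eye(3, dtype=bool)
    nd = len(doses)
    obs_off = np.empty((nd, 6))
    inv_n_r = np.empty(nd)
    obs_rho = np.ones((nd, 3))
    inv_n_rho = np.zeros(nd)
    ref_idx = doses.index(reference)
    for j, lab in enumerate(labels):
        if lab not in observed.lrc:
            raise ValueError(f"observed features lack condition {lab!r}")
        off = observed.lrc_array(lab)[off_mask]
        obs_off[j] = off
        inv_n_r[j] = 1.0 / np.linalg.norm(off)
        if j != ref_idx:
            rho = np.asarray(observed.ratios[lab], dtype=float)
            obs_rho[j] = rho
            inv_n_rho[j] = 1.0 / np.linalg.norm(rho)
    dose_arr = np.asarray(doses, dtype=float)

    def batch(thetas: np.ndarray) -> np.ndarray:
        thetas = np.ascontiguousarray(np.atleast_2d(thetas), dtype=float)
        return mapk_distance_batch(thetas, tot, dose_arr, ref_idx,
                                   obs_off, inv_n_r, obs_rho, inv_n_rho,
                                   1e-9, 300.0, 4800.0)

    def evaluator(theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (16,):
            return float("inf")
        return float(batch(theta[np.newaxis, :])[0])

    evaluator.batch = batch
    return evaluator


def observed_responses(dataset) -> tuple[ResponseSet, list[float]]:
    """Data-side features of a tidy perturbation dataset.

    Returns the observed :class:`~mrafit.objective.ResponseSet` (per-dose
    local response matrices plus ligand response ratios against the lowest
    dose) and the sorted dose list.
    """
    lrc, ratios, _ = mra.estimate_responses(dataset)
    observed = ResponseSet(lrc={c: m.r for c, m in lrc.items()},
                           ratios={c: rr.rho for c, rr in ratios.items()})
    doses = sorted(dataset.groupby("condition_id")["dose"].first())
    return observed, doses


def fit_mapk_sspr(
    dataset,
    seed: int,
    n_particles: int = 200,
    alpha: float = 0.5,
    max_stages: int = 10,
    initial_pool: int | None = 300_000,
    n_batch: int = 200,
    totals: Mapping[str, float] | None = None,
    prior: PriorSpec | None = None,
    max_evaluations_per_stage: int = 120_000,
) -> tuple[SMCResult, ResponseSet]:
    """Fit the EGF-driven cascade to a perturbation dataset end to end.

    The data side is reduced to local response coefficients and ligand
    response ratios; the sampler then needs one steady-state solve per dose
    per particle and never simulates a perturbation.  Stage 1 is classic
    quantile-threshold rejection sampling over ``initial_pool`` prior draws;
    later stages follow the adaptive-weight SMC scheme.
    """
    observed, doses = observed_responses(dataset)
    evaluator = make_mapk_lrc_evaluator(observed, doses, totals)
    if prior is None:
        prior = PriorSpec(MAPK_EGF_PARAM_NAMES)
    settings = SMCSettings(
        n_particles=n_particles, n_batch=n_batch, alpha=alpha,
        max_stages=max_stages, initial_pool=initial_pool,
        max_evaluations_per_stage=max_evaluations_per_stage,
        min_acceptance=1e-5, acceptance_floor=1e-6)
    result = run_abc_smc(prior, evaluator, settings, seed)
    return result, observed


def save_ensemble(result: SMCResult, particles_path, manifest_path=None) -> None:
    """Persist the stage history as CSV and the run manifest as JSON."""
    result.to_dataframe().to_csv(particles_path, index=False)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(result.manifest, fh, indent=2)


def load_history(particles_path) -> list[ParticleEnsemble]:
    """Reload a persisted stage history (inverse of :func:`save_ensemble`)."""
    df = pd.read_csv(particles_path)
    names = tuple(c for c in df.columns
                  if c not in ("stage", "weight", "distance", "epsilon"))
    history = []
    for stage, grp in df.groupby("stage", sort=True):
        history.append(ParticleEnsemble(
            stage=int(stage),
            particles=grp[list(names)].to_numpy(),
            weights=grp["weight"].to_numpy() / grp["weight"].sum(),
            distances=grp["distance"].to_numpy(),
            epsilon=float(grp["epsilon"].iloc[0]),
            names=names,
        ))
    return history
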