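"""Distances between data-derived and model-derived response features.

The core distance sums, over stimulation conditions E, normalised Euclidean
distances on the off-diagonal local response coefficients and on the ligand
response ratios:

    d_o = sum_E d(r^E, r_M^E) / n_r^E  +  sum_E d(rho^E, rho_M^E) / n_rho^E

with ``n_r^E = sqrt(sum_{i != j} (r^E_ij)^2)`` and
``n_rho^E = sqrt(sum_i (rho^E_i)^2)`` taken on the observed side.  Diagonal
LRC entries are -1 by construction on both sides and are excluded.

The augmented distance adds time-course blocks (normalised by the observed
curve norm) and pseudo-steady-state blocks: at stated times the model's
rate vector should vanish, so its plain Euclidean norm enters with weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .steady_state import LocalResponseMatrix

__all__ = ["ResponseSet", "overall_distance", "augmented_distance", "count_constraints"]


def _offdiag(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    return r[~np.eye(r.shape[0], dtype=bool)]


@dataclass
class ResponseSet:
    """Response features of one system across stimulation conditions.

    Attributes
    ----------
    lrc
        Condition id -> N x N local response matrix (or raw array).
    ratios
        Condition id -> per-species ligand response ratios against the
        reference condition.
    timecourses
        Optional ``(condition, species) -> array`` of concentrations on a
        shared time grid.
    pss_rates
        Optional ``condition -> rate vector`` of the model at that
        condition's pseudo-steady-state time (target: all zeros).  On the
        observed side these are zero vectors by definition.
    """

    lrc: Mapping[str, LocalResponseMatrix | np.ndarray] = field(default_factory=dict)
    ratios: Mapping[str, np.ndarray] = field(default_factory=dict)
    timecourses: Mapping[tuple, np.ndarray] = field(default_factory=dict)
    pss_rates: Mapping[str, np.ndarray] = field(default_factory=dict)

    def lrc_array(self, condition) -> np.ndarray:
        r = self.lrc[condition]
        return r.r if isinstance(r, LocalResponseMatrix) else np.asarray(r, dtype=float)

    def feature_vector(self) -> np.ndarray:
        """All compared features flattened (off-diagonal LRCs, then ratios)."""
        parts = [_offdiag(self.lrc_array(c)) for c in sorted(self.lrc)]
        parts += [np.asarray(self.ratios[c], dtype=float) for c in sorted(self.ratios)]
        return np.concatenate(parts) if parts else np.empty(0)


def _check_conditions(observed: Mapping, simulated: Mapping, what: str) -> None:
    missing = sorted(set(observed) - set(simulated))
    if missing:
        raise ValueError(f"simulated side is missing {what} for conditions {missing}")


def overall_distance(observed: ResponseSet, simulated: ResponseSet) -> float:
    """Normalised-Euclidean distance over LRC and ligand-ratio blocks.

    Zero iff all compared features are equal; each block is scaled by the
    observed-side norm, so a simulated all-zero LRC matrix scores exactly 1
    per condition.
    """
    _check_conditions(observed.lrc, simulated.lrc, "LRCs")
    _check_conditions(observed.ratios, simulated.ratios, "ligand ratios")
    d = 0.0
    for cond in observed.lrc:
        r_obs = _offdiag(observed.lrc_array(cond))
        r_sim = _offdiag(simulated.lrc_array(cond))
        if r_obs.shape != r_sim.shape:
            raise ValueError(f"LRC shape mismatch in condition {cond!r}")
        n_r = float(np.linalg.norm(r_obs))
        if n_r == 0:
            raise ValueError(f"observed LRCs in condition {cond!r} have zero norm")
        d += float(np.linalg.norm(r_obs - r_sim)) / n_r
    for cond in observed.ratios:
        rho_obs = np.asarray(observed.ratios[cond], dtype=float)
        rho_sim = np.asarray(simulated.ratios[cond], dtype=float)
        if rho_obs.shape != rho_sim.shape:
            raise ValueError(f"ratio shape mismatch in condition {cond!r}")
        n_rho = float(np.linalg.norm(rho_obs))
        if n_rho == 0:
            raise ValueError(f"observed ratios in condition {cond!r} have zero norm")
        d += float(np.linalg.norm(rho_obs - rho_sim)) / n_rho
    return d


def augmented_distance(
    observed: ResponseSet,
    simulated: ResponseSet,
    timecourse_weight: float = 1.0,
    pss_weight: float = 1.0,
) -> float:
    """Core distance plus time-course and pseudo-steady-state blocks.

    Time-course blocks compare observed and simulated curves on a shared
    grid, normalised by the observed curve's norm.  Pseudo-steady-state
    blocks penalise the norm of the simulated rate vector at time points
    where the measured system transiently peaked (all rates zero there).
    """
    d = overall_distance(observed, simulated)
    _check_conditions(observed.timecourses, simulated.timecourses, "time courses")
    for key in observed.timecourses:
        obs = np.asarray(observed.timecourses[key], dtype=float)
        sim = np.asarray(simulated.timecourses[key], dtype=float)
        if obs.shape != sim.shape:
            raise ValueError(f"time-course grid mismatch for {key!r}")
        n = float(np.linalg.norm(obs))
        if n == 0:
            raise ValueError(f"observed time course for {key!r} has zero norm")
        d += timecourse_weight * float(np.linalg.norm(obs - sim)) / n
    for cond in simulated.pss_rates:
        d += pss_weight * float(np.linalg.norm(np.asarray(simulated.pss_rates[cond], float)))
    return d


def count_constraints(response_set: ResponseSet, n_species: int | None = None) -> int:
    """Number of informative data points a response set contributes.

    Per condition: ``N^2 - N`` off-diagonal LRCs (diagonals carry no
    information) plus ``N`` vanishing-rate constraints per declared
    pseudo-steady state, plus one point per ligand-ratio entry and per
    time-course sample.
    """
    total = 0
    for cond in response_set.lrc:
        r = response_set.lrc_array(cond)
        n = r.shape[0]
        total += n * n - n
    for cond in response_set.pss_rates:
        total += np.asarray(response_set.pss_rates[cond]).size
    for cond in response_set.ratios:
        total += np.asarray(response_set.ratios[cond]).size
    for key in response_set.timecourses:
        total += np.asarray(response_set.timecourses[key]).size
    return total
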