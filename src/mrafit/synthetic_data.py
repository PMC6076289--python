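"""In-silico steady-state perturbation experiments.

Emulates the standard wet-lab protocol for mapping a kinase cascade:
starved cells (all active-kinase levels zero) are stimulated with a ligand
dose, left to relax to steady state, and the active fraction of each node is
read out with antibodies or fluorescent reporters that amplify the signal by
a large gain ``k_f``.  Perturbations are siRNA knockdowns, modelled as a
fractional reduction of a node's total (active + inactive) pool.  Each
measurement is replicated with additive Gaussian noise on the amplified
scale.

Default protocol: EGF doses 0.1/1/2/5 ng/ml, one knockdown per kinase plus
an unperturbed control, six replicates, noise sd drawn from
{0, 2, 5, 10, 15, 20} on an amplified signal of order ``k_f = 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mra import CONTROL_LABEL, DATASET_COLUMNS
from .ode_models import RateModel, build_mapk_egf_model
from .steady_state import SteadyStateError, find_steady_state

__all__ = [
    "PerturbationDataset",
    "apply_knockdown",
    "simulate_experiment",
    "DEFAULT_EGF_DOSES",
    "NOISE_LEVELS",
]

DEFAULT_EGF_DOSES = (0.1, 1.0, 2.0, 5.0)
#: Noise standard deviations of the study protocol, on the amplified scale.
NOISE_LEVELS = (0, 2, 5, 10, 15, 20)

DEFAULT_AMPLIFICATION = 100.0
DEFAULT_KNOCKDOWN = 0.5
DEFAULT_REPLICATES = 6
#: Floor applied after noise so log-ratio-based response coefficients stay defined.
TRUNCATION_FLOOR_FACTOR = 1e-6


@dataclass
class PerturbationDataset:
    """Long-form simulated measurements plus the generating metadata."""

    data: pd.DataFrame
    amplification: float
    noise_sd: float
    knockdown_fraction: float
    seed: int | None
    true_steady_states: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def apply_knockdown(model: RateModel, target: str, fraction: float) -> RateModel:
    """siRNA knockdown: scale the target species' total pool by (1 - fraction)."""
    if not 0 < fraction < 1:
        raise ValueError(f"knockdown fraction must be in (0, 1), got {fraction}")
    idx = model.species_index(target)  # raises KeyError for unknown species
    new_total = model.totals[idx] * (1.0 - fraction)
    return model.with_total(target, new_total)


def simulate_experiment(
    model_builder: Callable[[float], RateModel] | None = None,
    ligand_doses: Sequence[float] = DEFAULT_EGF_DOSES,
    knockdown_fraction: float = DEFAULT_KNOCKDOWN,
    amplification: float = DEFAULT_AMPLIFICATION,
    noise_sd: float = 0.0,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    ligand: str = "EGF",
    knockdown_targets: Sequence[str] | None = None,
) -> PerturbationDataset:
    """Simulate the full perturbation grid at one noise level.

    For each dose: the unperturbed model and one knockdown per species are
    run from the starved state to steady state; the steady concentrations
    are amplified by ``amplification`` and measured ``n_replicates`` times
    with i.i.d. additive N(0, noise_sd^2) noise.  Negative noisy values are
    truncated at a small positive floor.

    ``model_builder`` maps a dose to a :class:`RateModel`; the default is
    the EGF-driven MAPK cascade at its published parameters.
    """
    if model_builder is None:
        model_builder = lambda dose: build_mapk_egf_model(egf=dose)
    if any(d <= 0 for d in ligand_doses):
        raise ValueError("ligand doses must be positive")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")

    rng = np.random.default_rng(seed)
    floor = TRUNCATION_FLOOR_FACTOR * amplification
    records = []
    true_states: dict[tuple, np.ndarray] = {}
    for dose in ligand_doses:
        base = model_builder(dose)
        condition = _condition_id(ligand, dose)
        targets = list(knockdown_targets) if knockdown_targets is not None \
            else list(base.species_names)
        variants = [(CONTROL_LABEL, base)]
        variants += [(s, apply_knockdown(base, s, knockdown_fraction))
                     for s in targets]
        for target, model in variants:
            ss = find_steady_state(model)
            if not ss.converged:
                raise SteadyStateError(
                    f"no steady state at dose {dose} (perturbation {target!r})")
            true_states[(condition, target)] = ss.state.copy()
            amplified = amplification * ss.state
            for rep in range(1, n_replicates + 1):
                noisy = amplified + (rng.normal(0.0, noise_sd, size=amplified.size)
                                     if noise_sd > 0 else 0.0)
                noisy = np.maximum(noisy, floor)
                for species, value in zip(model.species_names, noisy):
                    records.append((condition, ligand, dose, target, rep, species, value))

    data = pd.DataFrame.from_records(records, columns=DATASET_COLUMNS)
    return PerturbationDataset(
        data=data,
        amplification=amplification,
        noise_sd=noise_sd,
        knockdown_fraction=knockdown_fraction,
        seed=seed,
        true_steady_states=true_states,
    )


def _condition_id(ligand: str, dose: float) -> str:
    return f"{ligand}_{dose:g}"
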