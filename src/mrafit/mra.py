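"""Modular response analysis: from perturbation data to response matrices.

Given replicate steady-state measurements of each network node under a
control condition and under exactly one perturbation per node, classical MRA
recovers the direct (local) interaction strengths from the propagated
(global) responses by matrix inversion:

* global response coefficient: ``R_ij = 2 (x_i^j - x_i) / (x_i + x_i^j)``,
  a symmetric finite-difference approximation of ``d ln x_i / d ln x_j``;
* local response matrix: ``r = -(dg(R^-1))^-1 R^-1``, normalised so that
  ``diag(r) = -1``.

Because both are built from ratios, any common amplification of the raw
signal (antibody/reporter gain) cancels.

Datasets are tidy long-form tables with columns ``condition_id, ligand,
dose, perturbation_target, replicate, species, value`` where
``perturbation_target == "none"`` marks the unperturbed control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .steady_state import LocalResponseMatrix

__all__ = [
    "DATASET_COLUMNS",
    "CONTROL_LABEL",
    "GlobalResponseMatrix",
    "LigandResponseRatios",
    "aggregate_replicates",
    "global_response_matrix",
    "local_response_from_global",
    "ligand_response_ratios",
    "condition_means",
    "estimate_responses",
    "read_dataset",
    "write_matrix_csv",
    "DatasetSchemaError",
    "InsufficientPerturbationsError",
]

DATASET_COLUMNS = (
    "condition_id", "ligand", "dose", "perturbation_target", "replicate", "species", "value",
)
CONTROL_LABEL = "none"


class DatasetSchemaError(ValueError):
    """The tidy dataset is missing columns or cells."""


class InsufficientPerturbationsError(ValueError):
    """Classical MRA needs exactly one perturbation per node."""


@dataclass
class GlobalResponseMatrix:
    """N x N global response coefficients; column j = perturbation of node j."""

    R: np.ndarray
    condition: str = ""
    species: tuple = ()


@dataclass
class LigandResponseRatios:
    """Per-species ratios of unperturbed steady levels between two conditions."""

    rho: np.ndarray
    condition: str = ""
    reference: str = ""
    species: tuple = ()


def read_dataset(path) -> pd.DataFrame:
    """Read a tidy perturbation dataset CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetSchemaError(f"dataset is missing columns {missing}")
    return df


def aggregate_replicates(dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean concentration per (condition, perturbation target, species).

    Returns a frame with columns ``condition_id, perturbation_target,
    species, value, n_replicates``.  Raises when any (condition x
    perturbation x species) cell present elsewhere in the grid is missing.
    """
    missing = [c for c in ("condition_id", "perturbation_target", "species", "value")
               if c not in dataset.columns]
    if missing:
        raise DatasetSchemaError(f"dataset is missing columns {missing}")
    if (dataset["value"] <= 0).any():
        raise ValueError("all measured values must be positive")
    grouped = (dataset.groupby(["condition_id", "perturbation_target", "species"], sort=True)
               ["value"].agg(value="mean", n_replicates="count").reset_index())
    # the (condition, perturbation, species) grid must be complete
    full = pd.MultiIndex.from_product(
        [grouped["condition_id"].unique(), grouped["perturbation_target"].unique(),
         grouped["species"].unique()],
        names=["condition_id", "perturbation_target", "species"])
    have = pd.MultiIndex.from_frame(grouped[["condition_id", "perturbation_target", "species"]])
    gaps = full.difference(have)
    if len(gaps):
        raise DatasetSchemaError(f"missing cells in dataset: {list(gaps[:10])}"
                                 + ("..." if len(gaps) > 10 else ""))
    return grouped


def condition_means(
    dataset: pd.DataFrame, condition: str, species_order: Sequence[str] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray], list[str]]:
    """Split replicate means of one condition into control and perturbed vectors.

    Returns ``(unperturbed, {target: perturbed_vector}, species_order)``.
    """
    sub = dataset[dataset["condition_id"] == condition]
    agg = aggregate_replicates(sub)
    if agg.empty:
        raise DatasetSchemaError(f"condition {condition!r} not present in dataset")
    # keep the dataset's species order (cascade order), not alphabetical
    species = list(species_order) if species_order else list(dict.fromkeys(sub["species"]))
    table = agg.pivot(index="perturbation_target", columns="species", values="value")
    if CONTROL_LABEL not in table.index:
        raise DatasetSchemaError(f"condition {condition!r} has no unperturbed control rows")
    unperturbed = table.loc[CONTROL_LABEL, species].to_numpy(dtype=float)
    perturbed = {t: table.loc[t, species].to_numpy(dtype=float)
                 for t in table.index if t != CONTROL_LABEL}
    return unperturbed, perturbed, species


def global_response_matrix(
    unperturbed: np.ndarray,
    perturbed: Mapping[str, np.ndarray],
    species: Sequence[str],
    condition: str = "",
) -> GlobalResponseMatrix:
    """Global response coefficients ``R_ij = 2 (x_i^j - x_i)/(x_i + x_i^j)``.

    ``perturbed`` maps each perturbed species (exactly one perturbation per
    node) to the vector of mean concentrations under that perturbation.
    """
    species = list(species)
    n = len(species)
    x = np.asarray(unperturbed, dtype=float)
    if x.shape != (n,):
        raise ValueError("unperturbed vector length must match species")
    if set(perturbed) != set(species):
        raise InsufficientPerturbationsError(
            f"classical MRA needs exactly one perturbation per node; "
            f"have {sorted(perturbed)}, need {sorted(species)}")
    if np.any(x <= 0):
        raise ValueError("nonpositive unperturbed concentration")
    R = np.empty((n, n))
    for j, target in enumerate(species):
        xj = np.asarray(perturbed[target], dtype=float)
        if np.any(xj <= 0):
            raise ValueError(f"nonpositive concentration under perturbation of {target!r}")
        R[:, j] = 2.0 * (xj - x) / (x + xj)
    return GlobalResponseMatrix(R=R, condition=condition, species=tuple(species))


def local_response_from_global(
    R: GlobalResponseMatrix | np.ndarray,
    condition: str | None = None,
    max_condition_number: float = 1e8,
) -> LocalResponseMatrix:
    """Invert the global response matrix into local response coefficients.

    ``r = -(dg(R^-1))^-1 R^-1``: each row of ``R^-1`` is rescaled by its
    diagonal element and negated, so ``diag(r) = -1`` exactly.  The sign
    puts self-regulation at -1, consistent with the scaled-Jacobian
    definition of the local response coefficients.
    """
    if isinstance(R, GlobalResponseMatrix):
        mat, species = R.R, R.species
        condition = R.condition if condition is None else condition
    else:
        mat, species = np.asarray(R, dtype=float), ()
        condition = condition or ""
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("global response matrix must be square")
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > max_condition_number:
        raise np.linalg.LinAlgError(
            f"global response matrix is singular or ill-conditioned (cond={cond:.2e}); "
            "more informative perturbations are needed")
    Rinv = np.linalg.inv(mat)
    r = -Rinv / np.diag(Rinv)[:, np.newaxis]
    np.fill_diagonal(r, -1.0)
    return LocalResponseMatrix(r=r, condition=condition, species=tuple(species))


def ligand_response_ratios(
    steady_means: Mapping[str, np.ndarray],
    condition: str,
    reference: str,
    species: Sequence[str] = (),
) -> LigandResponseRatios:
    """Per-species ratio of unperturbed means of ``condition`` over ``reference``."""
    if reference not in steady_means:
        raise KeyError(f"reference condition {reference!r} not present")
    if condition not in steady_means:
        raise KeyError(f"condition {condition!r} not present")
    num = np.asarray(steady_means[condition], dtype=float)
    den = np.asarray(steady_means[reference], dtype=float)
    if np.any(num <= 0) or np.any(den <= 0):
        raise ValueError("steady means must be strictly positive")
    return LigandResponseRatios(rho=num / den, condition=condition,
                                reference=reference, species=tuple(species))


def estimate_responses(
    dataset: pd.DataFrame,
    reference_condition: str | None = None,
    species_order: Sequence[str] | None = None,
):
    """Full data-side pipeline: tidy dataset -> per-condition r and rho.

    Returns ``(lrc, ratios, species)`` where ``lrc`` maps condition id to
    :class:`LocalResponseMatrix` and ``ratios`` maps each non-reference
    condition to :class:`LigandResponseRatios` against the reference
    (default: the condition with the smallest dose).
    """
    conditions = list(dict.fromkeys(dataset["condition_id"]))
    if reference_condition is None:
        doses = dataset.groupby("condition_id", sort=False)["dose"].first()
        reference_condition = doses.idxmin()
    lrc: dict[str, LocalResponseMatrix] = {}
    unperturbed_means: dict[str, np.ndarray] = {}
    species: list[str] = list(species_order) if species_order else []
    for cond in conditions:
        x0, perturbed, sp = condition_means(dataset, cond, species or None)
        species = sp
        unperturbed_means[cond] = x0
        R = global_response_matrix(x0, perturbed, sp, condition=str(cond))
        lrc[cond] = local_response_from_global(R)
    ratios = {
        cond: ligand_response_ratios(unperturbed_means, cond, reference_condition, species)
        for cond in conditions if cond != reference_condition
    }
    return lrc, ratios, species


def write_matrix_csv(path, matrix: np.ndarray, species: Sequence[str]) -> None:
    """Write a labelled square response matrix as CSV."""
    pd.DataFrame(matrix, index=list(species), columns=list(species)).to_csv(path)
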