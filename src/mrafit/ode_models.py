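"""ODE models of signalling networks.

The package ships two three-kinase MAPK/ERK cascade models:

* an EGF-driven cascade in which the ligand acts directly as the modifier of
  RAF activation (:func:`build_mapk_egf_model`), used for in-silico
  perturbation studies, and
* an EGF/NGF cascade driven by a transient RAS input pulse with
  ligand-selective feedback wiring (:func:`build_mapk_egf_ngf_model`).

Both are built from Michaelis-Menten activation and decay primitives.  Each
active kinase ``aX`` draws on a finite inactive pool ``iX = X_TOT - aX``, so
trajectories started inside the box ``[0, totals]`` stay inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "RateModel",
    "michaelis_activation",
    "michaelis_decay",
    "ras_input",
    "build_mapk_egf_model",
    "build_mapk_egf_ngf_model",
    "MAPK_EGF_PARAMS",
    "MAPK_EGF_PARAM_NAMES",
    "MAPK_EGF_NGF_PARAM_NAMES",
    "DEFAULT_TOTALS",
]


class ModelConfigurationError(ValueError):
    """Raised when a model is built from an incomplete or invalid parameter set."""


def michaelis_activation(k: float, K: float, S, M):
    """Michaelis-Menten activation rate ``k * S * M / (K + S)``.

    ``S`` is the substrate pool being converted and ``M`` the modifier
    (kinase or ligand) driving the conversion.  Monotone increasing in both.
    """
    if K <= 0:
        raise ValueError(f"Michaelis constant must be positive, got {K}")
    return k * S * M / (K + S)


def michaelis_decay(V, K, S):
    """Michaelis-Menten decay rate ``V * S / (K + S)``, bounded above by ``V``."""
    if K <= 0:
        raise ValueError(f"Michaelis constant must be positive, got {K}")
    return V * S / (K + S)


def ras_input(ligand_level: float, kd: float, t):
    """Transient RAS-GTP input pulse ``(L/(1+L)) * t^5 * exp(-kd*t)``.

    Models rapid activation and subsequent decay of RAS after ligand binding.
    Zero at ``t = 0``, unimodal in time with its maximum at ``t = 5/kd``.
    """
    if ligand_level < 0:
        raise ValueError("ligand level must be nonnegative")
    if kd <= 0:
        raise ValueError("decay rate must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = (ligand_level / (1.0 + ligand_level)) * t**5 * np.exp(-kd * t)
    return out if out.ndim else float(out)


@dataclass
class RateModel:
    """An N-node ODE system ``dx/dt = f(x, t)`` with finite total pools.

    Parameters
    ----------
    species_names
        Ordered names of the active-form state variables.
    rate
        Callable ``rate(x, t) -> dx/dt`` (vector of length N).
    totals
        Total (active + inactive) concentration per species, same order as
        ``species_names``.  Strictly positive.
    parameters
        Named positive rate constants the model was built from.
    inputs
        Named ligand levels (nonnegative constants).
    jacobian
        Optional analytic Jacobian ``jac(x, t) -> (N, N)``; used by solvers
        when present, otherwise finite differences are applied.
    autonomous
        True when ``rate`` does not depend on ``t`` (steady states exist).
    """

    species_names: Sequence[str]
    rate: Callable[[np.ndarray, float], np.ndarray]
    totals: np.ndarray
    parameters: Mapping[str, float] = field(default_factory=dict)
    inputs: Mapping[str, float] = field(default_factory=dict)
    jacobian: Callable[[np.ndarray, float], np.ndarray] | None = None
    autonomous: bool = True

    def __post_init__(self):
        self.species_names = list(self.species_names)
        self.totals = np.asarray(self.totals, dtype=float)
        if self.totals.shape != (len(self.species_names),):
            raise ModelConfigurationError("one total per species is required")
        if np.any(self.totals <= 0):
            raise ModelConfigurationError("totals must be strictly positive")
        for name, value in self.parameters.items():
            if value <= 0:
                raise ModelConfigurationError(f"parameter {name} must be positive, got {value}")
        for name, value in self.inputs.items():
            if value < 0:
                raise ModelConfigurationError(f"input {name} must be nonnegative, got {value}")

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}; known: {self.species_names}") from None

    def with_total(self, species: str, total: float) -> "RateModel":
        """Return a copy of the model with one species' total replaced."""
        raise NotImplementedError  # overridden by builders via `rebuild`


# The sixteen rate constants of the EGF-driven cascade, with their published
# defaults.  kf/Kmf: activation; kr/Kmr: ERK-mediated feedback deactivation of
# RAF and MEK; Vm/Km: phosphatase-mediated decay.
MAPK_EGF_PARAMS: dict[str, float] = {
    "k_f1": 1.0, "K_mf1": 10.0, "V_m1": 2.0, "K_m1": 10.0,
    "k_f2": 1.0, "K_mf2": 10.0, "V_m2": 1.0, "K_m2": 10.0,
    "k_f3": 0.1, "K_mf3": 10.0, "V_m3": 10.0, "K_m3": 10.0,
    "k_r1": 1.0, "K_mr1": 10.0,
    "k_r2": 1.0, "K_mr2": 10.0,
}
MAPK_EGF_PARAM_NAMES: tuple[str, ...] = tuple(MAPK_EGF_PARAMS)

# Total pools are not part of the sixteen free parameters; defaults are set on
# the order of the Michaelis constants (half-saturation at 10).
DEFAULT_TOTALS: dict[str, float] = {"RAF_TOT": 100.0, "MEK_TOT": 100.0, "ERK_TOT": 100.0}

SPECIES = ("aRAF", "aMEK", "aERK")


def _check_parameters(params: Mapping[str, float], required: Sequence[str]) -> dict[str, float]:
    missing = [name for name in required if name not in params]
    if missing:
        raise ModelConfigurationError(f"missing parameters: {missing}")
    extra = [name for name in params if name not in required]
    if extra:
        raise ModelConfigurationError(f"unknown parameters: {extra}")
    out = {name: float(params[name]) for name in required}
    for name, value in out.items():
        if value <= 0:
            raise ModelConfigurationError(f"parameter {name} must be positive, got {value}")
    return out


def build_mapk_egf_model(
    parameters: Mapping[str, float] | None = None,
    totals: Mapping[str, float] | None = None,
    egf: float = 0.1,
) -> RateModel:
    """Three-kinase EGF-driven MAPK cascade (aRAF, aMEK, aERK).

    EGF enters directly as the modifier of RAF activation.  Active ERK feeds
    back negatively on both RAF and MEK by catalysing their deactivation:

    .. code-block:: text

        d(aRAF)/dt = Ma(k_f1, K_mf1, iRAF, EGF)  - Ma(k_r1, K_mr1, aRAF, aERK) - M0(V_m1, K_m1, aRAF)
        d(aMEK)/dt = Ma(k_f2, K_mf2, iMEK, aRAF) - Ma(k_r2, K_mr2, aMEK, aERK) - M0(V_m2, K_m2, aMEK)
        d(aERK)/dt = Ma(k_f3, K_mf3, iERK, aMEK)                               - M0(V_m3, K_m3, aERK)

    with ``Ma(k, K, S, M) = k S M/(K+S)``, ``M0(V, K, S) = V S/(K+S)`` and
    ``iX = X_TOT - aX``.  Sixteen free rate parameters.
    """
    if egf < 0:
        raise ModelConfigurationError("EGF dose must be nonnegative")
    p = _check_parameters(parameters if parameters is not None else MAPK_EGF_PARAMS,
                          MAPK_EGF_PARAM_NAMES)
    tot = dict(DEFAULT_TOTALS)
    if totals is not None:
        tot.update(totals)
    raf_t, mek_t, erk_t = tot["RAF_TOT"], tot["MEK_TOT"], tot["ERK_TOT"]

    kf1, Kmf1, Vm1, Km1 = p["k_f1"], p["K_mf1"], p["V_m1"], p["K_m1"]
    kf2, Kmf2, Vm2, Km2 = p["k_f2"], p["K_mf2"], p["V_m2"], p["K_m2"]
    kf3, Kmf3, Vm3, Km3 = p["k_f3"], p["K_mf3"], p["V_m3"], p["K_m3"]
    kr1, Kmr1, kr2, Kmr2 = p["k_r1"], p["K_mr1"], p["k_r2"], p["K_mr2"]

    def rate(x, t=0.0):
        araf, amek, aerk = x
        iraf, imek, ierk = raf_t - araf, mek_t - amek, erk_t - aerk
        return np.array([
            kf1 * iraf * egf / (Kmf1 + iraf)
            - kr1 * araf * aerk / (Kmr1 + araf)
            - Vm1 * araf / (Km1 + araf),
            kf2 * imek * araf / (Kmf2 + imek)
            - kr2 * amek * aerk / (Kmr2 + amek)
            - Vm2 * amek / (Km2 + amek),
            kf3 * ierk * amek / (Kmf3 + ierk)
            - Vm3 * aerk / (Km3 + aerk),
        ])

    def jacobian(x, t=0.0):
        araf, amek, aerk = x
        iraf, imek, ierk = raf_t - araf, mek_t - amek, erk_t - aerk
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

    model = RateModel(
        species_names=SPECIES,
        rate=rate,
        totals=[raf_t, mek_t, erk_t],
        parameters=p,
        inputs={"EGF": float(egf)},
        jacobian=jacobian,
        autonomous=True,
    )
    model.with_total = _make_rebuilder(build_mapk_egf_model, p, tot, egf=egf)  # type: ignore[method-assign]
    return model


# Rate parameters of the EGF/NGF cascade.  First index: tier (1 RAF, 2 MEK,
# 3 ERK); second index: reaction within tier.  kd_* set the decay of the
# transient RAS input pulse.
MAPK_EGF_NGF_PARAM_NAMES: tuple[str, ...] = (
    "k_f11", "K_mf11",   # EGF-driven RAF activation (via RAS_EGF)
    "k_r12", "K_mr12",   # EGF-specific negative feedback aERK -| aRAF
    "k_f13", "K_mf13",   # NGF-driven RAF activation (via RAS_NGF)
    "k_f14", "K_mf14",   # NGF-specific positive feedback aERK -> aRAF
    "V_m1", "K_m1",
    "k_f21", "K_mf21",   # aRAF -> aMEK
    "k_f22", "K_mf22",   # aERK -| aMEK
    "V_m2", "K_m2",
    "k_f31", "K_mf31",   # aMEK -> aERK
    "k_f32", "K_mf32",   # NGF-specific feedforward aRAF -> aERK
    "V_m3", "K_m3",
    "kd_egf", "kd_ngf",
)


def build_mapk_egf_ngf_model(
    parameters: Mapping[str, float],
    totals: Mapping[str, float],
    ligand: str,
    dose: float,
) -> RateModel:
    """EGF/NGF-driven MAPK cascade with ligand-selective wiring.

    RAF is driven by a transient RAS-GTP pulse (:func:`ras_input`) rather
    than by the ligand directly.  Binary flags ``(b_e, b_n)`` select the
    ligand-specific interactions: under EGF a negative feedback from aERK to
    aRAF (``k_r12``); under NGF a positive feedback aERK -> aRAF (``k_f14``)
    and a feedforward aRAF -> aERK (``k_f32``).  Twenty-four rate parameters
    plus the three totals give 27 unknowns.  The model is non-autonomous
    (the RAS pulse depends on time), so it has pseudo-steady states only.
    """
    ligand = ligand.upper()
    if ligand not in ("EGF", "NGF"):
        raise ModelConfigurationError(f"ligand must be 'EGF' or 'NGF', got {ligand!r}")
    if dose < 0:
        raise ModelConfigurationError("ligand dose must be nonnegative")
    b_e, b_n = (1, 0) if ligand == "EGF" else (0, 1)
    p = _check_parameters(parameters, MAPK_EGF_NGF_PARAM_NAMES)
    for key in ("RAF_TOT", "MEK_TOT", "ERK_TOT"):
        if key not in totals:
            raise ModelConfigurationError(f"missing total {key}")
    raf_t, mek_t, erk_t = float(totals["RAF_TOT"]), float(totals["MEK_TOT"]), float(totals["ERK_TOT"])

    kd = p["kd_egf"] if b_e else p["kd_ngf"]
    scale = dose / (1.0 + dose)

    def ras(t):
        # inline ras_input without re-validation (hot path)
        return scale * t**5 * np.exp(-kd * t)

    def rate(x, t):
        araf, amek, aerk = x
        iraf, imek, ierk = raf_t - araf, mek_t - amek, erk_t - aerk
        u = ras(t)
        draf = (
            b_e * (p["k_f11"] * iraf * u / (p["K_mf11"] + iraf)
                   - p["k_r12"] * araf * aerk / (p["K_mr12"] + araf))
            + b_n * (p["k_f13"] * iraf * u / (p["K_mf13"] + iraf)
                     + p["k_f14"] * iraf * aerk / (p["K_mf14"] + iraf))
            - p["V_m1"] * araf / (p["K_m1"] + araf)
        )
        dmek = (
            p["k_f21"] * imek * araf / (p["K_mf21"] + imek)
            - p["k_f22"] * amek * aerk / (p["K_mf22"] + amek)
            - p["V_m2"] * amek / (p["K_m2"] + amek)
        )
        derk = (
            p["k_f31"] * ierk * amek / (p["K_mf31"] + ierk)
            + b_n * p["k_f32"] * ierk * araf / (p["K_mf32"] + ierk)
            - p["V_m3"] * aerk / (p["K_m3"] + aerk)
        )
        return np.array([draf, dmek, derk])

    model = RateModel(
        species_names=SPECIES,
        rate=rate,
        totals=[raf_t, mek_t, erk_t],
        parameters=p,
        inputs={ligand: float(dose)},
        jacobian=None,
        autonomous=False,
    )
    model.ligand_flags = (b_e, b_n)  # type: ignore[attr-defined]
    model.with_total = _make_rebuilder(  # type: ignore[method-assign]
        build_mapk_egf_ngf_model, p, {"RAF_TOT": raf_t, "MEK_TOT": mek_t, "ERK_TOT": erk_t},
        ligand=ligand, dose=dose)
    return model


def _make_rebuilder(builder, params, totals, **kwargs):
    def with_total(species: str, total: float) -> RateModel:
        key = {"aRAF": "RAF_TOT", "aMEK": "MEK_TOT", "aERK": "ERK_TOT"}.get(species, species)
        if key not in totals:
            raise KeyError(f"unknown species/total {species!r}")
        new_totals = dict(totals)
        new_totals[key] = total
        return builder(params, new_totals, **kwargs)
    return with_total
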