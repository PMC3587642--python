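"""ODE model abstraction, the two built-in study models, and trajectory integration.

A model is a :class:`ModelSpec`: a right-hand side ``f(s, x, t, u)`` over a
state vector ``s`` (species concentrations) and a parameter vector ``x``
(kinetic rates), together with an output map selecting the observed species.
Two kinetic systems ship with the package:

* a four-species p53–Mdm2 negative feedback loop (nuclear p53, Mdm2, the
  p53–Mdm2 complex, and Mdm2 mRNA; nine rate constants), and
* a three-species arginine catabolism model (external arginine, ornithine,
  internal arginine; sixteen rate constants) in which only ornithine and
  internal arginine are observed.

Perturbed variants used in model-selection studies (knockouts obtained by
zeroing or overriding individual rate constants) are registered under names
like ``"p53_E2"`` or ``"arginine_F3"``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "Trajectory",
    "IntegrationError",
    "p53_rhs",
    "arginine_rhs",
    "integrate_model",
    "apply_perturbation",
    "get_model",
    "list_models",
]

#: Default solver tolerances. Parameter estimation is tolerance-sensitive:
#: these are tight enough that fitness differences between candidate
#: parameter vectors exceed solver noise.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite state.

    Carries the offending parameter vector so optimizers can map the
    failure to an infinite fitness value.
    """

    def __init__(self, message: str, params: np.ndarray | None = None):
        super().__init__(message)
        self.params = None if params is None else np.asarray(params, float)


@dataclass(frozen=True)
class ModelSpec:
    """An ODE system with named states and parameters.

    ``rhs`` maps ``(state, params, t, u)`` to the state derivative.  The
    input signal ``u`` (a map ``time -> scalar``) is carried for generality
    but neither built-in model uses it.
    """

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, np.ndarray, float, Callable[[float], float] | None], np.ndarray]
    initial_state: np.ndarray
    observed_indices: tuple[int, ...]
    default_bounds: np.ndarray  # (M, 2) array of [LB, UB]
    input_signal: Callable[[float], float] | None = None
    default_horizon: float = 10.0  # sampling horizon for synthetic studies
    nominal_params: np.ndarray | None = None  # reference/true parameter set

    def __post_init__(self):
        object.__setattr__(self, "initial_state", np.asarray(self.initial_state, float))
        object.__setattr__(self, "default_bounds", np.asarray(self.default_bounds, float))
        if self.nominal_params is not None:
            object.__setattr__(self, "nominal_params", np.asarray(self.nominal_params, float))
        if len(self.initial_state) != len(self.state_names):
            raise ValueError(
                f"initial_state length {len(self.initial_state)} != "
                f"{len(self.state_names)} states"
            )
        if not self.observed_indices:
            raise ValueError("observed_indices must be non-empty")
        if any(i < 0 or i >= len(self.state_names) for i in self.observed_indices):
            raise ValueError("observed_indices out of range")
        if self.default_bounds.shape != (len(self.param_names), 2):
            raise ValueError("default_bounds must be (M, 2)")
        if np.any(self.default_bounds[:, 0] > self.default_bounds[:, 1]):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def observed_names(self) -> tuple[str, ...]:
        return tuple(self.state_names[i] for i in self.observed_indices)

    def param_index(self, label: str) -> int:
        try:
            return self.param_names.index(label)
        except ValueError:
            raise KeyError(f"unknown parameter {label!r} for model {self.name!r}") from None


@dataclass(frozen=True)
class Trajectory:
    """Observed-species values sampled on a strictly increasing time grid."""

    times: np.ndarray
    states: np.ndarray  # (N, K) for K observed species

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "states", np.asarray(self.states, float))
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states and times lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite values")


def p53_rhs(state: np.ndarray, params: np.ndarray, t: float = 0.0, u=None) -> np.ndarray:
    """p53–Mdm2 negative feedback loop derivative field.

    States ``A, B, C, D`` are nuclear p53, Mdm2, the p53–Mdm2 complex, and
    Mdm2 mRNA.  Rate constants: k1 p53 production, k2 p53 degradation,
    k3 complex formation, k4 complex diffusion (back-flux to free p53 and
    Mdm2), k5 Mdm2 degradation, k6 Mdm2 translation, k7 Mdm2-mediated p53
    degradation (the complex degrades its p53 moiety, releasing Mdm2),
    k8 p53-driven Mdm2 transcription, k9 Mdm2 mRNA degradation.
    """
    state = np.asarray(state, float)
    params = np.asarray(params, float)
    if state.shape != (4,):
        raise ValueError(f"p53 state must be a 4-vector, got shape {state.shape}")
    if params.shape != (9,):
        raise ValueError(f"p53 params must be a 9-vector, got shape {params.shape}")
    A, B, C, D = state
    k1, k2, k3, k4, k5, k6, k7, k8, k9 = params
    formation = k3 * A * B
    dA = k1 - k2 * A - formation + k4 * C
    dB = k6 * D - formation + k4 * C + k7 * C - k5 * B
    dC = formation - k4 * C - k7 * C
    dD = k8 * A - k9 * D
    return np.array([dA, dB, dC, dD])


def arginine_rhs(state: np.ndarray, params: np.ndarray, t: float = 0.0, u=None) -> np.ndarray:
    """Arginine catabolism derivative field.

    States ``A, B, C`` are external arginine, ornithine, and internal
    arginine.  Five Michaelis–Menten-type rates over sixteen constants:

    * cationic amino-acid transport of arginine (net influx), with
      competitive inhibition by ornithine entering the uptake denominator
      as the additive term ``k7*B`` (so k7 = 0 removes the inhibition);
    * arginase (internal arginine -> ornithine);
    * nitric-oxide synthase (internal arginine -> NO + citrulline);
    * ornithine decarboxylase (ornithine -> putrescine);
    * ornithine export (carrier-mediated plus a first-order leak).

    Only ornithine and internal arginine are observed.
    """
    state = np.asarray(state, float)
    params = np.asarray(params, float)
    if state.shape != (3,):
        raise ValueError(f"arginine state must be a 3-vector, got shape {state.shape}")
    if params.shape != (16,):
        raise ValueError(f"arginine params must be a 16-vector, got shape {params.shape}")
    A, B, C = state
    (k1, k2, k3, k4, k5, k6, k7, k8,
     k9, k10, k11, k12, k13, k14, k15, k16) = params
    denoms = np.array([k2 + A + k7 * B, k14 + C + k11 * B, k4 + C,
                       k6 + C, k9 + B, k16 + B + k12 * C])
    if np.any(denoms == 0.0):
        raise IntegrationError(
            "zero Michaelis-Menten denominator in arginine rate law", params
        )
    v_uptake = k1 * A / denoms[0] - k13 * C / denoms[1]  # net CAT transport
    v_arginase = k3 * C / denoms[2]
    v_nos = k5 * C / denoms[3]
    v_odc = k8 * B / denoms[4]
    v_export = k15 * B / denoms[5] + k10 * B
    dA = -v_uptake
    dB = v_arginase - v_odc - v_export
    dC = v_uptake - v_arginase - v_nos
    return np.array([dA, dB, dC])


def integrate_model(
    model: ModelSpec,
    params: np.ndarray,
    times: np.ndarray,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    observed_only: bool = True,
) -> Trajectory:
    """Integrate ``model`` at ``params`` and sample it on ``times``.

    Uses LSODA (adaptive, stiff-capable, automatic method switching).
    Integration always starts from the model's initial state at t = 0;
    if ``times[0] > 0`` the grid is extended internally.  Deterministic
    for fixed inputs.

    Raises :class:`IntegrationError` on solver failure or non-finite
    output; optimizers map this to an infinite fitness.
    """
    times = np.asarray(times, float)
    params = np.asarray(params, float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.all(np.isfinite(params)):
        raise IntegrationError("non-finite parameter vector", params)

    prepend = times[0] > 0.0
    grid = np.concatenate(([0.0], times)) if prepend else times

    def f(y, t):
        return model.rhs(y, params, t, model.input_signal)

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # failed candidate vectors are expected during optimization; the
        # failure is reported through IntegrationError instead
        warnings.simplefilter("ignore")
        sol, info = odeint(
            f, model.initial_state, grid, rtol=rtol, atol=atol,
            full_output=True, mxstep=10_000,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
        raise IntegrationError(f"ODE solver failed: {info['message']}", params)
    if prepend:
        sol = sol[1:]

    if sol.min() < -10.0 * atol:
        logger.warning(
            "model %s produced negative concentrations (min %.3g); "
            "concentrations cannot be negative", model.name, sol.min(),
        )
    if observed_only:
        sol = sol[:, list(model.observed_indices)]
    return Trajectory(times=times, states=sol)


def apply_perturbation(
    model: ModelSpec,
    params: np.ndarray,
    overrides: Mapping[str, float],
    *,
    name: str | None = None,
) -> tuple[ModelSpec, np.ndarray]:
    """Return a copy of ``(model, params)`` with named parameters overridden.

    The base model and vector are left unmodified.  Unknown labels raise
    ``KeyError``.  Applying the same override map twice is idempotent.
    """
    params = np.array(params, float, copy=True)
    for label, value in overrides.items():
        params[model.param_index(label)] = float(value)
    spec = replace(model, name=name or model.name)
    return spec, params


# ---------------------------------------------------------------------------
# Built-in model registry
# ---------------------------------------------------------------------------

# Reference rate constants for the p53-Mdm2 loop.  The study tables do not
# print the generating values, so these are synthetic defaults chosen to
# give the loop its characteristic damped relaxation toward the negative-
# feedback steady state over the default horizon, with comparable dynamic
# ranges for all four species (concentrations O(1) in scaled units), so an
# unweighted least-squares objective treats every species evenly.
_P53_NOMINAL = np.array([1.0, 0.2, 2.0, 0.2, 1.0, 1.0, 2.0, 1.0, 1.0])
_P53_X0 = np.array([1.0, 0.2, 0.1, 0.1])

# Arginine catabolism reference set F1 (printed parameter table).
_ARG_F1 = np.array(
    [70.0, 160.5, 380.0, 847.0, 420.0, 420.0, 110.0, 1500.0,
     1000.0, 0.013, 60.0, 1.33, 16.0, 160.5, 380.0, 847.0]
)
# Initial concentrations (uM): plasma arginine, cell ornithine, cell arginine.
_ARG_X0 = np.array([500.0, 300.0, 200.0])

_P53_BASE = ModelSpec(
    name="p53_E1",
    state_names=("A", "B", "C", "D"),
    param_names=tuple(f"k{i}" for i in range(1, 10)),
    rhs=p53_rhs,
    initial_state=_P53_X0,
    observed_indices=(0, 1, 2, 3),
    default_bounds=np.column_stack([np.zeros(9), np.full(9, 5.0)]),
    default_horizon=30.0,
    nominal_params=_P53_NOMINAL,
)

_ARG_BASE = ModelSpec(
    name="arginine_F1",
    state_names=("A", "B", "C"),
    param_names=tuple(f"k{i}" for i in range(1, 17)),
    rhs=arginine_rhs,
    initial_state=_ARG_X0,
    observed_indices=(1, 2),
    default_bounds=np.column_stack([np.zeros(16), 10.0 * np.maximum(_ARG_F1, 1.0)]),
    default_horizon=5.0,
    nominal_params=_ARG_F1,
)

#: Knockout / override maps defining the perturbed variants.
VARIANT_OVERRIDES: dict[str, tuple[str, dict[str, float]]] = {
    "p53_E1": ("p53_E1", {}),
    "p53_E2": ("p53_E1", {"k4": 0.0, "k9": 0.0}),
    "arginine_F1": ("arginine_F1", {}),
    "arginine_F2": ("arginine_F1", {"k7": 0.0}),
    "arginine_F3": ("arginine_F1", {"k8": 100.0, "k15": 1.0, "k16": 1.0}),
    "arginine_F4": ("arginine_F1", {"k7": 1.0, "k10": 1.0, "k14": 1.0, "k15": 1.0}),
    "arginine_F5": ("arginine_F1", {"k2": 1.0, "k5": 1.0, "k8": 1.0, "k15": 1.0, "k16": 1.0}),
}

_BASES = {"p53_E1": _P53_BASE, "arginine_F1": _ARG_BASE}


def list_models() -> list[str]:
    """Names of all registered model variants."""
    return sorted(VARIANT_OVERRIDES)


def get_model(name: str) -> tuple[ModelSpec, np.ndarray]:
    """Look up a registered variant.

    Returns the :class:`ModelSpec` (renamed to the variant) and the
    variant's nominal parameter vector (the base reference set with the
    variant's overrides applied).
    """
    try:
        base_name, overrides = VARIANT_OVERRIDES[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {', '.join(list_models())}"
        ) from None
    base = _BASES[base_name]
    spec, params = apply_perturbation(base, base.nominal_params, overrides, name=name)
    spec = replace(spec, nominal_params=params)
    return spec, params
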