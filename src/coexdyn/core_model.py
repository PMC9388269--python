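"""Core model definitions: parameters, states, incidence terms, and vector fields.

The model partitions a population of size ``N`` into seven compartments:

========  =====================================================
symbol    meaning
========  =====================================================
``S``     susceptible to both contagions
``C``     corrupted
``R``     racist
``C1``    co-affected (both corrupted and racist)
``R1``    recovered from corruption
``R2``    recovered from racism
``R3``    recovered from both simultaneously
========  =====================================================

Corruption spreads by standard incidence, ``lambda_C = (beta/N)(C + omega1*C1)``,
while racism spreads by mass action, ``lambda_R = alpha*(R + omega2*C1)``.
The co-affected class is fed by cross-infection of singly affected individuals
(modified by ``eta`` and ``xi``) and drains back into the single classes at
rates ``sigma1``/``sigma2`` or recovers at ``gamma3``.  Recovered individuals
lose their protection at rates ``theta1``–``theta3``.  Recruitment ``Lambda``
enters ``S``; every compartment is removed at the natural rate ``mu``, so the
total obeys ``dN/dt = Lambda - mu*N`` identically.  Rates are per year.

Two reduced systems are exposed besides the full model: the racism-only
submodel on (S, R, R2) and the corruption-only submodel on (S, C, R1).  Both
use the same 7-vector state layout with the absent compartments pinned to zero.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import yaml

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "Parameters",
    "ForceOfInfection",
    "ModelId",
    "ParameterError",
    "active_indices",
    "validate_parameters",
    "reference_parameters",
    "load_parameters",
    "dump_parameters",
    "as_state",
    "pin_absent",
    "forces_of_infection",
    "rhs",
]

PARAM_NAMES = (
    "Lambda", "mu", "alpha", "beta", "omega1", "omega2", "eta", "xi",
    "sigma1", "sigma2", "gamma1", "gamma2", "gamma3",
    "theta1", "theta2", "theta3",
)

STATE_NAMES = ("S", "C", "R", "C1", "R1", "R2", "R3")

#: solver round-off slack: components in [-ROUNDOFF_SLACK, 0) are clipped to 0
#: before incidence terms are evaluated.
ROUNDOFF_SLACK = 1e-9


class ParameterError(ValueError):
    """A parameter set violates the model's sign or range constraints."""


class ModelId(str, Enum):
    """Which vector field: the full coupled system or a single-contagion submodel."""

    FULL = "full"
    RACISM = "racism"
    CORRUPTION = "corruption"


#: compartments that participate in each (sub)model, as indices into STATE_NAMES
_ACTIVE = {
    ModelId.FULL: (0, 1, 2, 3, 4, 5, 6),
    ModelId.RACISM: (0, 2, 5),       # S, R, R2
    ModelId.CORRUPTION: (0, 1, 4),   # S, C, R1
}


def as_model_id(model_id: Union[str, ModelId]) -> ModelId:
    return ModelId(model_id)


def active_indices(model_id: Union[str, ModelId]) -> tuple[int, ...]:
    """Indices of the compartments a (sub)model actually evolves."""
    return _ACTIVE[as_model_id(model_id)]


@dataclass(frozen=True)
class Parameters:
    """The sixteen nonnegative model rates.

    Parameters
    ----------
    Lambda : recruitment rate into S (individuals / year); must be positive.
    mu : natural removal rate (1 / year); must be positive.
    alpha : racism transmission coefficient (1 / (individual * year), mass action).
    beta : corruption transmission coefficient (1 / year, standard incidence).
    omega1, omega2 : infectivity modification of the co-affected class in the
        corruption / racism incidence; both >= 1.
    eta, xi : modification of coexistence acquisition by the already racist /
        already corrupted (dimensionless).
    sigma1, sigma2 : reversion rates from the co-affected class back to C / R.
    gamma1, gamma2, gamma3 : recovery rates from corruption / racism / both.
    theta1, theta2, theta3 : rates at which R1 / R2 / R3 become susceptible again.
    """

    Lambda: float
    mu: float
    alpha: float
    beta: float
    omega1: float
    omega2: float
    eta: float
    xi: float
    sigma1: float
    sigma2: float
    gamma1: float
    gamma2: float
    gamma3: float
    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ParameterError(f"{name} must be finite, got {value!r}")
            object.__setattr__(self, name, float(value))
            if value < 0:
                raise ParameterError(f"{name} must be nonnegative, got {value}")
        if self.Lambda <= 0:
            raise ParameterError(f"Lambda must be positive, got {self.Lambda}")
        if self.mu <= 0:
            raise ParameterError(f"mu must be positive, got {self.mu}")
        for name in ("omega1", "omega2"):
            if getattr(self, name) < 1:
                raise ParameterError(
                    f"{name} must be >= 1 (it amplifies infectivity), got {getattr(self, name)}"
                )

    def replace(self, **changes: float) -> "Parameters":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)


def validate_parameters(params: Union[Parameters, Mapping[str, float]]) -> Parameters:
    """Coerce a mapping (or pass through a Parameters) and enforce all invariants.

    Raises :class:`ParameterError` naming the offending field, or listing
    missing / unknown keys for a mapping input.
    """
    if isinstance(params, Parameters):
        return Parameters(**params.as_dict())
    keys = set(params)
    missing = [n for n in PARAM_NAMES if n not in keys]
    unknown = sorted(keys - set(PARAM_NAMES))
    if missing:
        raise ParameterError(f"missing parameter keys: {', '.join(missing)}")
    if unknown:
        raise ParameterError(f"unknown parameter keys: {', '.join(unknown)}")
    return Parameters(**{n: float(params[n]) for n in PARAM_NAMES})


def reference_parameters(
    alpha: float,
    beta: float,
    omega1: float = 1.0,
    omega2: float = 1.0,
) -> Parameters:
    """The reference parameter set used throughout, with user-chosen transmission rates.

    The fixed rates are Lambda=50, mu=0.01, sigma1=0.6, sigma2=0.7, eta=1.3,
    xi=1.2, theta1=0.3, theta2=0.25, theta3=0.2, gamma1=0.007, gamma2=0.006,
    gamma3=0.008.  The transmission rates alpha and beta are free, and the
    infectivity modifications default to 1 (no amplification).
    """
    return Parameters(
        Lambda=50.0, mu=0.01, alpha=alpha, beta=beta,
        omega1=omega1, omega2=omega2, eta=1.3, xi=1.2,
        sigma1=0.6, sigma2=0.7, gamma1=0.007, gamma2=0.006, gamma3=0.008,
        theta1=0.3, theta2=0.25, theta3=0.2,
    )


def load_parameters(path: Union[str, Path]) -> Parameters:
    """Read a parameter config (YAML or JSON) with exactly the 16 rate keys."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ParameterError(f"config {path} must be a mapping of parameter names to numbers")
    return validate_parameters(raw)


def dump_parameters(params: Parameters, path: Union[str, Path]) -> None:
    """Write a parameter set as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = params.as_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class ForceOfInfection:
    """Per-susceptible acquisition rates (1 / year)."""

    lambda_C: float  # corruption, standard incidence
    lambda_R: float  # racism, mass action by default


def as_state(state) -> np.ndarray:
    """Coerce a state to a float 7-vector (accepts mappings keyed by STATE_NAMES)."""
    if isinstance(state, Mapping):
        state = [state.get(name, 0.0) for name in STATE_NAMES]
    arr = np.asarray(state, dtype=float)
    if arr.shape != (7,):
        raise ValueError(f"state must have 7 components {STATE_NAMES}, got shape {arr.shape}")
    return arr


def pin_absent(model_id: Union[str, ModelId], state: np.ndarray) -> np.ndarray:
    """Zero the compartments a submodel does not evolve."""
    model_id = as_model_id(model_id)
    if model_id is ModelId.FULL:
        return state
    out = np.zeros(7)
    idx = list(_ACTIVE[model_id])
    out[idx] = state[idx]
    return out


def _clip_roundoff(state: np.ndarray) -> np.ndarray:
    out = state.copy()
    mask = (out < 0) & (out >= -ROUNDOFF_SLACK)
    out[mask] = 0.0
    return out


def forces_of_infection(
    state,
    params: Parameters,
    racism_incidence: str = "mass_action",
) -> ForceOfInfection:
    """Incidence terms at a state.

    ``lambda_C = (beta/N)(C + omega1*C1)`` with ``N`` the live 7-compartment sum
    (defined as 0 when ``N = 0``: no population, no contact), and
    ``lambda_R = alpha*(R + omega2*C1)``.  Setting ``racism_incidence="standard"``
    divides the racism term by ``N`` as well (an exploratory variant; the model's
    default is mass action).
    """
    y = _clip_roundoff(as_state(state))
    N = float(y.sum())
    _, C, R, C1 = y[0], y[1], y[2], y[3]
    lam_C = 0.0 if N <= 0 else params.beta * (C + params.omega1 * C1) / N
    lam_R = params.alpha * (R + params.omega2 * C1)
    if racism_incidence == "standard":
        lam_R = 0.0 if N <= 0 else lam_R / N
    elif racism_incidence != "mass_action":
        raise ValueError(f"racism_incidence must be 'mass_action' or 'standard', got {racism_incidence!r}")
    return ForceOfInfection(lambda_C=lam_C, lambda_R=lam_R)


def rhs(
    model_id: Union[str, ModelId],
    state,
    params: Parameters,
    racism_incidence: str = "mass_action",
) -> np.ndarray:
    """Time derivative of the 7-vector state under the chosen (sub)model.

    For submodels the absent compartments are pinned to zero and their
    derivatives are returned as zero.  The components always sum to
    ``Lambda - mu*N`` (every transfer term cancels).
    """
    model_id = as_model_id(model_id)
    y = as_state(state)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state must be finite, got {y}")
    y = pin_absent(model_id, _clip_roundoff(y))
    foi = forces_of_infection(y, params, racism_incidence=racism_incidence)
    lam_C, lam_R = foi.lambda_C, foi.lambda_R
    p = params
    S, C, R, C1, R1, R2, R3 = y
    d = np.empty(7)
    d[0] = p.Lambda + p.theta1 * R1 + p.theta2 * R2 + p.theta3 * R3 - (lam_R + lam_C + p.mu) * S
    d[1] = lam_C * S + p.sigma1 * C1 - (p.gamma1 + p.xi * lam_R + p.mu) * C
    d[2] = lam_R * S + p.sigma2 * C1 - (p.eta * lam_C + p.gamma2 + p.mu) * R
    d[3] = p.eta * lam_C * R + p.xi * lam_R * C - (p.sigma2 + p.gamma3 + p.sigma1 + p.mu) * C1
    d[4] = p.gamma1 * C - (p.theta1 + p.mu) * R1
    d[5] = p.gamma2 * R - (p.theta2 + p.mu) * R2
    d[6] = p.gamma3 * C1 - (p.theta3 + p.mu) * R3
    if model_id is not ModelId.FULL:
        keep = np.zeros(7, dtype=bool)
        keep[list(_ACTIVE[model_id])] = True
        d[~keep] = 0.0
    return d
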