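"""Next-generation matrices and basic reproduction numbers.

At the contagion-free equilibrium ``S0 = Lambda/mu`` the linearized inflow of
new infections (F) and the transfers among infected compartments (V) give the
next-generation matrix ``K = F V^{-1}``; its spectral radius is the basic
reproduction number.  Closed forms:

* racism (mass action):   ``R_r = Lambda*alpha / ((gamma2+mu)*mu)``
* corruption (standard):  ``R_c = beta / (gamma1+mu)``
* full coupled model:     ``R_rc = max(R_r, R_c)``

The full-model matrices are 3x3 over the infected compartments ordered
(C, R, C1); the submodel matrices are 2x2 over (C, R1) and (R, R2).  The
spectral radius is ordering-invariant but the stored matrices are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .core_model import ModelId, Parameters, as_model_id, validate_parameters

__all__ = ["NGMResult", "ngm_matrices", "closed_form_r0", "reproduction_number"]


@dataclass(frozen=True)
class NGMResult:
    """Next-generation-matrix decomposition for one (sub)model."""

    model_id: ModelId
    F: np.ndarray
    V: np.ndarray
    K: np.ndarray
    spectral_radius: float
    closed_form: float


def _susceptible_dfe(params: Parameters) -> float:
    return params.Lambda / params.mu


def ngm_matrices(
    model_id: Union[str, ModelId],
    params: Parameters,
    racism_incidence: str = "mass_action",
) -> tuple[np.ndarray, np.ndarray]:
    """New-infection matrix F and transition matrix V at the model's DFE."""
    model_id = as_model_id(model_id)
    p = validate_parameters(params)
    S0 = _susceptible_dfe(p)
    # At the DFE N = S0, so the mass-action racism gradient is alpha*S0 while
    # the standard-incidence variant reduces to alpha.
    a_r = p.alpha * S0 if racism_incidence == "mass_action" else p.alpha
    if model_id is ModelId.RACISM:
        F = np.array([[a_r, 0.0], [0.0, 0.0]])
        V = np.array([[p.gamma2 + p.mu, 0.0], [-p.gamma2, p.theta2 + p.mu]])
    elif model_id is ModelId.CORRUPTION:
        F = np.array([[p.beta, 0.0], [0.0, 0.0]])
        V = np.array([[p.gamma1 + p.mu, 0.0], [-p.gamma1, p.theta1 + p.mu]])
    else:
        F = np.array([
            [p.beta, 0.0, p.beta * p.omega1],
            [0.0, a_r, a_r * p.omega2],
            [0.0, 0.0, 0.0],
        ])
        V = np.array([
            [p.gamma1 + p.mu, 0.0, -p.sigma1],
            [0.0, p.gamma2 + p.mu, -p.sigma2],
            [0.0, 0.0, p.sigma2 + p.gamma3 + p.sigma1 + p.mu],
        ])
    return F, V


def closed_form_r0(
    model_id: Union[str, ModelId],
    params: Parameters,
    racism_incidence: str = "mass_action",
) -> float:
    """The closed-form reproduction number for the chosen (sub)model."""
    model_id = as_model_id(model_id)
    p = params
    S0 = _susceptible_dfe(p)
    a_r = p.alpha * S0 if racism_incidence == "mass_action" else p.alpha
    r_r = a_r / (p.gamma2 + p.mu)
    r_c = p.beta / (p.gamma1 + p.mu)
    if model_id is ModelId.RACISM:
        return r_r
    if model_id is ModelId.CORRUPTION:
        return r_c
    return max(r_r, r_c)


def reproduction_number(
    model_id: Union[str, ModelId],
    params: Parameters,
    racism_incidence: str = "mass_action",
) -> NGMResult:
    """Spectral radius of F V^{-1} alongside the closed form (both recorded)."""
    model_id = as_model_id(model_id)
    p = validate_parameters(params)
    F, V = ngm_matrices(model_id, p, racism_incidence=racism_incidence)
    K = F @ np.linalg.inv(V)
    rho = float(np.max(np.abs(np.linalg.eigvals(K))))
    cf = closed_form_r0(model_id, p, racism_incidence=racism_incidence)
    return NGMResult(
        model_id=model_id, F=F, V=V, K=K, spectral_radius=rho, closed_form=cf
    )
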