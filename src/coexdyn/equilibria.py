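"""Equilibria: contagion-free point, submodel closed forms, full-model root finding.

At any equilibrium the total population is pinned at ``N* = Lambda/mu`` (the
component sum of the vector field is ``Lambda - mu*N``).  For each submodel
the equilibrium force of infection solves a scalar balance that is linear once
the trivial root is factored out:

* racism:     ``lambda_R* = (gamma2+mu)(theta2+mu)(R_r - 1) / (gamma2+theta2+mu)``
* corruption: ``lambda_C* = (gamma1+mu)(theta1+mu)(R_c - 1) / (gamma1+theta1+mu)``

each positive exactly when the corresponding reproduction number exceeds one.
The interior coexistence equilibrium of the full model has no tractable closed
form and is found by damped Newton iteration from integration-informed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import optimize

from .core_model import (
    ForceOfInfection,
    ModelId,
    Parameters,
    as_model_id,
    forces_of_infection,
    rhs,
    validate_parameters,
)
from .reproduction import closed_form_r0

__all__ = [
    "EquilibriumPoint",
    "CoexistenceResult",
    "NoEndemicEquilibrium",
    "residual_tolerance",
    "disease_free_equilibrium",
    "racism_endemic_equilibrium",
    "corruption_endemic_equilibrium",
    "coexistence_endemic_equilibrium",
]


class NoEndemicEquilibrium(ValueError):
    """Raised when an endemic equilibrium is requested below its threshold."""


@dataclass(frozen=True)
class EquilibriumPoint:
    model_id: ModelId
    state: np.ndarray
    residual: float           # max |rhs| re-evaluated at the point
    kind: str                 # dfe | racism_endemic | corruption_endemic | coexistence_endemic
    force_of_infection: ForceOfInfection


@dataclass
class CoexistenceResult:
    """Outcome of the interior coexistence search plus the boundary equilibria.

    ``interior`` is None when no positive root was found (``found = False``);
    ``best_residual`` then reports how close the search got.  ``racism_boundary``
    (E1*) and ``corruption_boundary`` (E2*) are the single-contagion endemic
    points embedded in 7 dimensions, present when their thresholds allow.
    """

    found: bool
    interior: Optional[EquilibriumPoint]
    best_residual: float
    racism_boundary: Optional[EquilibriumPoint]
    corruption_boundary: Optional[EquilibriumPoint]
    seeds_tried: list = field(default_factory=list)


def residual_tolerance(params: Parameters) -> float:
    return 1e-8 * max(1.0, params.Lambda / params.mu)


def _point(model_id: ModelId, state: np.ndarray, kind: str, params: Parameters) -> EquilibriumPoint:
    res = float(np.max(np.abs(rhs(model_id, state, params))))
    return EquilibriumPoint(
        model_id=model_id,
        state=state,
        residual=res,
        kind=kind,
        force_of_infection=forces_of_infection(state, params),
    )


def disease_free_equilibrium(model_id: Union[str, ModelId], params: Parameters) -> EquilibriumPoint:
    """The contagion-free point (Lambda/mu, 0, ..., 0); an equilibrium of every (sub)model."""
    model_id = as_model_id(model_id)
    p = validate_parameters(params)
    state = np.zeros(7)
    state[0] = p.Lambda / p.mu
    return _point(model_id, state, "dfe", p)


def racism_endemic_equilibrium(params: Parameters) -> EquilibriumPoint:
    """Closed-form endemic point of the racism-only submodel; requires R_r > 1."""
    p = validate_parameters(params)
    r = closed_form_r0(ModelId.RACISM, p)
    if r <= 1:
        raise NoEndemicEquilibrium(
            f"racism submodel has no endemic equilibrium: R_r = {r:.6g} <= 1"
        )
    g2m, t2m = p.gamma2 + p.mu, p.theta2 + p.mu
    lam = g2m * t2m * (r - 1) / (p.gamma2 + p.theta2 + p.mu)
    D = (lam + p.mu) * t2m * g2m - p.theta2 * p.gamma2 * lam
    S = p.Lambda * t2m * g2m / D
    R = p.Lambda * lam * t2m / D
    R2 = p.gamma2 * R / t2m
    state = np.zeros(7)
    state[0], state[2], state[5] = S, R, R2
    return _point(ModelId.RACISM, state, "racism_endemic", p)


def corruption_endemic_equilibrium(params: Parameters) -> EquilibriumPoint:
    """Closed-form endemic point of the corruption-only submodel; requires R_c > 1.

    Derived from the balance ``(gamma1+mu) + lambda_C (1 + gamma1/(theta1+mu)) = beta``
    (standard incidence with N* = Lambda/mu at equilibrium).
    """
    p = validate_parameters(params)
    r = closed_form_r0(ModelId.CORRUPTION, p)
    if r <= 1:
        raise NoEndemicEquilibrium(
            f"corruption submodel has no endemic equilibrium: R_c = {r:.6g} <= 1"
        )
    g1m, t1m = p.gamma1 + p.mu, p.theta1 + p.mu
    lam = g1m * t1m * (r - 1) / (p.gamma1 + p.theta1 + p.mu)
    N = p.Lambda / p.mu
    C = lam * N / p.beta          # lambda_C = beta*C/N
    S = g1m * C / lam             # inflow balance of the corrupted class
    R1 = p.gamma1 * C / t1m
    state = np.zeros(7)
    state[0], state[1], state[4] = S, C, R1
    return _point(ModelId.CORRUPTION, state, "corruption_endemic", p)


def _embed_boundary(point: EquilibriumPoint, params: Parameters, kind: str) -> EquilibriumPoint:
    # the submodel endemic states are already 7-vectors; re-evaluate under the full rhs
    return EquilibriumPoint(
        model_id=ModelId.FULL,
        state=point.state,
        residual=float(np.max(np.abs(rhs(ModelId.FULL, point.state, params)))),
        kind=kind,
        force_of_infection=forces_of_infection(point.state, params),
    )


def _newton_seeds(params: Parameters, guess: Optional[np.ndarray]) -> list[np.ndarray]:
    from .simulate import default_initial_state, integrate  # deferred: avoid cycle

    p = params
    N0 = p.Lambda / p.mu
    seeds: list[np.ndarray] = []
    if guess is not None:
        seeds.append(np.asarray(guess, dtype=float))
    # (i) long-time state of the simulator from the demo initial condition
    try:
        traj = integrate(ModelId.FULL, p, default_initial_state(p), t_end=5000.0)
        seeds.append(traj.states[-1])
    except Exception:
        pass
    # (ii) combinations of the submodel endemic points
    boundary = []
    for fn in (racism_endemic_equilibrium, corruption_endemic_equilibrium):
        try:
            boundary.append(fn(p).state)
        except NoEndemicEquilibrium:
            pass
    seeds.extend(boundary)
    if len(boundary) == 2:
        seeds.append(0.5 * (boundary[0] + boundary[1]))
    # a mildly infected interior point as a last resort
    mix = np.full(7, 0.02 * N0)
    mix[0] = 0.86 * N0
    seeds.append(mix)
    return seeds


def coexistence_endemic_equilibrium(
    params: Parameters,
    guess: Optional[np.ndarray] = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> CoexistenceResult:
    """Search for the interior equilibrium of the full model.

    Damped Newton (scipy's modified Powell hybrid) from a schedule of seeds:
    an integrated long-time state, the submodel boundary equilibria and their
    mixture, an optional user guess, and ``n_restarts`` seeded log-normal
    perturbations of each.  A root is accepted when every compartment is
    strictly positive and the independently re-evaluated residual is below
    ``1e-8 * max(1, Lambda/mu)``.  Failure returns a not-found result (with the
    best residual seen), never an exception.
    """
    p = validate_parameters(params)
    tol = residual_tolerance(p)
    rng = np.random.default_rng(seed)

    def fun(y: np.ndarray) -> np.ndarray:
        return rhs(ModelId.FULL, np.abs(y), p)

    base_seeds = _newton_seeds(p, guess)
    all_seeds: list[np.ndarray] = list(base_seeds)
    for s in base_seeds[: max(1, len(base_seeds))]:
        for _ in range(max(0, n_restarts) // max(1, len(base_seeds)) + 1):
            jitter = rng.lognormal(mean=0.0, sigma=0.3, size=7)
            all_seeds.append(np.maximum(s, 1e-8) * jitter)
    all_seeds = all_seeds[: len(base_seeds) + n_restarts]

    best_res = np.inf
    best_state = None
    tried = []
    for s0 in all_seeds:
        tried.append(np.asarray(s0))
        sol = optimize.root(fun, s0, method="hybr", tol=1e-12)
        y = np.abs(sol.x)
        res = float(np.max(np.abs(rhs(ModelId.FULL, y, p))))
        if res < best_res:
            best_res, best_state = res, y
        # positivity floor well above round-off so boundary roots (some
        # compartments numerically zero) are not mistaken for interior ones
        if res <= tol and np.all(y > 1e-9 * max(1.0, p.Lambda / p.mu)):
            point = _point(ModelId.FULL, y, "coexistence_endemic", p)
            return CoexistenceResult(
                found=True,
                interior=point,
                best_residual=res,
                racism_boundary=_boundary_or_none(p, racism_endemic_equilibrium, "racism_boundary"),
                corruption_boundary=_boundary_or_none(p, corruption_endemic_equilibrium, "corruption_boundary"),
                seeds_tried=tried,
            )
    # no strictly positive interior root found
    return CoexistenceResult(
        found=False,
        interior=None,
        best_residual=best_res if best_state is not None else np.inf,
        racism_boundary=_boundary_or_none(p, racism_endemic_equilibrium, "racism_boundary"),
        corruption_boundary=_boundary_or_none(p, corruption_endemic_equilibrium, "corruption_boundary"),
        seeds_tried=tried,
    )


def _boundary_or_none(params, fn, kind) -> Optional[EquilibriumPoint]:
    try:
        return _embed_boundary(fn(params), params, kind)
    except NoEndemicEquilibrium:
        return None
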