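"""Local stability (Jacobian spectra, Routh-Hurwitz) and sampled global checks.

Local stability of an equilibrium is read off the eigenvalues of the exact
Jacobian (symbolically generated, numerically evaluated).  For the
single-contagion submodels the endemic cubic can also be judged by the
Routh-Hurwitz array, and the contagion-free point admits a Lyapunov-style
derivative bound on the invariant region Omega = {x >= 0, N <= Lambda/mu}
that is verified here by seeded sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ._symbolic import jacobian_full
from .core_model import (
    ModelId,
    Parameters,
    active_indices,
    as_model_id,
    as_state,
    pin_absent,
    validate_parameters,
)
from .equilibria import disease_free_equilibrium
from .reproduction import closed_form_r0

__all__ = [
    "StabilityReport",
    "RouthHurwitzTable",
    "jacobian",
    "classify_local",
    "routh_hurwitz_cubic",
    "racism_endemic_cubic",
    "dfe_stability",
    "LyapunovCheck",
    "lyapunov_gas_check",
]

#: default tolerance (relative to the spectral radius) below which a real part
#: counts as zero when classifying a spectrum
DEFAULT_ZERO_TOLERANCE = 1e-8


@dataclass(frozen=True)
class RouthHurwitzTable:
    """Routh array for a cubic a0*l^3 + a1*l^2 + a2*l + a3."""

    a0: float
    a1: float
    a2: float
    a3: float
    b1: Optional[float]            # (a1*a2 - a0*a3)/a1; None when a1 == 0
    c1: float                      # equals a3
    first_column: tuple
    verdict: str                   # stable | unstable | indeterminate


@dataclass(frozen=True)
class StabilityReport:
    model_id: ModelId
    point: np.ndarray
    eigenvalues: np.ndarray
    classification: str            # asymptotically_stable | unstable | marginal
    zero_tolerance: float
    routh_hurwitz: Optional[RouthHurwitzTable] = None


def jacobian(
    model_id: Union[str, ModelId],
    state,
    params: Parameters,
) -> np.ndarray:
    """Exact Jacobian of the (sub)model vector field at a state.

    Full model: 7x7.  Submodels: the 3x3 block over the active compartments,
    evaluated with the absent compartments pinned to zero (the restriction of
    the full Jacobian, since the pinned faces are invariant).
    """
    model_id = as_model_id(model_id)
    p = validate_parameters(params)
    y = pin_absent(model_id, as_state(state))
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state must be finite, got {y}")
    J = jacobian_full(y, p)
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian has non-finite entries (is the total population zero?)")
    if model_id is ModelId.FULL:
        return J
    idx = np.array(active_indices(model_id))
    return J[np.ix_(idx, idx)]


def classify_local(eigenvalues: Sequence[complex], zero_tolerance: float) -> str:
    """Classify a spectrum: stable iff all real parts < -tol; marginal iff the
    largest real part sits within +/-tol of zero; unstable otherwise."""
    eig = np.asarray(list(eigenvalues), dtype=complex)
    if eig.size == 0:
        raise ValueError("cannot classify an empty spectrum")
    re = eig.real
    if np.all(re < -zero_tolerance):
        return "asymptotically_stable"
    if np.any(re > zero_tolerance):
        return "unstable"
    return "marginal"


def routh_hurwitz_cubic(a0: float, a1: float, a2: float, a3: float) -> RouthHurwitzTable:
    """Routh-Hurwitz array and verdict for a cubic with a0 > 0.

    Stable iff a1 > 0, a3 > 0 and a1*a2 > a0*a3.  A zero pivot (a1 = 0) yields
    an explicit ``indeterminate`` verdict rather than an epsilon perturbation.
    """
    if a0 <= 0:
        raise ValueError(f"leading coefficient a0 must be positive, got {a0}")
    if a1 == 0:
        return RouthHurwitzTable(
            a0=a0, a1=a1, a2=a2, a3=a3, b1=None, c1=a3,
            first_column=(a0, a1), verdict="indeterminate",
        )
    b1 = (a1 * a2 - a0 * a3) / a1
    c1 = a3
    column = (a0, a1, b1, c1)
    stable = a1 > 0 and a3 > 0 and a1 * a2 > a0 * a3
    return RouthHurwitzTable(
        a0=a0, a1=a1, a2=a2, a3=a3, b1=b1, c1=c1,
        first_column=column,
        verdict="stable" if stable else "unstable",
    )


def racism_endemic_cubic(params: Parameters) -> tuple[float, float, float, float]:
    """Characteristic-cubic coefficients of the racism submodel at its endemic point.

    Built from the Jacobian entries (A, B, C, D, E, F with the theta2 coupling)
    rather than from an eigendecomposition, so the Routh-Hurwitz verdict can be
    cross-checked against the spectrum independently:
    a1 = -(A+D+F), a2 = AF + DF - BC + AD, a3 = -(ADF + E*C*theta2 - BCF)
    (the constant term is minus the determinant of the 3x3 Jacobian).
    """
    from .equilibria import racism_endemic_equilibrium

    p = validate_parameters(params)
    point = racism_endemic_equilibrium(p)
    J = jacobian(ModelId.RACISM, point.state, p)   # rows/cols ordered (S, R, R2)
    A, B, th2 = J[0, 0], J[0, 1], J[0, 2]
    Cc, D = J[1, 0], J[1, 1]
    E, F = J[2, 1], J[2, 2]
    a0 = 1.0
    a1 = -(A + D + F)
    a2 = A * F + D * F - B * Cc + A * D
    a3 = -(A * D * F + E * Cc * th2 - B * Cc * F)
    return a0, a1, a2, a3


def dfe_stability(
    model_id: Union[str, ModelId],
    params: Parameters,
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE,
) -> StabilityReport:
    """Stability report at the model's contagion-free equilibrium.

    By the threshold theorem the verdict agrees with the reproduction number:
    asymptotically stable when R < 1, unstable when R > 1.
    """
    model_id = as_model_id(model_id)
    p = validate_parameters(params)
    point = disease_free_equilibrium(model_id, p)
    J = jacobian(model_id, point.state, p)
    eig = np.linalg.eigvals(J)
    tol = zero_tolerance * max(1.0, float(np.max(np.abs(eig))))
    return StabilityReport(
        model_id=model_id,
        point=point.state,
        eigenvalues=eig,
        classification=classify_local(eig, tol),
        zero_tolerance=tol,
    )


@dataclass(frozen=True)
class LyapunovCheck:
    model_id: ModelId
    reproduction_number: float
    n_samples: int
    seed: int
    passed: bool
    worst_margin: float       # max of (d(infected)/dt - certificate bound); <= 0 always on Omega
    worst_decrease: float     # max of d(infected)/dt itself; <= 0 iff the contagion is dying out
    n_violations: int         # samples where either quantity is positive


def _sample_omega(rng: np.random.Generator, n: int, total: float, dims: int) -> np.ndarray:
    # uniform over the simplex {x >= 0, sum(x) <= total}: Dirichlet(1,...,1)
    # with one slack coordinate, scaled
    d = rng.dirichlet(np.ones(dims + 1), size=n)[:, :dims]
    return d * total


def lyapunov_gas_check(
    model_id: Union[str, ModelId],
    params: Parameters,
    n_samples: int = 10000,
    seed: int = 0,
) -> LyapunovCheck:
    """Sampled verification of the sub-threshold Lyapunov derivative bound.

    On Omega the racism submodel satisfies dR/dt <= (gamma2+mu)(R_r - 1) R
    (because alpha*S <= alpha*Lambda/mu) and the corruption submodel satisfies
    dC/dt <= (gamma1+mu)(R_c - 1) C (because S/N <= 1).  These certificate
    inequalities hold on Omega for every parameter set; what changes sign at
    the threshold is their consequence, the Lyapunov decrease
    d(infected)/dt <= 0, which below threshold follows from the certificate
    and above threshold fails at some sampled states (reported, not raised).
    Both worst margins are returned; ``passed`` requires both to be
    nonpositive at every sample.  The full model is unsupported (the bound is
    only available for the submodels).
    """
    model_id = as_model_id(model_id)
    if model_id is ModelId.FULL:
        raise ValueError("lyapunov_gas_check supports only the single-contagion submodels")
    p = validate_parameters(params)
    rng = np.random.default_rng(seed)
    total = p.Lambda / p.mu
    X = _sample_omega(rng, int(n_samples), total, dims=3)
    if model_id is ModelId.RACISM:
        S, R = X[:, 0], X[:, 1]
        r = closed_form_r0(model_id, p)
        ddt = p.alpha * R * S - (p.gamma2 + p.mu) * R
        bound = (p.gamma2 + p.mu) * (r - 1.0) * R
    else:
        S, C, R1 = X[:, 0], X[:, 1], X[:, 2]
        r = closed_form_r0(model_id, p)
        N = S + C + R1
        lamC = np.where(N > 0, p.beta * C / np.where(N > 0, N, 1.0), 0.0)
        ddt = lamC * S - (p.gamma1 + p.mu) * C
        bound = (p.gamma1 + p.mu) * (r - 1.0) * C
    margins = ddt - bound
    slack = 1e-12 * max(1.0, total)
    violations = int(np.sum((margins > slack) | (ddt > slack)))
    return LyapunovCheck(
        model_id=model_id,
        reproduction_number=r,
        n_samples=int(n_samples),
        seed=int(seed),
        passed=violations == 0,
        worst_margin=float(np.max(margins)),
        worst_decrease=float(np.max(ddt)),
        n_violations=violations,
    )
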