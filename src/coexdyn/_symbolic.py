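"""Symbolically generated derivatives of the vector field.

The Jacobian, the state Hessians of each component, and the mixed
state/``beta`` second partials are derived once with sympy and lambdified to
fast numpy callables (cached at module level).  Finite differences never back
these — they serve only as independent oracles in the test suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

from .core_model import PARAM_NAMES, Parameters

_STATE_SYMS = sp.symbols("S C R C1 R1 R2 R3", real=True)
_PARAM_SYMS = sp.symbols(" ".join(PARAM_NAMES), real=True)
_P = dict(zip(PARAM_NAMES, _PARAM_SYMS))


def vector_field_exprs() -> list[sp.Expr]:
    """The seven symbolic component functions of the full coupled model."""
    S, C, R, C1, R1, R2, R3 = _STATE_SYMS
    p = _P
    N = S + C + R + C1 + R1 + R2 + R3
    lam_C = p["beta"] * (C + p["omega1"] * C1) / N
    lam_R = p["alpha"] * (R + p["omega2"] * C1)
    return [
        p["Lambda"] + p["theta1"] * R1 + p["theta2"] * R2 + p["theta3"] * R3
        - (lam_R + lam_C + p["mu"]) * S,
        lam_C * S + p["sigma1"] * C1 - (p["gamma1"] + p["xi"] * lam_R + p["mu"]) * C,
        lam_R * S + p["sigma2"] * C1 - (p["eta"] * lam_C + p["gamma2"] + p["mu"]) * R,
        p["eta"] * lam_C * R + p["xi"] * lam_R * C
        - (p["sigma2"] + p["gamma3"] + p["sigma1"] + p["mu"]) * C1,
        p["gamma1"] * C - (p["theta1"] + p["mu"]) * R1,
        p["gamma2"] * R - (p["theta2"] + p["mu"]) * R2,
        p["gamma3"] * C1 - (p["theta3"] + p["mu"]) * R3,
    ]


@lru_cache(maxsize=None)
def _jacobian_func():
    f = sp.Matrix(vector_field_exprs())
    J = f.jacobian(sp.Matrix(_STATE_SYMS))
    return sp.lambdify((_STATE_SYMS, _PARAM_SYMS), J, modules="numpy")


@lru_cache(maxsize=None)
def _hessians_func():
    f = vector_field_exprs()
    hess = [
        [[sp.diff(fk, xi, xj) for xj in _STATE_SYMS] for xi in _STATE_SYMS]
        for fk in f
    ]
    return sp.lambdify((_STATE_SYMS, _PARAM_SYMS), hess, modules="numpy")


@lru_cache(maxsize=None)
def _beta_cross_func():
    f = vector_field_exprs()
    beta = _P["beta"]
    cross = [[sp.diff(fk, xi, beta) for xi in _STATE_SYMS] for fk in f]
    return sp.lambdify((_STATE_SYMS, _PARAM_SYMS), cross, modules="numpy")


def jacobian_full(state: np.ndarray, params: Parameters) -> np.ndarray:
    """Exact 7x7 Jacobian of the full model at a state with positive total."""
    J = _jacobian_func()(tuple(state), tuple(params.as_array()))
    return np.asarray(J, dtype=float)


def hessians_full(state: np.ndarray, params: Parameters) -> np.ndarray:
    """(7,7,7) array H[k,i,j] = d^2 f_k / dx_i dx_j at a state."""
    H = _hessians_func()(tuple(state), tuple(params.as_array()))
    return np.asarray(H, dtype=float)


def beta_cross_partials(state: np.ndarray, params: Parameters) -> np.ndarray:
    """(7,7) array M[k,i] = d^2 f_k / dx_i d(beta) at a state."""
    M = _beta_cross_func()(tuple(state), tuple(params.as_array()))
    return np.asarray(M, dtype=float)
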