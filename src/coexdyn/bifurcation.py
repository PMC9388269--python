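"""Center-manifold analysis at the corruption invasion threshold.

With the corruption transmission rate beta as the bifurcation parameter, the
contagion-free equilibrium loses a simple zero eigenvalue at
``beta* = gamma1 + mu`` (where R_c = 1), provided R_r < 1 so no second
eigenvalue sits on the axis.  The normal-form coefficients

    a = sum_k v_k u_i u_j d^2 f_k / dx_i dx_j        (full Hessian sums)
    b = sum_k v_k u_i     d^2 f_k / dx_i d(beta)

evaluated at the contagion-free point with beta = beta*, decide the branch
direction: a < 0 < b is a forward (supercritical) bifurcation -- the endemic
branch emerges into R_c > 1 and is locally stable there; a > 0 < b would be
backward.  Here the standard-incidence quotient terms make a strictly negative
whenever the null vectors have their expected signs, so the bifurcation is
forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._symbolic import beta_cross_partials, hessians_full, jacobian_full
from .core_model import ModelId, Parameters, validate_parameters
from .reproduction import closed_form_r0

__all__ = [
    "BifurcationResult",
    "critical_transmission_rate",
    "center_manifold_coefficients",
    "classify_bifurcation",
]


@dataclass(frozen=True)
class BifurcationResult:
    beta_star: float
    u: np.ndarray              # right null eigenvector of J(E0; beta*)
    v: np.ndarray              # left null eigenvector, scaled so v.u = 1
    a: float                   # second-order (curvature) coefficient
    b: float                   # transversality coefficient
    verdict: str               # forward | backward | transversality_failure
    eigenvalue_residual: float  # max of |J u| and |v^T J| relative to ||J||
    a_two_term: float          # the truncated two-term variant (audit only)
    b_times_beta: float        # beta* * v2 * u2 (audit only)


def critical_transmission_rate(params: Parameters) -> float:
    """beta* = gamma1 + mu, the corruption rate at which R_c crosses one."""
    p = validate_parameters(params)
    beta_star = p.gamma1 + p.mu
    r = closed_form_r0(ModelId.CORRUPTION, p.replace(beta=beta_star))
    assert abs(r - 1.0) <= 1e-12, "R_c at beta* must equal one"
    return beta_star


def classify_bifurcation(a: float, b: float) -> str:
    """forward if a < 0 < b; backward if a > 0 < b; otherwise the genericity
    condition b > 0 fails and the normal form does not apply."""
    if b <= 0:
        return "transversality_failure"
    return "forward" if a < 0 else "backward"


def center_manifold_coefficients(params: Parameters) -> BifurcationResult:
    """Null eigenvectors and normal-form coefficients at (E0, beta*).

    Requires R_r < 1 at beta = beta* so the zero eigenvalue is simple; when
    R_r = 1 as well the point is codimension-2 and an error is raised.  The
    right vector u is scaled so its corrupted component u2 = 1 > 0; the left
    vector v is scaled so v.u = 1.  Second partials come from the symbolically
    generated Hessians of the vector field evaluated at the contagion-free
    point.
    """
    p = validate_parameters(params)
    beta_star = critical_transmission_rate(p)
    p_star = p.replace(beta=beta_star)
    r_r = closed_form_r0(ModelId.RACISM, p_star)
    if abs(r_r - 1.0) <= 1e-10:
        raise ValueError(
            "codimension-2 point: R_r = 1 at beta = beta*, zero eigenvalue is not simple"
        )
    if r_r > 1:
        raise ValueError(
            f"center-manifold analysis requires R_r < 1 at beta*, got R_r = {r_r:.6g}"
        )

    x0 = np.zeros(7)
    x0[0] = p.Lambda / p.mu
    J = jacobian_full(x0, p_star)
    Jnorm = np.linalg.norm(J, 2)

    # null vectors of the (structurally exact) zero eigenvalue
    u = _null_vector(J)
    v = _null_vector(J.T)
    if u[1] < 0:
        u = -u
    u = u / u[1]                      # u2 = 1 > 0
    if v[1] < 0:
        v = -v
    v = v / float(v @ u)              # normalization v.u = 1

    resid = max(
        float(np.max(np.abs(J @ u))) / max(Jnorm, 1.0) / max(np.max(np.abs(u)), 1.0),
        float(np.max(np.abs(v @ J))) / max(Jnorm, 1.0) / max(np.max(np.abs(v)), 1.0),
    )

    H = hessians_full(x0, p_star)             # H[k,i,j]
    a = float(np.einsum("k,i,j,kij->", v, u, u, H))
    M = beta_cross_partials(x0, p_star)       # M[k,i]
    b = float(np.einsum("k,i,ki->", v, u, M))

    # audit-only variants: the truncated two-term curvature sum and beta*v2*u2
    a_two = float(2.0 * v[1] * u[1] * (u[0] * H[1, 0, 1] + u[2] * H[1, 2, 1]))
    b_beta = float(beta_star * v[1] * u[1])

    return BifurcationResult(
        beta_star=beta_star,
        u=u,
        v=v,
        a=a,
        b=b,
        verdict=classify_bifurcation(a, b),
        eigenvalue_residual=resid,
        a_two_term=a_two,
        b_times_beta=b_beta,
    )


def _null_vector(J: np.ndarray) -> np.ndarray:
    """Unit vector spanning the (simple) numerically-zero kernel of J (via SVD)."""
    _, _, Vt = np.linalg.svd(J)
    vec = Vt[-1]               # right-singular vector of the smallest singular value
    return vec / np.linalg.norm(vec)
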