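"""Generic sparse solver for Henderson's mixed-model equations.

Solves, for a model ``y = X b + sum_k Z_k u_k + e`` with ``u_k ~ N(0, G_k)``
and ``e ~ N(0, sigma2_e I)``, the system

    [ X'X   X'Z ] [ b ]   [ X'y ]
    [ Z'X   Z'Z + D ] [ u ] = [ Z'y ]

where the prior block for term *k* is ``D_k = lambda_k * P_k`` with
``lambda_k = sigma2_e / sigma2_k`` and ``P_k`` the (scaled) prior precision
of the term (identity for i.i.d. effects, the inverse numerator
relationship matrix for a pedigree animal effect).

The BLUE/BLUP solutions of this system coincide with generalized least
squares on the dense covariance ``V = sum_k sigma2_k Z_k P_k^-1 Z_k' +
sigma2_e I``; the test-suite oracles exploit that equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class SingularSystemError(RuntimeError):
    """Raised when the mixed-model equations cannot be solved."""


@dataclass
class RandomTerm:
    """One random effect: design matrix plus (optionally) a prior precision.

    ``prior_precision`` is the matrix multiplying ``lambda_k`` in the MME
    prior block; ``None`` means the identity (i.i.d. levels).
    """

    name: str
    Z: sp.spmatrix
    sigma2: float
    prior_precision: sp.spmatrix | None = None

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]


@dataclass
class MMESolution:
    fixed: np.ndarray
    random: dict[str, np.ndarray]
    relative_residual: float
    rhs: np.ndarray = field(repr=False, default=None)


def solve_mme(
    X: sp.spmatrix | np.ndarray,
    terms: list[RandomTerm],
    sigma2_e: float,
    y: np.ndarray,
    rtol: float = 1e-8,
) -> MMESolution:
    """Assemble and solve the mixed-model equations.

    Variances must be strictly positive (callers floor them); a numerically
    singular system raises :class:`SingularSystemError` naming the block
    whose diagonal degenerates.
    """
    y = np.asarray(y, dtype=float)
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be strictly positive")
    for t in terms:
        if t.sigma2 <= 0:
            raise ValueError(f"variance of term {t.name!r} must be strictly positive")

    X = sp.csr_matrix(X)
    blocks = [X] + [sp.csr_matrix(t.Z) for t in terms]
    W = sp.hstack(blocks, format="csr")
    M = (W.T @ W).tolil()
    off = X.shape[1]
    for t in terms:
        lam = sigma2_e / t.sigma2
        q = t.n_levels
        P = sp.identity(q, format="csr") if t.prior_precision is None else sp.csr_matrix(t.prior_precision)
        M[off : off + q, off : off + q] = M[off : off + q, off : off + q] + lam * P
        off += q
    M = M.tocsc()
    rhs = W.T @ y

    try:
        sol = spla.spsolve(M, rhs)
    except Exception as exc:  # pragma: no cover - scipy error paths vary
        raise SingularSystemError(_diagnose(M, X, terms)) from exc
    if not np.all(np.isfinite(sol)):
        raise SingularSystemError(_diagnose(M, X, terms))
    denom = max(float(np.linalg.norm(rhs)), 1e-30)
    rel = float(np.linalg.norm(M @ sol - rhs)) / denom
    if rel > rtol:
        raise SingularSystemError(
            f"mixed-model equations solved to relative residual {rel:.2e} > {rtol:.0e}; "
            + _diagnose(M, X, terms)
        )

    fixed = sol[: X.shape[1]]
    random = {}
    off = X.shape[1]
    for t in terms:
        random[t.name] = sol[off : off + t.n_levels]
        off += t.n_levels
    return MMESolution(fixed=fixed, random=random, relative_residual=rel, rhs=rhs)


def _diagnose(M: sp.spmatrix, X, terms) -> str:
    d = np.abs(M.diagonal())
    scale = d.max() if d.size else 1.0
    bad = d < 1e-12 * max(scale, 1.0)
    if not bad.any():
        return "system numerically singular (no degenerate diagonal found)"
    names = []
    off = X.shape[1]
    if bad[: X.shape[1]].any():
        names.append("fixed")
    for t in terms:
        if bad[off : off + t.n_levels].any():
            names.append(t.name)
        off += t.n_levels
    return f"singular diagonal in block(s): {', '.join(names)}"
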