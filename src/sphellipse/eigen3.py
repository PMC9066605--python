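"""Closed-form eigendecomposition of symmetric 3x3 matrices.

The characteristic cubic of a real symmetric 3x3 matrix always falls in the
casus irreducibilis (three real roots) and is solvable with trigonometric
functions; no iteration is required.  This is the inner kernel of the contact
search, where the smallest eigenvalue of an interpolated quadratic form is
evaluated many times inside a 1-D optimizer.

Eigenvectors are obtained from cross products of rows of ``M - lambda*I``
(the row cross product spans the null space), with a deterministic sign
convention so results are reproducible across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["EigenTriple", "eig_sym3", "eigvals_sym3"]

_TWO_PI_3 = 2.0 * math.pi / 3.0


@dataclass(frozen=True)
class EigenTriple:
    """Eigenvalues sorted ascending with matching orthonormal eigenvectors.

    ``vectors[:, i]`` is the unit eigenvector for ``values[i]``.
    """

    values: np.ndarray
    vectors: np.ndarray


def eigvals_sym3(M: np.ndarray) -> tuple[float, float, float]:
    """Eigenvalues of a symmetric 3x3 matrix, ascending, via the trig formula.

    The acos argument is clamped to [-1, 1] so nearly degenerate spectra do
    not produce NaNs from roundoff.
    """
    a00 = M[0, 0]
    a11 = M[1, 1]
    a22 = M[2, 2]
    a01 = M[0, 1]
    a02 = M[0, 2]
    a12 = M[1, 2]
    p1 = a01 * a01 + a02 * a02 + a12 * a12
    q = (a00 + a11 + a22) / 3.0
    if p1 == 0.0:
        v = sorted((a00, a11, a22))
        return v[0], v[1], v[2]
    b00 = a00 - q
    b11 = a11 - q
    b22 = a22 - q
    p2 = b00 * b00 + b11 * b11 + b22 * b22 + 2.0 * p1
    p = math.sqrt(p2 / 6.0)
    # det(B)/2 with B = (M - q I)/p
    detb = (
        b00 * (b11 * b22 - a12 * a12)
        - a01 * (a01 * b22 - a12 * a02)
        + a02 * (a01 * a12 - b11 * a02)
    )
    r = detb / (2.0 * p * p * p)
    r = min(1.0, max(-1.0, r))
    phi = math.acos(r) / 3.0
    lam3 = q + 2.0 * p * math.cos(phi)
    lam1 = q + 2.0 * p * math.cos(phi + _TWO_PI_3)
    lam2 = 3.0 * q - lam1 - lam3
    return lam1, lam2, lam3


def _null_vector(M: np.ndarray, lam: float) -> np.ndarray | None:
    """Best cross product of rows of ``M - lam*I``, or None if degenerate."""
    C = M - lam * np.eye(3)
    c01 = np.cross(C[0], C[1])
    c02 = np.cross(C[0], C[2])
    c12 = np.cross(C[1], C[2])
    norms = (np.linalg.norm(c01), np.linalg.norm(c02), np.linalg.norm(c12))
    k = int(np.argmax(norms))
    if norms[k] < 1e-14 * max(1.0, float(np.abs(M).max())) ** 2:
        return None
    return (c01, c02, c12)[k] / norms[k]


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude component is positive (first on ties)."""
    k = int(np.argmax(np.abs(v)))
    return -v if v[k] < 0.0 else v


def _any_orthonormal(v: np.ndarray) -> np.ndarray:
    k = int(np.argmin(np.abs(v)))
    e = np.zeros(3)
    e[k] = 1.0
    w = e - (e @ v) * v
    return w / np.linalg.norm(w)


def eig_sym3(M: np.ndarray) -> EigenTriple:
    """Full closed-form eigendecomposition of a symmetric 3x3 matrix.

    Eigenvalues sorted ascending; eigenvectors orthonormal with the
    largest-magnitude component of each made positive.  Near-degenerate
    eigenvalue pairs (gap below ``1e-8 * scale``) fall back to completing an
    orthonormal frame around the well-separated eigenvector.

    Raises
    ------
    DomainError
        If ``M`` is not symmetric within ``1e-10 * scale``.
    """
    M = np.asarray(M, dtype=float)
    scale = max(1.0, float(np.abs(M).max()))
    if np.abs(M - M.T).max() > 1e-10 * scale:
        raise DomainError("matrix is not symmetric")
    M = 0.5 * (M + M.T)
    lam = eigvals_sym3(M)
    gap_lo = lam[1] - lam[0]
    gap_hi = lam[2] - lam[1]
    tol = 1e-8 * scale

    if gap_lo < tol and gap_hi < tol:
        vecs = np.eye(3)
    elif gap_lo < tol:
        v3 = _null_vector(M, lam[2])
        if v3 is None:
            v3 = np.array([0.0, 0.0, 1.0])
        v1 = _any_orthonormal(v3)
        v2 = np.cross(v3, v1)
        vecs = np.column_stack([v1, v2, v3])
    elif gap_hi < tol:
        v1 = _null_vector(M, lam[0])
        if v1 is None:
            v1 = np.array([0.0, 0.0, 1.0])
        v2 = _any_orthonormal(v1)
        v3 = np.cross(v1, v2)
        vecs = np.column_stack([v1, v2, v3])
    else:
        v1 = _null_vector(M, lam[0])
        v3 = _null_vector(M, lam[2])
        if v1 is None or v3 is None:  # pathological roundoff; fall back
            vals, vecs = np.linalg.eigh(M)
            lam = (float(vals[0]), float(vals[1]), float(vals[2]))
            v1, v3 = vecs[:, 0], vecs[:, 2]
        # re-orthogonalize the pair before completing the frame
        v3 = v3 - (v3 @ v1) * v1
        v3 = v3 / np.linalg.norm(v3)
        v2 = np.cross(v3, v1)
        vecs = np.column_stack([v1, v2, v3])

    vecs = np.column_stack([_fix_sign(vecs[:, i]) for i in range(3)])
    return EigenTriple(values=np.array(lam, dtype=float), vectors=vecs)
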