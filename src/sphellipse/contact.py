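"""Contact function for pairs of spherical ellipses.

Two ellipses with quadratic forms ``A`` and ``B`` are probed through the
linear interpolation ``Q(t) = A(1-t) + Bt`` on ``t in [0, 1]``.  The smallest
eigenvalue band ``lambda1(t)`` vanishes at both endpoints and has a single
interior maximum ``Lambda1``; the ellipse pair (including antipodes)
intersects on the sphere iff ``Lambda1 <= 1``.  ``Lambda1`` is the factor by
which the squared projected semiaxes of both ellipses must be scaled to reach
first tangency, and its eigenvector is the tangency point.

Because a quadratic form represents an *antipodal pair* of ellipses, the
first tangency may involve an antipode.  A sign test on the tangency vector
against the two signed centers decides whether the contact is between the
true ellipses; if not, the interior minimum ``Lambda2`` of the middle
eigenvalue band provides the second tangency scale.  Scales beyond
``Omega`` (the smallest nonzero eigenvalue of ``A`` and ``B``) would invert
an ellipse through the great-circle limit, so the contact function is clipped
there: ``F = Omega`` with no contact point, which keeps ``F`` continuous over
the whole configuration space.

``F < 1`` means overlap, ``F = 1`` tangency, ``F > 1`` separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .eigen3 import eig_sym3, eigvals_sym3
from .errors import DomainError, SphellipseError
from .geometry import QuadraticForm, SphericalEllipse, quadratic_form

__all__ = [
    "Branch",
    "ContactResult",
    "IndeterminateSignError",
    "interpolated_form",
    "maximize_lambda1",
    "minimize_lambda2_interior",
    "sign_test",
    "omega",
    "contact_function",
    "overlap",
    "Lambda1Result",
    "Lambda2Result",
]

_GOLDEN = 0.5 * (3.0 - math.sqrt(5.0))
_INVPHI = 0.5 * (math.sqrt(5.0) - 1.0)
_SQRT_EPS = math.sqrt(np.finfo(float).eps)

DEFAULT_TOL_T = 1e-7


class Branch(str, Enum):
    """Which critical scale provides the contact function."""

    LAMBDA1 = "LAMBDA1"
    LAMBDA2 = "LAMBDA2"
    OMEGA = "OMEGA"


class IndeterminateSignError(SphellipseError):
    """Contact point is orthogonal to an ellipse center; sign test undecided."""


@dataclass(frozen=True)
class Lambda1Result:
    t_star: float
    value: float
    vector: np.ndarray | None
    n_evals: int
    early_exit: bool  # True => value is only a lower bound on Lambda1


@dataclass(frozen=True)
class Lambda2Result:
    t_star: float
    value: float
    vector: np.ndarray
    n_evals: int


@dataclass(frozen=True)
class ContactResult:
    """Outcome of the branch-selection contact algorithm for one pair."""

    F: float
    branch: Branch
    t_star: float | None
    Lambda1: float
    Lambda2: float | None
    v: np.ndarray | None
    n_a: np.ndarray | None
    n_b: np.ndarray | None
    overlap: bool
    omega: float
    n_evals_lambda1: int = 0
    n_evals_lambda2: int = 0


def _matrix(q) -> np.ndarray:
    if isinstance(q, QuadraticForm):
        return q.matrix
    return np.asarray(q, dtype=float)


def interpolated_form(A, B, t: float) -> np.ndarray:
    """The interpolated quadratic form ``Q(t) = A(1-t) + Bt``."""
    return (1.0 - t) * _matrix(A) + t * _matrix(B)


def omega(A, B) -> float:
    """Smallest nonzero eigenvalue of ``A`` and ``B``.

    Corresponds to the inverse squared projected semi-major axis of the
    larger ellipse; scales beyond it would push an ellipse through the
    great-circle (inversion) limit.
    """
    # LAPACK here: the closed form loses ~sqrt(eps) accuracy on the exactly
    # degenerate spectra of circles, and omega is evaluated once per pair
    la = np.linalg.eigvalsh(_matrix(A))
    lb = np.linalg.eigvalsh(_matrix(B))
    return float(min(la[1], la[2], lb[1], lb[2]))


def sign_test(v, rA, rB) -> bool:
    """True iff contact vector ``v`` touches the true ellipses, not an antipode.

    The test is the sign of ``(v . rA)(v . rB)``: a contact between the true
    ellipse and the antipode of the other projects with opposite signs onto
    the two signed centers.  Invariant under ``v -> -v``.

    Raises
    ------
    IndeterminateSignError
        If ``v`` is orthogonal to either center within 1e-12 (zero-measure
        configuration; callers resolve by perturbing ``t``).
    """
    v = np.asarray(v, dtype=float)
    da = float(v @ np.asarray(rA, dtype=float))
    db = float(v @ np.asarray(rB, dtype=float))
    if abs(da) < 1e-12 or abs(db) < 1e-12:
        raise IndeterminateSignError("contact vector orthogonal to a center")
    return da * db > 0.0


# ---------------------------------------------------------------------------
# 1-D optimizers (eigenvalue-evaluation counting, optional early termination)
# ---------------------------------------------------------------------------


def _brent_min(g, a, b, xatol, stop_below=None, maxiter=200):
    """Bounded Brent minimization (golden section + parabolic interpolation).

    Returns ``(x, g(x), n_evals, early)``; if ``stop_below`` is given the
    search aborts as soon as any sample falls below it (``early=True``).
    """
    xf = a + _GOLDEN * (b - a)
    v = w = xf
    e = 0.0
    d = 0.0
    fx = g(xf)
    num = 1
    if stop_below is not None and fx < stop_below:
        return xf, fx, num, True
    fv = fw = fx
    xm = 0.5 * (a + b)
    tol1 = _SQRT_EPS * abs(xf) + xatol / 3.0
    tol2 = 2.0 * tol1
    while abs(xf - xm) > (tol2 - 0.5 * (b - a)):
        golden = True
        if abs(e) > tol1:
            # try parabolic fit through (v, w, xf)
            r = (xf - w) * (fx - fv)
            q = (xf - v) * (fx - fw)
            p = (xf - v) * q - (xf - w) * r
            q = 2.0 * (q - r)
            if q > 0.0:
                p = -p
            q = abs(q)
            r = e
            e = d
            if (abs(p) < abs(0.5 * q * r)) and (p > q * (a - xf)) and (p < q * (b - xf)):
                d = p / q
                x = xf + d
                if (x - a) < tol2 or (b - x) < tol2:
                    d = tol1 if xm - xf >= 0 else -tol1
                golden = False
        if golden:  # golden-section step
            e = (a - xf) if xf >= xm else (b - xf)
            d = _GOLDEN * e
        x = xf + (d if abs(d) >= tol1 else (tol1 if d >= 0 else -tol1))
        fu = g(x)
        num += 1
        if stop_below is not None and fu < stop_below:
            return x, fu, num, True
        if fu <= fx:
            if x >= xf:
                a = xf
            else:
                b = xf
            v, fv = w, fw
            w, fw = xf, fx
            xf, fx = x, fu
        else:
            if x < xf:
                a = x
            else:
                b = x
            if fu <= fw or w == xf:
                v, fv = w, fw
                w, fw = x, fu
            elif fu <= fv or v == xf or v == w:
                v, fv = x, fu
        xm = 0.5 * (a + b)
        tol1 = _SQRT_EPS * abs(xf) + xatol / 3.0
        tol2 = 2.0 * tol1
        if num >= maxiter:
            break
    return xf, fx, num, False


def _gss_min(g, a, b, xatol, stop_below=None):
    """Golden-section search; same return convention as :func:`_brent_min`."""
    x1 = b - _INVPHI * (b - a)
    x2 = a + _INVPHI * (b - a)
    f1 = g(x1)
    num = 1
    if stop_below is not None and f1 < stop_below:
        return x1, f1, num, True
    f2 = g(x2)
    num += 1
    if stop_below is not None and f2 < stop_below:
        return x2, f2, num, True
    while (b - a) > xatol:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _INVPHI * (b - a)
            f1 = g(x1)
            num += 1
            if stop_below is not None and f1 < stop_below:
                return x1, f1, num, True
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _INVPHI * (b - a)
            f2 = g(x2)
            num += 1
            if stop_below is not None and f2 < stop_below:
                return x2, f2, num, True
    return (x1, f1, num, False) if f1 <= f2 else (x2, f2, num, False)


def _minimize(method: str):
    m = method.lower()
    if m == "brent":
        return _brent_min
    if m == "gss":
        return _gss_min
    raise DomainError(f"unknown 1-D method {method!r} (expected 'brent' or 'gss')")


# ---------------------------------------------------------------------------
# eigenvalue-band extremization
# ---------------------------------------------------------------------------


def maximize_lambda1(
    A,
    B,
    tol_t: float = DEFAULT_TOL_T,
    method: str = "brent",
    early_exit_above: float | None = None,
) -> Lambda1Result:
    """Maximize the smallest eigenvalue of ``Q(t)`` over ``t in [0, 1]``.

    The band vanishes at both endpoints and is anticonvex with a single
    interior maximum, so bounded Brent (default) or golden-section search
    converges reliably.  ``early_exit_above`` aborts as soon as a sample
    exceeds the threshold — enough to decide "no overlap" for hard particles;
    the returned value is then only a lower bound and no eigenvector is
    computed.
    """
    if tol_t <= 0:
        raise DomainError("tol_t must be positive")
    Am = _matrix(A)
    Bm = _matrix(B)
    D = Bm - Am

    def neg_l1(t: float) -> float:
        return -eigvals_sym3(Am + t * D)[0]

    stop = None if early_exit_above is None else -early_exit_above
    t, fneg, num, early = _minimize(method)(neg_l1, 0.0, 1.0, tol_t, stop_below=stop)
    if early:
        return Lambda1Result(t_star=t, value=-fneg, vector=None, n_evals=num, early_exit=True)
    trip = eig_sym3(Am + t * D)
    return Lambda1Result(
        t_star=t, value=float(trip.values[0]), vector=trip.vectors[:, 0],
        n_evals=num, early_exit=False,
    )


_N_PROBES = 9


def minimize_lambda2_interior(
    A, B, tol_t: float = DEFAULT_TOL_T, method: str = "brent"
) -> Lambda2Result | None:
    """Interior local minimum of the middle eigenvalue band, if it exists.

    The band is probed at 9 equally spaced points of ``[0, 1]``.  Candidate
    minima are bracketed two ways: a probe strictly below both neighbours,
    and a sign change of the band slope between consecutive probes.  Slopes
    are finite differences of the *sorted* middle eigenvalue (one-sided at
    the endpoints), which remain meaningful where bands touch — e.g. at the
    endpoint degeneracy of a circle — and catch dips much narrower than the
    probe spacing (the middle band has at most one minimum and one maximum
    on the whole real line, so a sign pattern over 9 probes cannot hide a
    finite dip).  Each bracket is refined with the 1-D minimizer and the
    lowest interior minimum is returned.  If no bracket exists the
    constrained minimum sits at an interval endpoint, meaning the second
    tangency cannot be a true contact — ``None`` is returned.
    """
    if tol_t <= 0:
        raise DomainError("tol_t must be positive")
    Am = _matrix(A)
    Bm = _matrix(B)
    D = Bm - Am

    def l2(t: float) -> float:
        return eigvals_sym3(Am + t * D)[1]

    delta = 1e-4
    ts = np.linspace(0.0, 1.0, _N_PROBES)
    fs = np.empty(_N_PROBES)
    slopes = np.empty(_N_PROBES)
    for k, t in enumerate(ts):
        fs[k] = l2(t)
        lo = max(0.0, t - delta)
        hi = min(1.0, t + delta)
        slopes[k] = (l2(hi) - l2(lo)) / (hi - lo)
    n_evals = 3 * _N_PROBES

    brackets = []
    for i in range(1, _N_PROBES - 1):
        if fs[i] < fs[i - 1] and fs[i] < fs[i + 1]:
            brackets.append((ts[i - 1], ts[i + 1]))
    for i in range(_N_PROBES - 1):
        if slopes[i] < 0.0 and slopes[i + 1] > 0.0:
            brackets.append((ts[i], ts[i + 1]))
    if not brackets:
        return None

    best = None
    for a, b in brackets:
        t, fmin, num, _ = _minimize(method)(l2, a, b, tol_t)
        n_evals += num
        if t <= tol_t or t >= 1.0 - tol_t:
            continue  # minimizer pushed to an interval edge: not interior
        if best is None or fmin < best[1]:
            best = (t, fmin)
    if best is None:
        return None
    t = best[0]
    trip = eig_sym3(Am + t * D)
    return Lambda2Result(
        t_star=t, value=float(trip.values[1]), vector=trip.vectors[:, 1], n_evals=n_evals
    )


def _polish_band_extremum(Am: np.ndarray, Bm: np.ndarray, t0: float, band: int) -> float:
    """Refine a band extremum by root-finding the band slope near ``t0``.

    The 1-D optimizer locates the extremum to its tolerance in ``t``; for
    strongly curved bands the residual slope there can still be noticeable.
    A Brent root-find on the (finite-difference) slope of the sorted band
    pins the stationary point to ~1e-11 in ``t``, which makes the envelope
    condition ``v^T (B - A) v = 0`` hold to high accuracy at the reported
    contact point.
    """
    D = Bm - Am
    delta = 1e-6

    def slope(t: float) -> float:
        lo = max(0.0, t - delta)
        hi = min(1.0, t + delta)
        return (eigvals_sym3(Am + hi * D)[band] - eigvals_sym3(Am + lo * D)[band]) / (hi - lo)

    w = 1e-5
    for _ in range(7):
        a = max(0.0, t0 - w)
        b = min(1.0, t0 + w)
        sa, sb = slope(a), slope(b)
        if abs(sa) < 1e-13 and abs(sb) < 1e-13:
            return t0  # flat band (identical forms)
        if sa * sb < 0.0:
            return float(brentq(slope, a, b, xtol=1e-11))
        w *= 8.0
    return t0


# ---------------------------------------------------------------------------
# branch selection
# ---------------------------------------------------------------------------


def _degenerate_band_vector(v1: np.ndarray, v2: np.ndarray, rA, rB) -> np.ndarray:
    """Vector of the degenerate eigenplane maximizing |sign-test product|.

    The product ``(v.rA)(v.rB)`` restricted to ``span(v1, v2)`` is a 2x2
    quadratic form in the plane coordinates; its extremal values are the
    eigenvalues, so the best direction is the eigenvector of the
    largest-magnitude one.  Deterministic and continuous in the limit of a
    closing eigenvalue gap.
    """
    a = float(v1 @ rA)
    b = float(v2 @ rA)
    c = float(v1 @ rB)
    d = float(v2 @ rB)
    S = np.array([[a * c, 0.5 * (a * d + b * c)], [0.5 * (a * d + b * c), b * d]])
    w, V = np.linalg.eigh(S)
    k = int(np.argmax(np.abs(w)))
    vec = V[0, k] * v1 + V[1, k] * v2
    n = np.linalg.norm(vec)
    return vec / n if n > 0 else v1


def _band_vector(Am, Bm, t, band: int, rA, rB) -> np.ndarray:
    """Eigenvector of band ``band`` (0 = lowest) of Q(t), degeneracy-aware."""
    trip = eig_sym3(interpolated_form(Am, Bm, t))
    lam = trip.values
    scale = 1e-8 * (1.0 + abs(float(lam[band])))
    if band == 0 and lam[1] - lam[0] < scale:
        return _degenerate_band_vector(trip.vectors[:, 0], trip.vectors[:, 1], rA, rB)
    if band == 1 and min(lam[1] - lam[0], lam[2] - lam[1]) < scale:
        other = 0 if lam[1] - lam[0] < lam[2] - lam[1] else 2
        return _degenerate_band_vector(trip.vectors[:, 1], trip.vectors[:, other], rA, rB)
    return trip.vectors[:, band]


def _robust_sign_test(Am, Bm, t, band, v, rA, rB, tol_t) -> tuple[bool, np.ndarray]:
    """Sign test with perturbation fallback for indeterminate configurations."""
    try:
        return sign_test(v, rA, rB), v
    except IndeterminateSignError:
        pass
    for dt in (10.0 * tol_t, -10.0 * tol_t):
        tp = min(1.0, max(0.0, t + dt))
        vp = _band_vector(Am, Bm, tp, band, rA, rB)
        try:
            return sign_test(vp, rA, rB), v
        except IndeterminateSignError:
            continue
    # still orthogonal: zero-measure case, resolve deterministically as a
    # true-pair contact (product 0 counted as nonnegative)
    return True, v


def _normal(M: np.ndarray, F: float, v: np.ndarray) -> np.ndarray | None:
    n = M @ v - F * v
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        return None
    return n / nn


def contact_function(
    eA: SphericalEllipse,
    eB: SphericalEllipse,
    tol_t: float = DEFAULT_TOL_T,
    method: str = "brent",
) -> ContactResult:
    """Contact function ``F`` and contact geometry for an ellipse pair.

    Branch selection:

    1. maximize the lowest band: if the tangency vector passes the antipode
       sign test and ``Lambda1 <= Omega``, ``F = Lambda1``;
    2. otherwise, if the middle band has an interior minimum whose vector
       passes the sign test and ``Lambda2 <= Omega``, ``F = Lambda2``;
    3. otherwise no valid contact exists at any admissible scale and
       ``F = Omega`` (continuous clip, no contact point).

    When a contact point ``v`` exists, the outward unit normals of the two
    grown ellipses at ``v`` are ``n_a ~ (A - F I)v`` and ``n_b ~ (B - F I)v``
    (antiparallel at tangency).
    """
    Am = quadratic_form(eA).matrix
    Bm = quadratic_form(eB).matrix
    rA = eA.center
    rB = eB.center
    om = omega(Am, Bm)
    om_slack = om * (1.0 + 1e-12)

    l1 = maximize_lambda1(Am, Bm, tol_t=tol_t, method=method)
    t1 = _polish_band_extremum(Am, Bm, l1.t_star, 0)
    L1 = eigvals_sym3(interpolated_form(Am, Bm, t1))[0]
    v1 = _band_vector(Am, Bm, t1, 0, rA, rB)
    ok1, v1 = _robust_sign_test(Am, Bm, t1, 0, v1, rA, rB, tol_t)

    l2 = None
    L2 = None
    if ok1 and L1 <= om_slack:
        F, branch, t_star, v = L1, Branch.LAMBDA1, t1, v1
    else:
        l2 = minimize_lambda2_interior(Am, Bm, tol_t=tol_t, method=method)
        picked = False
        if l2 is not None:
            t2 = _polish_band_extremum(Am, Bm, l2.t_star, 1)
            L2 = eigvals_sym3(interpolated_form(Am, Bm, t2))[1]
            v2 = _band_vector(Am, Bm, t2, 1, rA, rB)
            ok2, v2 = _robust_sign_test(Am, Bm, t2, 1, v2, rA, rB, tol_t)
            if ok2 and L2 <= om_slack:
                F, branch, t_star, v = L2, Branch.LAMBDA2, t2, v2
                picked = True
        if not picked:
            F, branch, t_star, v = om, Branch.OMEGA, None, None

    n_a = n_b = None
    if v is not None:
        n_a = _normal(Am, F, v)
        n_b = _normal(Bm, F, v)
    return ContactResult(
        F=float(F),
        branch=branch,
        t_star=None if t_star is None else float(t_star),
        Lambda1=float(L1),
        Lambda2=None if L2 is None else float(L2),
        v=v,
        n_a=n_a,
        n_b=n_b,
        overlap=bool(F < 1.0),
        omega=float(om),
        n_evals_lambda1=l1.n_evals,
        n_evals_lambda2=0 if l2 is None else l2.n_evals,
    )


def overlap(eA: SphericalEllipse, eB: SphericalEllipse, tol_t: float = DEFAULT_TOL_T) -> bool:
    """True iff the two *true* ellipses intersect on the sphere.

    Fast paths: center separations below the sum of minor semiaxes always
    overlap, above the sum of major semiaxes never do.  In between, the
    lowest-band maximization runs with early termination (any sample above 1
    proves separation); otherwise the full branch logic decides.
    """
    theta = math.acos(min(1.0, max(-1.0, float(eA.center @ eB.center))))
    if theta < eA.xi2 + eB.xi2:
        return True
    if theta > eA.xi1 + eB.xi1:
        return False
    Am = quadratic_form(eA).matrix
    Bm = quadratic_form(eB).matrix
    l1 = maximize_lambda1(Am, Bm, tol_t=tol_t, early_exit_above=1.0)
    if l1.early_exit:
        return False
    return contact_function(eA, eB, tol_t=tol_t).overlap
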