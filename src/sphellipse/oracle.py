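"""Brute-force ground truth for overlap and the contact function.

Used by the test-suite and the ``validate`` command only: everything here is
deliberately simple and slow.  Overlap is decided by dense boundary sampling
plus center-containment checks; the contact function is recovered by
bisecting the growth factor at which the pair first overlaps.  Growing an
ellipse by factor ``s`` scales its projected (sine) semiaxes by ``sqrt(s)``,
i.e. divides the quadratic-form matrix by ``s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .geometry import SphericalEllipse, make_ellipse, quadratic_form

__all__ = [
    "OracleSettings",
    "grown_ellipse",
    "overlap_bruteforce",
    "contact_bruteforce",
    "circle_contact_reference",
]


@dataclass(frozen=True)
class OracleSettings:
    """Sampling density and bisection tolerance for the brute-force oracle."""

    n_boundary: int = 2048
    tol_scale: float = 1e-6

    def __post_init__(self):
        if self.n_boundary < 64:
            raise DomainError("n_boundary must be >= 64")
        if self.tol_scale <= 0:
            raise DomainError("tol_scale must be positive")


def grown_ellipse(e: SphericalEllipse, s: float) -> SphericalEllipse:
    """Ellipse grown by factor ``s``: ``sin xi' = sqrt(s) * sin xi``.

    Raises
    ------
    DomainError
        If ``s <= 0`` or the grown major semiaxis reaches the great circle.
    """
    if s <= 0:
        raise DomainError("growth factor must be positive")
    r = math.sqrt(s)
    s1 = r * math.sin(e.xi1)
    s2 = r * math.sin(e.xi2)
    if s1 >= 1.0:
        raise DomainError(f"growth {s} pushes the major semiaxis past the great circle")
    return make_ellipse(e.center, e.major_axis, math.asin(s1), math.asin(s2))


def _boundary_points(e: SphericalEllipse, n: int) -> np.ndarray:
    phi = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    s1 = math.sin(e.xi1)
    s2 = math.sin(e.xi2)
    x = s1 * np.cos(phi)
    y = s2 * np.sin(phi)
    z = np.sqrt(np.clip(1.0 - x * x - y * y, 0.0, None))
    return (
        x[:, None] * e.major_axis[None, :]
        + y[:, None] * e.minor_axis[None, :]
        + z[:, None] * e.center[None, :]
    )


def _any_contained(points: np.ndarray, e: SphericalEllipse) -> bool:
    A = quadratic_form(e).matrix
    vals = np.einsum("ij,jk,ik->i", points, A, points)
    dots = points @ e.center
    return bool(np.any((vals <= 1.0) & (dots > 0.0)))


def overlap_bruteforce(
    eA: SphericalEllipse, eB: SphericalEllipse, settings: OracleSettings = OracleSettings()
) -> bool:
    """Dense-sampling overlap test between the *true* ellipses.

    True iff a sampled boundary point of one ellipse lies inside the other,
    or either center lies inside the other (covers full containment with no
    boundary crossing).
    """
    n = settings.n_boundary
    A = quadratic_form(eA).matrix
    B = quadratic_form(eB).matrix
    # center containment
    if float(eA.center @ B @ eA.center) <= 1.0 and float(eA.center @ eB.center) > 0.0:
        return True
    if float(eB.center @ A @ eB.center) <= 1.0 and float(eB.center @ eA.center) > 0.0:
        return True
    if _any_contained(_boundary_points(eA, n), eB):
        return True
    return _any_contained(_boundary_points(eB, n), eA)


def contact_bruteforce(
    eA: SphericalEllipse, eB: SphericalEllipse, settings: OracleSettings = OracleSettings()
) -> float:
    """Tangency growth factor by bisection of :func:`overlap_bruteforce`.

    Returns the scale ``s*`` at which the pair first overlaps when both are
    grown by ``s``.  If the pair still does not overlap at the largest
    admissible growth (major semiaxis at the great-circle limit), there is no
    tangency in the valid regime and the upper bracket (the inversion-limit
    sentinel, playing the role of Omega) is returned.
    """
    lo = 1e-4
    s1max = max(math.sin(eA.xi1), math.sin(eB.xi1))
    hi = (1.0 / s1max) ** 2 - 1e-9

    def f(s: float) -> bool:
        return overlap_bruteforce(grown_ellipse(eA, s), grown_ellipse(eB, s), settings)

    if f(lo):  # pair overlaps even at near-zero size (coincident centers)
        return lo
    if not f(hi):
        return hi
    while hi - lo > settings.tol_scale:
        mid = 0.5 * (lo + hi)
        if f(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def circle_contact_reference(alpha: float, beta: float, theta: float) -> float:
    """Closed-form contact function for two circles.

    ``alpha`` and ``beta`` are the inverse squared sine radii of the circles
    (quadratic-form eigenvalues) and ``theta`` their center separation:

        F(theta) = alpha*beta*sin^2(theta) /
                   (alpha + beta + 2*sqrt(alpha*beta)*cos(theta)),

    clipped to ``Omega = min(alpha, beta)`` beyond the maximum at
    ``cos^2 theta = beta/alpha`` (for unequal circles the decreasing part of
    the raw expression corresponds to contacts between wrong/inverted pairs).
    At equal radii the expression reduces to ``alpha * sin^2(theta/2)``.
    """
    if alpha <= 1.0 or beta <= 1.0:
        raise DomainError("circle parameters must exceed 1 (radii below pi/2)")
    hi, lo_ = max(alpha, beta), min(alpha, beta)
    c = math.cos(theta)
    if c < 0.0 and c * c >= lo_ / hi:
        return lo_
    num = alpha * beta * math.sin(theta) ** 2
    den = alpha + beta + 2.0 * math.sqrt(alpha * beta) * c
    return num / den
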