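"""Spherical ellipses and their quadratic-form representation.

A spherical ellipse is the locus of points on the unit sphere whose geodesic
distances to two foci sum to a constant ``2*eta < pi``.  Equivalently it is
the intersection of the sphere with an elliptic cylinder through the origin,
which we encode as a degenerate (rank-2) positive-semidefinite quadratic form

    a(r) = r^T A r,    A = (1/sin^2 xi1) u u^T + (1/sin^2 xi2) w w^T,

where ``u`` is the major-axis direction, ``w = center x u`` the minor-axis
direction and ``xi1 >= xi2`` are the *geodesic* angular semiaxes.  The level
set ``a(r) = 1`` on the sphere consists of the ellipse *and* its antipodal
mirror image; the signed center vector selects the true ellipse (points ``r``
of the true ellipse satisfy ``r . center > 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidGeometryError

__all__ = [
    "SphericalEllipse",
    "QuadraticForm",
    "make_ellipse",
    "ellipse_from_foci",
    "quadratic_form",
    "evaluate_form",
    "boundary_point",
    "contains",
    "ellipse_area",
]

_UNIT_TOL = 1e-12


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise InvalidGeometryError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidGeometryError(f"{name} contains non-finite entries")
    return a


@dataclass(frozen=True)
class SphericalEllipse:
    """An ellipse on the unit sphere.

    Attributes
    ----------
    center : ndarray, shape (3,)
        Unit vector to the ellipse center; its sign selects the true ellipse
        of the antipodal pair produced by the quadratic form.
    major_axis : ndarray, shape (3,)
        Unit vector along the major axis, orthogonal to ``center``.
    xi1, xi2 : float
        Geodesic semi-major and semi-minor axes in radians,
        ``0 < xi2 <= xi1 < pi/2``.
    """

    center: np.ndarray
    major_axis: np.ndarray
    xi1: float
    xi2: float

    @property
    def minor_axis(self) -> np.ndarray:
        """Unit vector along the minor axis (``center x major_axis``)."""
        return np.cross(self.center, self.major_axis)

    @property
    def aspect_ratio(self) -> float:
        """Ratio of the geodesic semiaxes ``xi1 / xi2``."""
        return self.xi1 / self.xi2

    def __post_init__(self):
        c = self.center
        u = self.major_axis
        if abs(np.linalg.norm(c) - 1.0) > _UNIT_TOL:
            raise InvalidGeometryError("center is not a unit vector")
        if abs(np.linalg.norm(u) - 1.0) > _UNIT_TOL:
            raise InvalidGeometryError("major_axis is not a unit vector")
        if abs(float(c @ u)) > _UNIT_TOL:
            raise InvalidGeometryError("major_axis is not orthogonal to center")
        if not (0.0 < self.xi2 <= self.xi1 < math.pi / 2):
            raise DomainError(
                "semiaxes must satisfy 0 < xi2 <= xi1 < pi/2 "
                f"(got xi1={self.xi1}, xi2={self.xi2})"
            )


@dataclass(frozen=True)
class QuadraticForm:
    """Symmetric rank-2 PSD 3x3 matrix representing an elliptic cylinder.

    The two nonzero eigenvalues are ``1/sin^2 xi1`` and ``1/sin^2 xi2`` and
    the zero-eigenvector is (plus or minus) the generating ellipse's center.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InvalidGeometryError("quadratic form must be 3x3")
        if not np.allclose(m, m.T, atol=1e-12):
            raise InvalidGeometryError("quadratic form must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        """The two nonzero eigenvalues (inverse squared projected semiaxes)."""
        vals = np.linalg.eigvalsh(self.matrix)
        return vals[1:]


def make_ellipse(center, major_axis, xi1: float, xi2: float) -> SphericalEllipse:
    """Construct a spherical ellipse from center, axis direction and semiaxes.

    ``center`` is normalized; ``major_axis`` is re-orthogonalized against the
    center (Gram-Schmidt) and normalized.  Semiaxes are geodesic, in radians.

    Raises
    ------
    InvalidGeometryError
        If ``center`` is (near) zero or ``major_axis`` is (near) parallel to it.
    DomainError
        If the semiaxes violate ``0 < xi2 <= xi1 < pi/2``.
    """
    c = _as_vec3(center, "center")
    u = _as_vec3(major_axis, "major_axis")
    nc = np.linalg.norm(c)
    if nc < 1e-12:
        raise InvalidGeometryError("center vector is zero")
    c = c / nc
    # project out the center component
    u = u - (u @ c) * c
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        raise InvalidGeometryError("major_axis is parallel to center")
    u = u / nu
    xi1 = float(xi1)
    xi2 = float(xi2)
    if not (0.0 < xi2 <= xi1 < math.pi / 2):
        raise DomainError(
            f"semiaxes must satisfy 0 < xi2 <= xi1 < pi/2 (got xi1={xi1}, xi2={xi2})"
        )
    return SphericalEllipse(center=c, major_axis=u, xi1=xi1, xi2=xi2)


def ellipse_from_foci(f1, f2, eta: float) -> SphericalEllipse:
    """Build the ellipse with foci ``f1, f2`` and geodesic-distance sum ``2*eta``.

    With ``2*psi`` the geodesic separation of the foci, the semiaxes follow
    from the focal property: ``xi1 = eta`` and
    ``sin xi2 = sqrt(sin^2 eta - sin^2 psi) / cos psi`` (equivalently
    ``cos eta = cos xi2 cos psi`` at the co-vertex).

    Raises
    ------
    DomainError
        If ``eta <= psi`` (empty locus) or ``2*eta >= pi``.
    """
    f1 = _as_vec3(f1, "f1")
    f2 = _as_vec3(f2, "f2")
    for f, name in ((f1, "f1"), (f2, "f2")):
        if abs(np.linalg.norm(f) - 1.0) > 1e-9:
            raise InvalidGeometryError(f"{name} must be a unit vector")
    eta = float(eta)
    cos2psi = float(np.clip(f1 @ f2, -1.0, 1.0))
    psi = 0.5 * math.acos(cos2psi)
    if not (psi < eta and 2 * eta < math.pi):
        raise DomainError(
            f"require psi < eta < pi/2 (got psi={psi:.6g}, eta={eta:.6g})"
        )
    mid = f1 + f2
    center = mid / np.linalg.norm(mid)
    if psi < 1e-12:
        # coincident foci: a circle; pick a deterministic axis orthogonal to center
        k = int(np.argmin(np.abs(center)))
        e = np.zeros(3)
        e[k] = 1.0
        u = e - (e @ center) * center
    else:
        u = f1 - (f1 @ center) * center
    xi2 = math.asin(math.sqrt(math.sin(eta) ** 2 - math.sin(psi) ** 2) / math.cos(psi))
    return make_ellipse(center, u, eta, xi2)


def quadratic_form(e: SphericalEllipse) -> QuadraticForm:
    """Quadratic-form matrix ``A`` of an ellipse.

    ``A = uu^T/sin^2 xi1 + ww^T/sin^2 xi2`` with ``u`` the major axis and
    ``w = center x u``; the zero-eigenvector is (+/-) the center.
    """
    u = e.major_axis
    w = e.minor_axis
    a1 = 1.0 / math.sin(e.xi1) ** 2
    a2 = 1.0 / math.sin(e.xi2) ** 2
    return QuadraticForm(a1 * np.outer(u, u) + a2 * np.outer(w, w))


def evaluate_form(q: QuadraticForm | np.ndarray, r) -> float:
    """Evaluate ``r^T A r`` (nonnegative; 1 on the ellipse boundary)."""
    m = q.matrix if isinstance(q, QuadraticForm) else np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    return float(r @ m @ r)


def boundary_point(e: SphericalEllipse, phi: float) -> np.ndarray:
    """Point of the (true) ellipse boundary at cylinder parameter ``phi``.

    Projects the planar cylinder cross-section onto the sphere along the
    center axis:
    ``p = sin xi1 cos phi * u + sin xi2 sin phi * w + sqrt(1 - ...) * center``.
    """
    s1 = math.sin(e.xi1)
    s2 = math.sin(e.xi2)
    x = s1 * math.cos(phi)
    y = s2 * math.sin(phi)
    z = math.sqrt(max(0.0, 1.0 - x * x - y * y))
    return x * e.major_axis + y * e.minor_axis + z * e.center


def contains(e: SphericalEllipse, r) -> bool:
    """True iff unit vector ``r`` lies inside or on the *true* ellipse.

    Membership requires both ``a(r) <= 1`` and ``r . center > 0``; the second
    condition rejects the antipodal mirror ellipse.
    """
    r = np.asarray(r, dtype=float)
    A = quadratic_form(e)
    return evaluate_form(A, r) <= 1.0 and float(r @ e.center) > 0.0


def _polar_radius_sin2(e: SphericalEllipse, psi: np.ndarray) -> np.ndarray:
    # sin^2 of the geodesic polar radius Theta(psi) of the boundary,
    # psi the azimuth about the center measured from the major axis
    c = np.cos(psi) ** 2 / math.sin(e.xi1) ** 2 + np.sin(psi) ** 2 / math.sin(e.xi2) ** 2
    return 1.0 / c


def ellipse_area(e: SphericalEllipse, rel_tol: float = 1e-10) -> float:
    """Solid angle (steradians) enclosed by the ellipse boundary.

    In geodesic polar coordinates about the center the enclosed area is
    ``integral over azimuth of (1 - cos Theta(psi))`` with
    ``sin^2 Theta = (cos^2 psi / sin^2 xi1 + sin^2 psi / sin^2 xi2)^{-1}``.
    The integrand is smooth and 2*pi-periodic, so the trapezoidal rule
    converges spectrally; node count is doubled until the relative change
    drops below ``rel_tol`` (start 256, cap 16384).
    """
    n = 256
    prev = None
    while True:
        psi = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        sin2 = _polar_radius_sin2(e, psi)
        cos_theta = np.sqrt(1.0 - sin2)
        val = float(np.mean(1.0 - cos_theta)) * 2 * math.pi
        if prev is not None and abs(val - prev) <= rel_tol * max(abs(val), 1e-300):
            return val
        if n >= 16384:
            return val
        prev = val
        n *= 2
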