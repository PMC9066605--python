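"""Soft pair potentials built on the contact function, with forces/torques.

The contact function ``F`` is a dimensionless growth factor, so a repulsive
pair energy can be any decreasing function of ``F`` that vanishes at
tangency.  Four overlap-only kinds are provided (zero for ``F >= 1``):

====================  ===========================
kind                  E(F) for F < 1
====================  ===========================
``NEG_LOG``           ``-ln F``
``ONE_MINUS``         ``1 - F``     (finite at complete overlap)
``INV``               ``1/F - 1``
``INV12``             ``1/F + 1/F**2 - 2``
====================  ===========================

The inverse-power kinds are shifted by their value at ``F = 1`` so the energy
is continuous at contact; forces are unaffected by the constant.

Force *directions* follow the quadratic-form gradients at the contact point
(the outward normals of the grown ellipses); the common *magnitude* is
``|dE/dF| * |dF/dtheta|`` with ``dF/dtheta`` estimated by central differences
of ``F`` under a geodesic displacement of one particle along the
center-to-center great circle.  Newton's third law and zero total torque
about the sphere center hold exactly by construction (equal and opposite
forces applied at the shared contact point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .contact import Branch, contact_function
from .errors import DomainError
from .geometry import SphericalEllipse, make_ellipse

__all__ = ["PotentialKind", "ForceTorque", "pair_energy", "pair_force_torque"]


class PotentialKind(str, Enum):
    NEG_LOG = "NEG_LOG"
    ONE_MINUS = "ONE_MINUS"
    INV = "INV"
    INV12 = "INV12"


@dataclass(frozen=True)
class ForceTorque:
    """Pair forces (tangent to the sphere at the contact) and torques."""

    force_on_A: np.ndarray
    force_on_B: np.ndarray
    torque_on_A: np.ndarray
    torque_on_B: np.ndarray


def _coerce_kind(kind) -> PotentialKind:
    try:
        return PotentialKind(kind)
    except ValueError as exc:
        raise DomainError(f"unknown potential kind {kind!r}") from exc


def pair_energy(F: float, kind: PotentialKind | str = PotentialKind.ONE_MINUS) -> float:
    """Overlap-only soft repulsion energy as a function of the contact value."""
    kind = _coerce_kind(kind)
    if F <= 0.0 and kind is not PotentialKind.ONE_MINUS:
        # only the finite-strength potential is defined at complete overlap
        raise DomainError("F must be positive")
    if F >= 1.0:
        return 0.0
    if kind is PotentialKind.NEG_LOG:
        return -math.log(F)
    if kind is PotentialKind.ONE_MINUS:
        return 1.0 - F
    if kind is PotentialKind.INV:
        return 1.0 / F - 1.0
    if kind is PotentialKind.INV12:
        return 1.0 / F + 1.0 / F**2 - 2.0
    raise DomainError(f"unknown potential kind {kind!r}")


def _dE_dF(F: float, kind: PotentialKind) -> float:
    if F >= 1.0:
        return 0.0
    if kind is PotentialKind.NEG_LOG:
        return -1.0 / F
    if kind is PotentialKind.ONE_MINUS:
        return -1.0
    if kind is PotentialKind.INV:
        return -1.0 / F**2
    if kind is PotentialKind.INV12:
        return -1.0 / F**2 - 2.0 / F**3
    raise DomainError(f"unknown potential kind {kind!r}")


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis``."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


def _displaced(e: SphericalEllipse, axis: np.ndarray, angle: float) -> SphericalEllipse:
    return make_ellipse(
        _rotate(e.center, axis, angle), _rotate(e.major_axis, axis, angle), e.xi1, e.xi2
    )


_ZERO = np.zeros(3)


def pair_force_torque(
    eA: SphericalEllipse,
    eB: SphericalEllipse,
    kind: PotentialKind | str = PotentialKind.ONE_MINUS,
    h: float = 1e-5,
) -> ForceTorque:
    """Contact forces and torques of the soft pair potential.

    Zero for non-overlapping pairs (overlap-only potentials) and in the
    clipped ``F = Omega`` region, where the potential is constant by
    construction.  ``h`` is the central-difference step (radians) for the
    separation derivative of ``F``.
    """
    kind = _coerce_kind(kind)
    res = contact_function(eA, eB)
    zero = ForceTorque(_ZERO.copy(), _ZERO.copy(), _ZERO.copy(), _ZERO.copy())
    if res.branch is Branch.OMEGA or res.F >= 1.0 or res.v is None or res.n_a is None:
        return zero
    axis = np.cross(eA.center, eB.center)
    na = np.linalg.norm(axis)
    if na < 1e-12:
        # coincident (or antipodal) centers: symmetric, no net push direction
        return zero
    axis = axis / na
    # dF/dtheta by rotating B away from / toward A along the joining great circle
    Fp = contact_function(eA, _displaced(eB, axis, +h)).F
    Fm = contact_function(eA, _displaced(eB, axis, -h)).F
    dF_dtheta = (Fp - Fm) / (2.0 * h)
    mag = abs(_dE_dF(res.F, kind)) * abs(dF_dtheta)
    # n_a points out of ellipse A at the contact: push B along it, A opposite
    force_on_B = mag * res.n_a
    force_on_A = -force_on_B
    v = res.v if float(res.v @ eA.center) >= 0.0 else -res.v
    return ForceTorque(
        force_on_A=force_on_A,
        force_on_B=force_on_B,
        torque_on_A=np.cross(v, force_on_A),
        torque_on_B=np.cross(v, force_on_B),
    )
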