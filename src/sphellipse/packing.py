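"""Dense packings of spherical ellipses by iterative growth and relaxation.

Particles share base shape parameters and a global growth ``scale``; the
actual projected semiaxes are ``scale * sin(xi_base)``.  Starting from a
random configuration far from jamming, the scale is increased in steps; after
each step the total overlap energy (a soft contact-function potential) is
minimized over particle poses by projected gradient descent.  If overlaps
cannot be removed the growth step is halved and the scale reverted, giving a
monotone schedule that terminates with an overlap-free packing.

Pose space is parameterized by rigid rotations of each particle: about its
own center (spin) and about the two tangent directions (translation on the
sphere).  Since touching neighbours are always separated by less than pi/2
for the particle counts and sizes used here, only the lowest-eigenvalue
branch of the contact function is needed; antipodal contacts are excluded by
the center-separation pre-test alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .contact import maximize_lambda1
from .dynamics import PotentialKind, _coerce_kind, pair_energy
from .errors import DomainError
from .geometry import SphericalEllipse, ellipse_area, make_ellipse, quadratic_form

__all__ = [
    "PackingState",
    "random_configuration",
    "initial_semiaxes",
    "relax",
    "grow_and_relax",
    "packing_fraction",
    "pair_contact_values",
]

_F_TOL = 1e-9  # a pair with F >= 1 - _F_TOL counts as overlap-free


@dataclass(frozen=True)
class PackingState:
    """Poses and shared shape parameters of ``N`` particles on the sphere."""

    centers: np.ndarray  # (N, 3) unit rows
    axes: np.ndarray  # (N, 3) unit rows, orthogonal to centers
    base_xi1: np.ndarray  # (N,) geodesic semi-major axes at scale 1
    base_xi2: np.ndarray  # (N,)
    scale: float  # growth factor on the projected (sine) semiaxes
    rng_seed: int
    dispersity: str  # "mono" or "bi"

    @property
    def n(self) -> int:
        return len(self.centers)

    def sin_semiaxes(self) -> tuple[np.ndarray, np.ndarray]:
        return self.scale * np.sin(self.base_xi1), self.scale * np.sin(self.base_xi2)

    def xi(self) -> tuple[np.ndarray, np.ndarray]:
        s1, s2 = self.sin_semiaxes()
        if np.any(s1 >= 1.0):
            raise DomainError("scaled semiaxis reaches the great circle")
        return np.arcsin(s1), np.arcsin(s2)

    def ellipse(self, i: int) -> SphericalEllipse:
        xi1, xi2 = self.xi()
        return make_ellipse(self.centers[i], self.axes[i], float(xi1[i]), float(xi2[i]))

    def ellipses(self) -> list[SphericalEllipse]:
        return [self.ellipse(i) for i in range(self.n)]


def initial_semiaxes(n: int, aspect: float, fraction: float = 0.2) -> tuple[float, float]:
    """Semiaxes giving roughly the target packing fraction at scale 1.

    Uses the small-ellipse area ``pi * xi1 * xi2``; the default 0.2 starts
    the growth schedule well below jamming.
    """
    xi2 = math.sqrt(4.0 * fraction / (n * aspect))
    return aspect * xi2, xi2


def random_configuration(
    n: int,
    xi1: float,
    xi2: float,
    dispersity: str = "mono",
    seed: int = 0,
    size_factor: float = 1.4,
) -> PackingState:
    """Random initial packing: uniform centers and in-plane orientations.

    ``dispersity="bi"`` makes half of the particles smaller by
    ``size_factor`` (both semiaxes divided, aspect ratio preserved).
    Reproducible for a fixed seed.
    """
    if n < 2:
        raise DomainError("need at least two particles")
    if dispersity not in ("mono", "bi"):
        raise DomainError("dispersity must be 'mono' or 'bi'")
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    raw = rng.normal(size=(n, 3))
    axes = raw - (np.sum(raw * centers, axis=1, keepdims=True)) * centers
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    b1 = np.full(n, float(xi1))
    b2 = np.full(n, float(xi2))
    if dispersity == "bi":
        half = n // 2
        b1[:half] /= size_factor
        b2[:half] /= size_factor
    return PackingState(
        centers=centers, axes=axes, base_xi1=b1, base_xi2=b2,
        scale=1.0, rng_seed=int(seed), dispersity=dispersity,
    )


def packing_fraction(state: PackingState) -> float:
    """Total particle area over the sphere area ``4 pi`` (no overlap check)."""
    return sum(ellipse_area(e) for e in state.ellipses()) / (4.0 * math.pi)


# ---------------------------------------------------------------------------
# pair bookkeeping
# ---------------------------------------------------------------------------


def _form_matrix(center, axis, xi1, xi2):
    u = axis
    w = np.cross(center, u)
    return np.outer(u, u) / math.sin(xi1) ** 2 + np.outer(w, w) / math.sin(xi2) ** 2


def _candidate_pairs(centers: np.ndarray, xi1: np.ndarray) -> list[tuple[int, int]]:
    """Pairs whose separation is below the sum of major semiaxes."""
    dots = np.clip(centers @ centers.T, -1.0, 1.0)
    theta = np.arccos(dots)
    bound = xi1[:, None] + xi1[None, :]
    ii, jj = np.where(np.triu(theta < bound, k=1))
    return list(zip(ii.tolist(), jj.tolist()))


def _pair_F(Mi, Mj, tol_t=1e-6, early_exit_above=None):
    res = maximize_lambda1(Mi, Mj, tol_t=tol_t, early_exit_above=early_exit_above)
    return math.inf if res.early_exit else res.value


def pair_contact_values(state: PackingState, tol_t: float = 1e-7) -> dict[tuple[int, int], float]:
    """Contact value per candidate pair (pairs beyond the pre-test omitted)."""
    xi1, xi2 = state.xi()
    forms = [
        _form_matrix(state.centers[i], state.axes[i], xi1[i], xi2[i])
        for i in range(state.n)
    ]
    out = {}
    for i, j in _candidate_pairs(state.centers, xi1):
        out[(i, j)] = _pair_F(forms[i], forms[j], tol_t=tol_t)
    return out


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------


def _rodrigues(v, axis, angle):
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


class _Workspace:
    """Mutable pose arrays + cached quadratic forms during relaxation."""

    def __init__(self, state: PackingState):
        self.centers = state.centers.copy()
        self.axes = state.axes.copy()
        xi1, xi2 = state.xi()
        self.xi1 = xi1
        self.xi2 = xi2
        self.forms = [
            _form_matrix(self.centers[i], self.axes[i], xi1[i], xi2[i])
            for i in range(len(xi1))
        ]

    def rotate_particle(self, i, rotvec):
        angle = float(np.linalg.norm(rotvec))
        if angle == 0.0:
            return
        axis = rotvec / angle
        c = _rodrigues(self.centers[i], axis, angle)
        u = _rodrigues(self.axes[i], axis, angle)
        c = c / np.linalg.norm(c)
        u = u - (u @ c) * c
        u = u / np.linalg.norm(u)
        self.centers[i] = c
        self.axes[i] = u
        self.forms[i] = _form_matrix(c, u, self.xi1[i], self.xi2[i])


def _pair_energy_ws(ws, i, j, kind):
    ci, cj = ws.centers[i], ws.centers[j]
    theta = math.acos(min(1.0, max(-1.0, float(ci @ cj))))
    if theta > ws.xi1[i] + ws.xi1[j]:
        return 0.0
    F = _pair_F(ws.forms[i], ws.forms[j], early_exit_above=1.0)
    return 0.0 if F >= 1.0 else pair_energy(F, kind)


def _total_energy(ws, pairs, kind):
    return sum(_pair_energy_ws(ws, i, j, kind) for i, j in pairs)


def relax(
    state: PackingState,
    kind: PotentialKind | str = PotentialKind.ONE_MINUS,
    max_iters: int = 150,
    gtol: float = 1e-5,
    fd_step: float = 1e-5,
) -> PackingState:
    """Minimize the total overlap energy over particle poses.

    Projected gradient descent with backtracking line search on rigid
    per-particle rotations (two tangent translations + one spin); the energy
    is non-increasing across accepted steps and the loop stops at zero energy
    (no overlaps), at ``gtol`` on the infinity norm of the gradient, or at
    ``max_iters``.  Gradients are central finite differences restricted to
    particles that currently participate in an overlapping pair.
    """
    kind = _coerce_kind(kind)
    ws = _Workspace(state)
    n = state.n
    step = 0.05

    for _ in range(max_iters):
        pairs = _candidate_pairs(ws.centers, ws.xi1)
        # pairs that actually overlap
        active_pairs = [
            (i, j) for i, j in pairs if _pair_energy_ws(ws, i, j, kind) > 0.0
        ]
        if not active_pairs:
            break
        neighbors = {}
        for i, j in pairs:
            neighbors.setdefault(i, []).append(j)
            neighbors.setdefault(j, []).append(i)
        active = sorted({k for ij in active_pairs for k in ij})
        energy0 = _total_energy(ws, pairs, kind)

        grad = np.zeros((n, 3))
        for i in active:
            gens = (ws.axes[i], np.cross(ws.centers[i], ws.axes[i]), ws.centers[i])
            c0, u0, f0 = ws.centers[i].copy(), ws.axes[i].copy(), ws.forms[i].copy()
            for k, g in enumerate(gens):
                vals = []
                for sgn in (+1.0, -1.0):
                    ws.rotate_particle(i, sgn * fd_step * g)
                    vals.append(
                        sum(_pair_energy_ws(ws, *sorted((i, j)), kind) for j in neighbors.get(i, []))
                    )
                    ws.centers[i], ws.axes[i], ws.forms[i] = c0.copy(), u0.copy(), f0.copy()
                grad[i, k] = (vals[0] - vals[1]) / (2.0 * fd_step)
        gmax = float(np.abs(grad).max())
        if gmax < gtol:
            break

        # backtracking line search along the negative gradient
        saved = (ws.centers.copy(), ws.axes.copy(), [f.copy() for f in ws.forms])
        eta = step
        accepted = False
        for _bt in range(25):
            for i in active:
                gens = (ws.axes[i], np.cross(ws.centers[i], ws.axes[i]), ws.centers[i])
                rotvec = -eta * sum(grad[i, k] * gens[k] for k in range(3))
                ws.rotate_particle(i, rotvec)
            energy1 = _total_energy(ws, _candidate_pairs(ws.centers, ws.xi1), kind)
            if energy1 < energy0:
                accepted = True
                step = min(eta * 1.5, 0.2)
                break
            ws.centers, ws.axes, ws.forms = (
                saved[0].copy(), saved[1].copy(), [f.copy() for f in saved[2]],
            )
            eta *= 0.5
        if not accepted:
            break

    return replace(state, centers=ws.centers, axes=ws.axes)


def _min_F(state: PackingState) -> float:
    vals = pair_contact_values(state)
    return min(vals.values(), default=math.inf)


def grow_and_relax(
    state: PackingState,
    growth_step: float = 0.03,
    max_cycles: int = 8,
    kind: PotentialKind | str = PotentialKind.ONE_MINUS,
    relax_kwargs: dict | None = None,
) -> tuple[PackingState, dict]:
    """Grow particles and relax overlaps until the growth step is exhausted.

    Schedule: relax the initial state (shrinking it if its overlaps cannot be
    removed); then repeatedly try ``scale * (1 + growth_step)``, relax, and
    either accept (overlap-free) or revert and halve the step.  The reported
    packing fraction never decreases across accepted cycles and the final
    state satisfies ``min pairwise F >= 1 - 1e-9``.

    Returns the final state and a report with the packing fraction, the
    minimum pairwise contact value, the contact count (pairs with
    ``F < 1 + 1e-3``), cycles used and a convergence flag.
    """
    relax_kwargs = dict(relax_kwargs or {})
    st = relax(state, kind=kind, **relax_kwargs)
    shrink_guard = 0
    while _min_F(st) < 1.0 - _F_TOL and shrink_guard < 20:
        st = relax(replace(st, scale=st.scale * 0.9), kind=kind, **relax_kwargs)
        shrink_guard += 1

    g = growth_step
    cycles = 0
    while cycles < max_cycles and g > 1e-4:
        trial_scale = st.scale * (1.0 + g)
        s1max = trial_scale * float(np.sin(st.base_xi1).max())
        if s1max >= 0.999:
            g *= 0.5
            continue
        trial = relax(replace(st, scale=trial_scale), kind=kind, **relax_kwargs)
        cycles += 1
        if _min_F(trial) >= 1.0 - _F_TOL:
            st = trial
        else:
            g *= 0.5

    vals = pair_contact_values(st)
    min_f = min(vals.values(), default=math.inf)
    report = {
        "packing_fraction": packing_fraction(st),
        "min_F": min_f,
        "n_contacts": sum(1 for f in vals.values() if f < 1.0 + 1e-3),
        "cycles": cycles,
        "converged": bool(min_f >= 1.0 - _F_TOL),
        "scale": st.scale,
        "n": st.n,
        "dispersity": st.dispersity,
        "seed": st.rng_seed,
    }
    return st, report
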