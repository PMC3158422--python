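"""Rigid-body shape superposition and the shape Tanimoto similarity.

The shape Tanimoto of two conformers A and B is

    ST = V_AB / (V_AA + V_BB - V_AB),

where V_AA and V_BB are the Gaussian self-overlap volumes and V_AB is the
cross overlap maximised over all rigid placements of B.  The maximisation is
the expensive step of 3-D neighbouring, which is why the descriptor filters in
:mod:`shapequad.filters` exist: they preclude pairs whose maximal ST provably
cannot reach the search threshold.

The optimiser places both conformers in their principal-axes frames and
refines each of the four proper axis alignments (identity plus the three pi
flips) by quasi-Newton ascent on a rotation-vector + translation chart with
analytic gradients of the Gaussian overlap sum.

A cheap, provable upper bound on ST from the self-overlap volumes alone is
also provided: by Cauchy-Schwarz, V_AB <= sqrt(V_AA * V_BB) for any relative
pose, hence ST <= s / (V_AA + V_BB - s) with s = sqrt(V_AA * V_BB).  This is
the volume-only prefilter applied before any superposition work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .shape import AtomGaussianSet, quadrupoles, self_overlap_volume

__all__ = [
    "OverlapResult",
    "RigidTransform",
    "cross_overlap",
    "optimize_superposition",
    "st_from_volumes",
    "st_volume_bound",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be (3,3) and translation (3,)")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (determinant +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class OverlapResult:
    """Outcome of a superposition optimisation."""

    v_ab: float
    st: float
    transform: RigidTransform
    n_starts: int
    converged: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.st <= 1.0):
            raise ValueError(f"ST out of [0, 1]: {self.st}")
        if self.v_ab < 0:
            raise ValueError("overlap volume must be non-negative")


def st_from_volumes(v_aa: float, v_bb: float, v_ab: float) -> float:
    """Shape Tanimoto from self- and cross-overlap volumes."""
    if v_aa <= 0 or v_bb <= 0:
        raise ValueError("self-overlap volumes must be positive")
    if v_ab < 0:
        raise ValueError("cross overlap must be non-negative")
    denom = v_aa + v_bb - v_ab
    if denom <= 0:
        raise ValueError("non-positive Tanimoto denominator")
    st = v_ab / denom
    if st > 1.0:
        if st > 1.0 + 1e-12:
            raise ValueError(f"ST exceeds 1 beyond floating tolerance: {st}")
        st = 1.0
    return st


def st_volume_bound(v_aa: float, v_bb: float) -> float:
    """Upper bound on achievable ST from self-overlap volumes alone."""
    if v_aa <= 0 or v_bb <= 0:
        raise ValueError("self-overlap volumes must be positive")
    s = math.sqrt(v_aa * v_bb)
    return s / (v_aa + v_bb - s)


def _overlap_kernels(ga: AtomGaussianSet, gb: AtomGaussianSet) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise prefactors K_ij and exponents G_ij of the cross overlap sum."""
    asum = ga.alphas[:, None] + gb.alphas[None, :]
    k = ga.amplitude * gb.amplitude * (math.pi / asum) ** 1.5
    gamma = ga.alphas[:, None] * gb.alphas[None, :] / asum
    return k, gamma


def cross_overlap(
    ga: AtomGaussianSet, gb: AtomGaussianSet, transform: RigidTransform | None = None
) -> float:
    """Integral of rho_A * rho_B with B under an optional rigid transform."""
    k, gamma = _overlap_kernels(ga, gb)
    centers_b = gb.centers if transform is None else transform.apply(gb.centers)
    d2 = np.sum((ga.centers[:, None, :] - centers_b[None, :, :]) ** 2, axis=2)
    return float((k * np.exp(-gamma * d2)).sum())


def _hat(w: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]]
    )


def _exp_so3(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    wh = _hat(w)
    if theta < 1e-9:
        return np.eye(3) + wh + 0.5 * wh @ wh
    return (
        np.eye(3)
        + (math.sin(theta) / theta) * wh
        + ((1.0 - math.cos(theta)) / theta**2) * wh @ wh
    )


def _left_jacobian(w: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3): exp(w + dw) ~ exp(J_l(w) dw) exp(w)."""
    theta = np.linalg.norm(w)
    wh = _hat(w)
    if theta < 1e-6:
        return np.eye(3) + 0.5 * wh + wh @ wh / 6.0
    return (
        np.eye(3)
        + ((1.0 - math.cos(theta)) / theta**2) * wh
        + ((theta - math.sin(theta)) / theta**3) * wh @ wh
    )


def _objective(
    u: np.ndarray,
    ac: np.ndarray,
    bc0: np.ndarray,
    k: np.ndarray,
    gamma: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative overlap and its gradient on the (rotvec, translation) chart."""
    w, t = u[:3], u[3:]
    rot = _exp_so3(w)
    yb = bc0 @ rot.T + t
    diff = ac[:, None, :] - yb[None, :, :]  # (n, m, 3)
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    e = k * np.exp(-gamma * d2)
    f = float(e.sum())
    c = 2.0 * gamma * e  # (n, m)
    # gradient wrt each placed centre y_j, then chain through t and w
    grad_y = np.einsum("ij,ijk->jk", c, diff)  # (m, 3) d f / d y_j
    grad_t = grad_y.sum(axis=0)
    rb = yb - t  # rotated centres
    grad_omega = np.cross(rb, grad_y).sum(axis=0)
    grad_w = _left_jacobian(w).T @ grad_omega
    return -f, -np.concatenate([grad_w, grad_t])


_FLIPS = (
    np.eye(3),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
)


def optimize_superposition(
    ga: AtomGaussianSet,
    gb: AtomGaussianSet,
    max_iter: int = 200,
    extra_starts: int = 0,
    seed: int | None = None,
) -> OverlapResult:
    """Maximise the cross overlap of two Gaussian sets over rigid motions.

    Both conformers are moved to their principal-axes frames; the four proper
    axis alignments seed local quasi-Newton refinements.  ``extra_starts``
    adds uniformly random rotation starts (a seed is then required).  The
    result's ST uses the self-overlap volumes, and its transform maps B's
    original coordinates into A's original frame.
    """
    mu_a, axes_a, *_ = quadrupoles(ga)
    mu_b, axes_b, *_ = quadrupoles(gb)
    ac = (ga.centers - mu_a) @ axes_a
    bc = (gb.centers - mu_b) @ axes_b
    k, gamma = _overlap_kernels(ga, gb)

    starts = [f for f in _FLIPS]
    if extra_starts:
        if seed is None:
            raise ValueError("random restarts require a seed")
        rng = np.random.default_rng(seed)
        for _ in range(extra_starts):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            starts.append(_quat_to_matrix(q))

    best_f = -np.inf
    best_u = np.zeros(6)
    best_r0 = starts[0]
    converged = True
    for r0 in starts:
        bc0 = bc @ r0.T
        res = minimize(
            _objective,
            np.zeros(6),
            args=(ac, bc0, k, gamma),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
        )
        f = -res.fun
        if f > best_f:
            best_f = f
            best_u = res.x
            best_r0 = r0
            converged = bool(res.success)

    rot_local = _exp_so3(best_u[:3]) @ best_r0
    t_local = best_u[3:]
    # compose canonical-frame solution back to original frames:
    # y_world = axes_a @ (rot_local @ axes_b.T @ (b - mu_b) + t_local) + mu_a
    rotation = axes_a @ rot_local @ axes_b.T
    translation = axes_a @ t_local + mu_a - rotation @ mu_b
    transform = RigidTransform(rotation, translation)

    v_aa = self_overlap_volume(ga)
    v_bb = self_overlap_volume(gb)
    v_ab = min(best_f, v_aa + v_bb)  # guard against tiny overshoot
    st = st_from_volumes(v_aa, v_bb, v_ab)
    return OverlapResult(
        v_ab=float(v_ab),
        st=st,
        transform=transform,
        n_starts=len(starts),
        converged=converged,
    )


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
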