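"""Gaussian shape model of a rigid conformer and its steric descriptors.

A conformer is represented as a sum of spherical atom-centred Gaussians,

    rho(r) = sum_i p * exp(-alpha_i |r - c_i|^2),

with the exponent of each atom calibrated so that the integral of its own
Gaussian equals the hard-sphere volume (4/3) pi r_vdw^3.  From this density
we compute three molecular volumes:

* monopole volume  V_mp = integral of rho          (sum of atomic volumes),
* self-overlap     V_so = integral of rho^2        (the V_AA of shape Tanimoto),
* analytic volume  V_an = inclusion-exclusion approximation to the volume of
  the union of the atomic hard spheres, evaluated with closed-form Gaussian
  product integrals,

and the steric shape quadrupoles (Qx, Qy, Qz): the eigenvalues of the
monopole-normalised second-moment tensor of rho about its centroid, ordered
Qx >= Qy >= Qz.  They are rotation/translation invariant proxies for the
squared length, width and height of the conformer, and satisfy the identity
Qx + Qy + Qz = R_g^2 with R_g the density radius of gyration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AMPLITUDE_DEFAULT",
    "BONDI_RADII",
    "AtomGaussianSet",
    "Conformer",
    "DescriptorConfig",
    "RadiusTable",
    "ShapeDescriptors",
    "analytic_volume",
    "build_gaussians",
    "descriptors",
    "monopole_volume",
    "quadrupoles",
    "self_overlap_volume",
]

#: Grant-Pickup Gaussian amplitude; makes a single atom's self-overlap volume
#: equal its monopole volume (p / 2^(3/2) = 1).
AMPLITUDE_DEFAULT: float = 2.0 * math.sqrt(2.0)

#: Bondi van der Waals radii (angstrom) for the common organic elements.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "As": 1.85,
    "Se": 1.90,
    "Br": 1.85,
    "Kr": 2.02,
    "Te": 2.06,
    "I": 1.98,
    "Xe": 2.16,
}

_HYDROGEN_SYMBOLS = frozenset({"H", "D", "T"})


class UnknownElementError(KeyError):
    """Raised when an element has no radius and no default is configured."""


@dataclass(frozen=True)
class RadiusTable:
    """Element -> van der Waals radius (angstrom) with an optional default.

    The default table is Bondi radii with 1.70 angstrom for unlisted elements.
    """

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default: float | None = 1.70

    def __post_init__(self) -> None:
        bad = [el for el, r in self.radii.items() if not r > 0]
        if bad:
            raise ValueError(f"non-positive radius for element(s): {bad}")
        if self.default is not None and not self.default > 0:
            raise ValueError("default radius must be positive")

    def radius(self, element: str) -> float:
        r = self.radii.get(element)
        if r is None:
            if self.default is None:
                raise UnknownElementError(
                    f"no van der Waals radius for element {element!r} "
                    "and no default radius configured"
                )
            return self.default
        return r


@dataclass(frozen=True)
class Conformer:
    """A single rigid 3-D conformer: element symbols plus coordinates."""

    id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3) angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"conformer {self.id!r} has non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def without_hydrogens(self) -> "Conformer":
        keep = [i for i, el in enumerate(self.elements) if el not in _HYDROGEN_SYMBOLS]
        if len(keep) == self.n_atoms:
            return self
        return Conformer(
            self.id,
            tuple(self.elements[i] for i in keep),
            self.coords[keep],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        return replace(self, coords=self.coords @ np.asarray(rotation).T + translation)


@dataclass(frozen=True)
class AtomGaussianSet:
    """Per-atom Gaussians calibrated to hard-sphere atomic volumes."""

    centers: np.ndarray  # (n, 3)
    alphas: np.ndarray  # (n,) angstrom^-2
    amplitude: float  # shared prefactor p
    volumes: np.ndarray  # (n,) hard-sphere volumes (4/3) pi r^3

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        alphas = np.asarray(self.alphas, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 3:
            raise ValueError("centers must be (n, 3)")
        if alphas.shape != (centers.shape[0],) or volumes.shape != alphas.shape:
            raise ValueError("alphas/volumes shape mismatch with centers")
        if centers.shape[0] == 0:
            raise ValueError("empty Gaussian set")
        if not np.all(alphas > 0):
            raise ValueError("all Gaussian exponents must be positive")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "volumes", volumes)

    @property
    def n_atoms(self) -> int:
        return self.centers.shape[0]

    def density(self, points: np.ndarray) -> np.ndarray:
        """rho evaluated at an (m, 3) array of points (used by test oracles)."""
        d2 = np.sum((points[:, None, :] - self.centers[None, :, :]) ** 2, axis=2)
        return self.amplitude * np.exp(-d2 * self.alphas[None, :]).sum(axis=1)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomGaussianSet":
        return replace(
            self, centers=self.centers @ np.asarray(rotation).T + np.asarray(translation)
        )


@dataclass(frozen=True)
class ShapeDescriptors:
    """The full steric descriptor bundle of one conformer.

    Quadrupoles are monopole-normalised second moments (angstrom^2) unless the
    producing :class:`DescriptorConfig` requested the raw variant scaled by
    V_mp (angstrom^5).
    """

    id: str
    n_atoms: int
    v_an: float
    v_mp: float
    v_so: float
    qx: float
    qy: float
    qz: float
    rg: float
    centroid: np.ndarray
    principal_axes: np.ndarray  # columns = principal axes, det = +1

    def volume(self, volume_type: str) -> float:
        try:
            return {"an": self.v_an, "mp": self.v_mp, "so": self.v_so}[volume_type]
        except KeyError:
            raise ValueError(f"unknown volume type {volume_type!r}") from None

    def q_component(self, component: str) -> float:
        try:
            return {"x": self.qx, "y": self.qy, "z": self.qz}[component]
        except KeyError:
            raise ValueError(f"unknown quadrupole component {component!r}") from None


@dataclass(frozen=True)
class DescriptorConfig:
    """Knobs of the shape model.

    amplitude
        Gaussian prefactor p; the default 2*sqrt(2) makes an isolated atom's
        V_so equal its hard-sphere volume.
    include_hydrogens
        Heavy-atom shape model by default; hydrogens contribute little shape.
    max_order
        Truncation order of the inclusion-exclusion series for V_an.
    raw_quadrupoles
        If True, report quadrupoles multiplied by V_mp (angstrom^5) instead of
        the monopole-normalised values (angstrom^2).
    """

    radii: RadiusTable = field(default_factory=RadiusTable)
    amplitude: float = AMPLITUDE_DEFAULT
    include_hydrogens: bool = False
    max_order: int = 3
    overlap_cutoff_scale: float = 1.2
    raw_quadrupoles: bool = False


def build_gaussians(
    conformer: Conformer,
    radii: RadiusTable | None = None,
    amplitude: float = AMPLITUDE_DEFAULT,
    include_hydrogens: bool = False,
) -> AtomGaussianSet:
    """Calibrate one Gaussian per atom against its hard-sphere volume.

    The exponent solves p * (pi/alpha)^(3/2) = (4/3) pi r^3, i.e.
    alpha = pi * (3 p / (4 pi))^(2/3) / r^2.
    """
    if radii is None:
        radii = RadiusTable()
    if not include_hydrogens:
        conformer = conformer.without_hydrogens()
    if conformer.n_atoms == 0:
        raise ValueError(
            f"conformer {conformer.id!r} has no atoms after the hydrogen policy"
        )
    if not amplitude > 0:
        raise ValueError("amplitude must be positive")
    r = np.array([radii.radius(el) for el in conformer.elements])
    alphas = math.pi * (3.0 * amplitude / (4.0 * math.pi)) ** (2.0 / 3.0) / r**2
    volumes = (4.0 / 3.0) * math.pi * r**3
    return AtomGaussianSet(conformer.coords, alphas, amplitude, volumes)


def monopole_volume(g: AtomGaussianSet) -> float:
    """Integral of rho: the sum of calibrated atomic volumes."""
    return float(g.volumes.sum())


def self_overlap_volume(g: AtomGaussianSet) -> float:
    """Integral of rho^2 via the closed-form pairwise Gaussian product sum."""
    a = g.alphas
    asum = a[:, None] + a[None, :]
    d2 = np.sum((g.centers[:, None, :] - g.centers[None, :, :]) ** 2, axis=2)
    terms = (
        g.amplitude**2
        * (math.pi / asum) ** 1.5
        * np.exp(-a[:, None] * a[None, :] * d2 / asum)
    )
    return float(terms.sum())


def _product_integral(g: AtomGaussianSet, subset: tuple[int, ...], d2: np.ndarray) -> float:
    """Closed-form integral of the product of the Gaussians in ``subset``."""
    a = g.alphas[list(subset)]
    asum = a.sum()
    cross = 0.0
    for u, i in enumerate(subset):
        for j in subset[u + 1 :]:
            cross += g.alphas[i] * g.alphas[j] * d2[i, j]
    return g.amplitude ** len(subset) * (math.pi / asum) ** 1.5 * math.exp(-cross / asum)


def analytic_volume(
    g: AtomGaussianSet,
    max_order: int = 3,
    overlap_cutoff_scale: float = 1.2,
) -> float:
    """Inclusion-exclusion estimate of the hard-sphere union volume.

    V_an = sum_k (-1)^(k+1) sum_{|S|=k} integral of prod_{i in S} g_i, truncated
    at ``max_order``.  Subsets are restricted to cliques of atoms whose centre
    distance is below ``overlap_cutoff_scale`` times the radius sum, which
    prunes negligible far-apart intersection terms.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    n = g.n_atoms
    d2 = np.sum((g.centers[:, None, :] - g.centers[None, :, :]) ** 2, axis=2)
    radii = (3.0 * g.volumes / (4.0 * math.pi)) ** (1.0 / 3.0)
    cutoff2 = (overlap_cutoff_scale * (radii[:, None] + radii[None, :])) ** 2
    close = d2 <= cutoff2

    total = float(g.volumes.sum())  # k = 1 term
    if max_order == 1 or n == 1:
        return total

    # grow cliques one atom at a time; neighbour lists keep this cheap
    neighbors = [np.nonzero(close[i])[0] for i in range(n)]
    stack: list[tuple[tuple[int, ...], np.ndarray]] = [
        ((i,), neighbors[i][neighbors[i] > i]) for i in range(n)
    ]
    while stack:
        subset, cand = stack.pop()
        k = len(subset) + 1
        for j in cand:
            new = subset + (int(j),)
            sign = -1.0 if k % 2 == 0 else 1.0
            total += sign * _product_integral(g, new, d2)
            if k < max_order:
                stack.append((new, cand[(cand > j) & close[j, cand]]))
    return total


def _deterministic_frame(eigvecs: np.ndarray) -> np.ndarray:
    """Fix eigenvector signs to get a reproducible proper rotation."""
    axes = eigvecs.copy()
    for k in range(3):
        col = axes[:, k]
        lead = np.argmax(np.abs(col))
        if col[lead] < 0:
            axes[:, k] = -col
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes


def quadrupoles(
    g: AtomGaussianSet,
) -> tuple[np.ndarray, np.ndarray, float, float, float, float]:
    """Centroid, principal axes, (Qx, Qy, Qz) and R_g of the shape density.

    The second-moment tensor is computed in closed form: each atom contributes
    V_i * ((c_i - mu)(c_i - mu)^T + I / (2 alpha_i)), normalised by V_mp.
    Eigenvalues are sorted descending (Qx >= Qy >= Qz); R_g = sqrt(trace).
    """
    v = g.volumes
    vmp = v.sum()
    centroid = (v[:, None] * g.centers).sum(axis=0) / vmp
    rel = g.centers - centroid
    m = (v[:, None, None] * rel[:, :, None] * rel[:, None, :]).sum(axis=0)
    m += np.eye(3) * (v / (2.0 * g.alphas)).sum()
    m /= vmp
    eigvals, eigvecs = np.linalg.eigh(m)  # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    axes = _deterministic_frame(eigvecs[:, order])
    qx, qy, qz = (float(x) for x in eigvals)
    rg = math.sqrt(qx + qy + qz)
    return centroid, axes, qx, qy, qz, rg


def descriptors(conformer: Conformer, config: DescriptorConfig | None = None) -> ShapeDescriptors:
    """Compute the full descriptor bundle for one conformer."""
    if config is None:
        config = DescriptorConfig()
    g = build_gaussians(
        conformer, config.radii, config.amplitude, config.include_hydrogens
    )
    v_mp = monopole_volume(g)
    v_so = self_overlap_volume(g)
    v_an = analytic_volume(g, config.max_order, config.overlap_cutoff_scale)
    centroid, axes, qx, qy, qz, rg = quadrupoles(g)
    if config.raw_quadrupoles:
        qx, qy, qz = qx * v_mp, qy * v_mp, qz * v_mp
    return ShapeDescriptors(
        id=conformer.id,
        n_atoms=g.n_atoms,
        v_an=v_an,
        v_mp=v_mp,
        v_so=v_so,
        qx=qx,
        qy=qy,
        qz=qz,
        rg=rg,
        centroid=centroid,
        principal_axes=axes,
    )
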