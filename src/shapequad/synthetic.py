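"""Synthetic drug-like conformers and labelled pair corpora.

Real filter construction runs over billions of neighbour pairs from a
chemical database; for development and validation this module generates
heavy-atom conformers with drug-like sizes and mixed van der Waals radii, and
assembles fully reproducible pair corpora with controlled shape similarity:

* "similar" pairs are a conformer and a jittered, rigidly re-posed copy of
  itself (coordinate noise of scale ``perturbation_sigma``), which
  concentrates labels near ST = 1;
* "dissimilar" pairs are two independent random conformers.

Every pair is labelled with the shape Tanimoto produced by the actual
superposition optimiser, so the ground truth is internally consistent with
the screening pipeline that consumes it.  There is no bond topology, valence
or torsion model: a pure shape method only needs plausible point clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .shape import (
    AMPLITUDE_DEFAULT,
    Conformer,
    DescriptorConfig,
    RadiusTable,
    ShapeDescriptors,
    build_gaussians,
    descriptors,
)
from .superpose import optimize_superposition

__all__ = [
    "DEFAULT_PALETTE",
    "Corpus",
    "CorpusSpec",
    "build_corpus",
    "perturb_conformer",
    "random_conformer",
]

#: (element, weight) draws for synthetic heavy atoms; roughly the element mix
#: of organic drug-like molecules.
DEFAULT_PALETTE: tuple[tuple[str, float], ...] = (
    ("C", 0.65),
    ("N", 0.12),
    ("O", 0.14),
    ("S", 0.04),
    ("F", 0.03),
    ("Cl", 0.02),
)

_BOND_MIN, _BOND_MAX = 1.3, 1.6  # angstrom, typical heavy-atom bond lengths
_CORE_SCALE = 0.8  # hard-core rejection below this fraction of the radius sum
_CHAIN_BIAS = 0.65  # probability of extending the chain end vs. branching
_MAX_REJECTS = 10_000


def _uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_conformer(
    n_atoms: int,
    palette: Sequence[tuple[str, float]] = DEFAULT_PALETTE,
    seed: int | np.random.Generator = 0,
    conformer_id: str = "synthetic",
    radii: RadiusTable | None = None,
) -> Conformer:
    """Grow a random heavy-atom conformer by sequential bonded placement.

    Each new atom is placed at a bonded distance (1.3-1.6 angstrom) from an
    anchor atom in a random direction: usually the previously placed atom
    (chain extension), occasionally a uniformly drawn earlier atom
    (branching).  The chain bias keeps the shapes elongated and diverse, like
    real scaffolds, instead of collapsing into near-spherical blobs whose
    descriptors are all alike.  Placements closer than the hard core to any
    prior atom are re-drawn.  Deterministic for a given seed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if radii is None:
        radii = RadiusTable()
    symbols = [p[0] for p in palette]
    weights = np.array([p[1] for p in palette], dtype=float)
    weights /= weights.sum()

    elements = [str(rng.choice(symbols, p=weights)) for _ in range(n_atoms)]
    coords = np.zeros((n_atoms, 3))
    r = np.array([radii.radius(el) for el in elements])
    rejects = 0
    for i in range(1, n_atoms):
        while True:
            if i == 1 or rng.random() < _CHAIN_BIAS:
                anchor = i - 1
            else:
                anchor = int(rng.integers(i))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rng.uniform(_BOND_MIN, _BOND_MAX)
            pos = coords[anchor] + dist * direction
            gaps = np.linalg.norm(coords[:i] - pos, axis=1)
            # hard core at 0.8x the mean vdW radius of the pair: blocks
            # collapsed geometry while admitting bonded-distance neighbours
            if np.all(gaps >= _CORE_SCALE * (r[:i] + r[i]) / 2.0):
                coords[i] = pos
                break
            rejects += 1
            if rejects > _MAX_REJECTS:
                raise RuntimeError(
                    f"could not place atom {i} after {_MAX_REJECTS} rejections"
                )
    return Conformer(conformer_id, tuple(elements), coords)


def perturb_conformer(
    c: Conformer,
    sigma: float,
    seed: int | np.random.Generator,
    conformer_id: str | None = None,
) -> Conformer:
    """Jitter coordinates by isotropic noise then re-pose rigidly.

    sigma = 0 yields an exact rigid copy (ST = 1 up to optimiser tolerance).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = c.coords + rng.normal(scale=sigma, size=c.coords.shape) if sigma > 0 else c.coords.copy()
    rot = _uniform_rotation(rng)
    trans = rng.uniform(-5.0, 5.0, size=3)
    return Conformer(
        conformer_id if conformer_id is not None else c.id,
        c.elements,
        coords @ rot.T + trans,
    )


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions of a synthetic pair corpus.  The seed is mandatory."""

    n_train_pairs: int
    n_test_pairs: int
    seed: int
    atoms_min: int = 6
    atoms_max: int = 24
    perturbation_sigma: float = 0.05
    fraction_similar: float = 0.3
    palette: tuple[tuple[str, float], ...] = DEFAULT_PALETTE

    def __post_init__(self) -> None:
        if self.n_train_pairs <= 0 or self.n_test_pairs <= 0:
            raise ValueError("pair counts must be positive")
        if not (1 <= self.atoms_min <= self.atoms_max):
            raise ValueError("need 1 <= atoms_min <= atoms_max")
        if self.perturbation_sigma < 0:
            raise ValueError("perturbation_sigma must be non-negative")
        if not (0.0 <= self.fraction_similar <= 1.0):
            raise ValueError("fraction_similar must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is required")


@dataclass(frozen=True)
class Corpus:
    """Labelled pair corpus plus the descriptors of every conformer."""

    train_pairs: pd.DataFrame  # id1, id2, st
    test_pairs: pd.DataFrame
    descriptors: Mapping[str, ShapeDescriptors]
    conformers: Mapping[str, Conformer]

    def descriptor_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": d.id,
                "n_atoms": d.n_atoms,
                "v_an": d.v_an,
                "v_mp": d.v_mp,
                "v_so": d.v_so,
                "qx": d.qx,
                "qy": d.qy,
                "qz": d.qz,
                "rg": d.rg,
            }
            for d in self.descriptors.values()
        ]
        return pd.DataFrame(rows).sort_values("id", ignore_index=True)


def _label_st(a: Conformer, b: Conformer, config: DescriptorConfig) -> float:
    ga = build_gaussians(a, config.radii, config.amplitude, config.include_hydrogens)
    gb = build_gaussians(b, config.radii, config.amplitude, config.include_hydrogens)
    return optimize_superposition(ga, gb).st


def _build_split(
    split: str,
    n_pairs: int,
    spec: CorpusSpec,
    rng: np.random.Generator,
    config: DescriptorConfig,
    conformers: dict[str, Conformer],
) -> pd.DataFrame:
    n_similar = int(round(spec.fraction_similar * n_pairs))
    records = []
    serial = 0

    def new_conformer() -> Conformer:
        nonlocal serial
        cid = f"{split}-{serial:05d}"
        serial += 1
        n = int(rng.integers(spec.atoms_min, spec.atoms_max + 1))
        c = random_conformer(n, spec.palette, rng, conformer_id=cid)
        conformers[cid] = c
        return c

    for i in range(n_pairs):
        if i < n_similar:
            base = new_conformer()
            twin = perturb_conformer(
                base, spec.perturbation_sigma, rng, conformer_id=f"{split}-{serial:05d}"
            )
            serial += 1
            conformers[twin.id] = twin
            a, b = base, twin
        else:
            a, b = new_conformer(), new_conformer()
        records.append({"id1": a.id, "id2": b.id, "st": _label_st(a, b, config)})
    return pd.DataFrame(records)


def build_corpus(spec: CorpusSpec, config: DescriptorConfig | None = None) -> Corpus:
    """Generate train/test pair corpora with optimiser-ST labels.

    Train and test splits draw disjoint conformer-id namespaces and
    independent random streams derived from the one corpus seed, so the two
    splits share a generator but no conformers.
    """
    if config is None:
        config = DescriptorConfig()
    root = np.random.SeedSequence(spec.seed)
    rng_train, rng_test = (np.random.default_rng(s) for s in root.spawn(2))
    conformers: dict[str, Conformer] = {}
    train = _build_split("train", spec.n_train_pairs, spec, rng_train, config, conformers)
    test = _build_split("test", spec.n_test_pairs, spec, rng_test, config, conformers)
    desc = {cid: descriptors(c, config) for cid, c in conformers.items()}
    return Corpus(
        train_pairs=train, test_pairs=test, descriptors=desc, conformers=conformers
    )
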