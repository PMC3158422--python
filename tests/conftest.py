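"""Shared fixtures: small deterministic conformers and the study corpus.

The full-scale corpus (2,000 training / 5,000 held-out pairs, 30% perturbation
pairs at sigma = 0.05 angstrom) is expensive to label, so it is built once per
session and shared by every test that needs study-scale statistics.
"""

from __future__ import annotations

import numpy as np
import pytest

from shapequad import (
    Conformer,
    CorpusSpec,
    build_corpus,
    build_gaussians,
    random_conformer,
)

CORPUS_SEED = 1


@pytest.fixture(scope="session")
def study_corpus():
    """The canonical desk-scale corpus used by the acceptance-level checks."""
    spec = CorpusSpec(n_train_pairs=2000, n_test_pairs=5000, seed=CORPUS_SEED)
    return build_corpus(spec)


@pytest.fixture(scope="session")
def small_corpus():
    """A fast corpus for unit-level pipeline tests."""
    spec = CorpusSpec(n_train_pairs=60, n_test_pairs=80, seed=11)
    return build_corpus(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def single_atom():
    return Conformer("atom", ("F",), np.zeros((1, 3)))


@pytest.fixture()
def chain6():
    """Six carbons on a line at 1.5 angstrom spacing."""
    coords = np.zeros((6, 3))
    coords[:, 0] = 1.5 * np.arange(6)
    return Conformer("chain6", ("C",) * 6, coords)


def random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniform random proper rotation and a bounded random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-10, 10, size=3)
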