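"""Shape-model tests: closed forms, numeric-integration oracles, invariances."""

import math

import numpy as np
import pytest

from shapequad import (
    AMPLITUDE_DEFAULT,
    Conformer,
    DescriptorConfig,
    RadiusTable,
    analytic_volume,
    build_gaussians,
    descriptors,
    monopole_volume,
    quadrupoles,
    random_conformer,
    self_overlap_volume,
)
from shapequad.shape import UnknownElementError

from conftest import random_rigid


def grid_integral(func, centers, radii_extent=5.0, spacing=0.1):
    """Midpoint-rule quadrature of ``func`` on a box around the centers."""
    lo = centers.min(axis=0) - radii_extent
    hi = centers.max(axis=0) + radii_extent
    axes = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
    total = 0.0
    # slab by slab along x to bound memory
    yz = np.stack(np.meshgrid(axes[1], axes[2], indexing="ij"), axis=-1).reshape(-1, 2)
    for x in axes[0]:
        pts = np.column_stack([np.full(len(yz), x), yz])
        total += func(pts).sum()
    return total * spacing**3


class TestCalibration:
    def test_carbon_exponent_closed_form(self):
        c = Conformer("c", ("C",), np.zeros((1, 3)))
        g = build_gaussians(c)
        p = AMPLITUDE_DEFAULT
        expected = math.pi * (3 * p / (4 * math.pi)) ** (2 / 3) / 1.70**2
        assert g.alphas[0] == pytest.approx(expected, rel=1e-12)
        assert g.alphas[0] == pytest.approx(0.8366, abs=1e-4)

    def test_isolated_atom_volume_identities(self, single_atom):
        g = build_gaussians(single_atom)  # fluorine, r = 1.47
        sphere = (4 / 3) * math.pi * 1.47**3
        assert sphere == pytest.approx(13.31, abs=0.005)
        for vol in (monopole_volume(g), self_overlap_volume(g), analytic_volume(g)):
            assert vol == pytest.approx(sphere, rel=1e-10)
        # calibration: amplitude-weighted Gaussian integral equals V_i
        integral = g.amplitude * (math.pi / g.alphas[0]) ** 1.5
        assert integral == pytest.approx(sphere, rel=1e-10)

    def test_empty_conformer_rejected(self):
        c = Conformer("h2", ("H", "H"), np.array([[0.0, 0, 0], [0.74, 0, 0]]))
        with pytest.raises(ValueError, match="hydrogen policy"):
            build_gaussians(c)  # all-hydrogen conformer vanishes by default
        assert build_gaussians(c, include_hydrogens=True).n_atoms == 2

    def test_unknown_element_without_default_is_named(self):
        table = RadiusTable(radii={"C": 1.70}, default=None)
        c = Conformer("x", ("C", "Uuq"), np.array([[0.0, 0, 0], [1.5, 0, 0]]))
        with pytest.raises(UnknownElementError, match="Uuq"):
            build_gaussians(c, radii=table)


class TestVolumes:
    def test_monopole_is_sum_of_atomic_spheres(self):
        c = Conformer("cc", ("C", "C"), np.array([[0.0, 0, 0], [37.0, 0, 0]]))
        g = build_gaussians(c)
        assert monopole_volume(g) == pytest.approx(2 * 20.5795, abs=2e-3)

    def test_monopole_matches_grid_quadrature(self):
        c = random_conformer(10, seed=5, conformer_id="g10")
        g = build_gaussians(c)
        numeric = grid_integral(g.density, g.centers)
        assert monopole_volume(g) == pytest.approx(numeric, rel=5e-3)

    def test_self_overlap_matches_grid_quadrature(self):
        c = random_conformer(10, seed=6, conformer_id="s2")
        g = build_gaussians(c)
        numeric = grid_integral(lambda p: g.density(p) ** 2, g.centers)
        assert self_overlap_volume(g) == pytest.approx(numeric, rel=5e-3)

    def test_self_overlap_distant_atoms_additive(self):
        far = Conformer("far", ("C", "C"), np.array([[0.0, 0, 0], [100.0, 0, 0]]))
        single = Conformer("one", ("C",), np.zeros((1, 3)))
        v_far = self_overlap_volume(build_gaussians(far))
        v_one = self_overlap_volume(build_gaussians(single))
        assert v_far == pytest.approx(2 * v_one, rel=1e-12)

    def test_coincident_pair_analytic_volume_collapses(self):
        c = Conformer("dup", ("C", "C"), np.zeros((2, 3)))
        g = build_gaussians(c)
        single = monopole_volume(g) / 2
        # 2V - int g^2 = V under the amplitude calibration
        assert analytic_volume(g, max_order=2) == pytest.approx(single, rel=1e-10)

    def test_analytic_volume_matches_monte_carlo_union(self, chain6, rng):
        g = build_gaussians(chain6)
        radii = np.full(6, 1.70)
        lo = g.centers.min(axis=0) - 1.8
        hi = g.centers.max(axis=0) + 1.8
        box = np.prod(hi - lo)
        n_total, hits = 10_000_000, 0
        for _ in range(10):
            pts = rng.uniform(lo, hi, size=(n_total // 10, 3))
            d2 = np.sum((pts[:, None, :] - g.centers[None, :, :]) ** 2, axis=2)
            hits += int(np.any(d2 <= radii**2, axis=1).sum())
        mc_volume = box * hits / n_total
        assert analytic_volume(g, max_order=3) == pytest.approx(mc_volume, rel=0.03)

    def test_max_order_validation(self, chain6):
        with pytest.raises(ValueError):
            analytic_volume(build_gaussians(chain6), max_order=0)


class TestQuadrupoles:
    def test_single_atom_isotropic(self, single_atom):
        g = build_gaussians(single_atom)
        _, _, qx, qy, qz, rg = quadrupoles(g)
        expected = 1 / (2 * g.alphas[0])
        assert (qx, qy, qz) == pytest.approx((expected,) * 3, rel=1e-12)
        assert expected == pytest.approx(0.447, abs=5e-4)
        assert rg**2 == pytest.approx(3 * expected, rel=1e-12)

    def test_axial_pair_degenerate_transverse(self):
        c = Conformer("ax", ("C", "C"), np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        g = build_gaussians(c)
        _, _, qx, qy, qz, _ = quadrupoles(g)
        iso = 1 / (2 * g.alphas[0])
        assert qy == pytest.approx(iso, rel=1e-12)
        assert qz == pytest.approx(iso, rel=1e-12)
        assert qx > qy

    @pytest.mark.parametrize("case", range(20))
    def test_rigid_invariance(self, case):
        rng = np.random.default_rng(1000 + case)
        c = random_conformer(int(rng.integers(5, 25)), seed=rng, conformer_id="inv")
        rot, trans = random_rigid(rng)
        d0 = descriptors(c)
        d1 = descriptors(c.transformed(rot, trans))
        for name in ("v_an", "v_mp", "v_so", "qx", "qy", "qz", "rg"):
            assert getattr(d1, name) == pytest.approx(
                getattr(d0, name), rel=1e-8
            ), name
        # centroid transforms covariantly
        np.testing.assert_allclose(d1.centroid, rot @ d0.centroid + trans, atol=1e-8)


class TestDescriptorBundle:
    def test_single_atom_bundle(self, single_atom):
        d = descriptors(single_atom)
        assert d.v_an == pytest.approx(d.v_mp, rel=1e-12)
        assert d.v_so == pytest.approx(d.v_mp, rel=1e-12)
        assert d.qx == pytest.approx(d.qz, rel=1e-12)

    @pytest.mark.parametrize("seed", [3, 17, 92])
    def test_ordering_and_trace_identity(self, seed):
        c = random_conformer(20, seed=seed, conformer_id="t")
        d = descriptors(c)
        assert d.qx >= d.qy >= d.qz > 0
        assert d.qx + d.qy + d.qz == pytest.approx(d.rg**2, rel=1e-9)
        assert abs(np.linalg.det(d.principal_axes) - 1) < 1e-10
        assert d.v_so >= d.v_mp  # bonded-distance overlaps present

    def test_mirror_image_identical(self):
        c = random_conformer(12, seed=8, conformer_id="m")
        mirrored = Conformer("m2", c.elements, c.coords * np.array([-1.0, 1.0, 1.0]))
        d0, d1 = descriptors(c), descriptors(mirrored)
        for name in ("v_an", "v_mp", "v_so", "qx", "qy", "qz", "rg"):
            assert getattr(d1, name) == pytest.approx(getattr(d0, name), rel=1e-10)

    def test_raw_quadrupole_variant_scales_by_monopole(self):
        c = random_conformer(10, seed=9, conformer_id="r")
        d_norm = descriptors(c)
        d_raw = descriptors(c, DescriptorConfig(raw_quadrupoles=True))
        assert d_raw.qx == pytest.approx(d_norm.qx * d_norm.v_mp, rel=1e-12)

    def test_distant_fragments_additive(self):
        a = random_conformer(6, seed=21, conformer_id="fa")
        b = random_conformer(7, seed=22, conformer_id="fb")
        merged = Conformer(
            "ab",
            a.elements + b.elements,
            np.vstack([a.coords, b.coords + np.array([60.0, 0, 0])]),
        )
        da, db, dm = descriptors(a), descriptors(b), descriptors(merged)
        assert dm.v_so == pytest.approx(da.v_so + db.v_so, rel=1e-9)
        assert dm.v_an == pytest.approx(da.v_an + db.v_an, rel=1e-9)
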