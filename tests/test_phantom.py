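import numpy as np
import pytest
from scipy.stats import kstest

from abseit.phantom import (CONTRAST_RANGE, PhantomSpec, ShapeSpec,
                            build_phantom, inverse_transform, perturb_field,
                            phys_to_pixel, rasterize_target,
                            sample_background, sample_enclosure, shape_mask)


def _spec(kind="sphere", t=(0, 0, 0), s=(1, 1, 1), euler=(0, 0, 0),
          contrast=1.0):
    return ShapeSpec(kind=kind, t=t, s=s, euler=euler, contrast=contrast)


class TestInverseTransform:
    def test_identity(self):
        pts = np.array([[0.3, -0.2, 1.0], [1, 0, 0]])
        assert np.allclose(inverse_transform(pts, _spec()), pts)

    def test_translation_then_scaling(self):
        assert np.allclose(
            inverse_transform([[1, 0, 0]], _spec(t=(1, 0, 0))), [[0, 0, 0]])
        assert np.allclose(
            inverse_transform([[2, 0, 0]], _spec(s=(2, 2, 2))), [[1, 0, 0]])

    def test_rotation_after_translation(self):
        # 90 deg about z: R(v - t); with t=(1,0,0), point (1,1,0) -> R(0,1,0)
        spec = _spec(t=(1, 0, 0), euler=(0, 0, np.pi / 2))
        out = inverse_transform([[1, 1, 0]], spec)
        assert np.allclose(out, [[-1, 0, 0]], atol=1e-12)

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            _spec(s=(1, 0, 1))


class TestShapeMask:
    @pytest.mark.parametrize("kind", ["sphere", "cube", "octahedron"])
    def test_origin_inside(self, kind):
        assert shape_mask(kind, [[0, 0, 0]])[0]

    def test_corner_point(self):
        p = [[1, 1, 1]]
        assert shape_mask("cube", p)[0]
        assert not shape_mask("octahedron", p)[0]
        assert not shape_mask("sphere", p)[0]

    def test_boundary_included(self):
        assert shape_mask("sphere", [[1, 0, 0]])[0]
        assert shape_mask("octahedron", [[0.5, 0.5, 0]])[0]

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            shape_mask("torus", [[0, 0, 0]])


class TestSampling:
    def test_enclosure_ranges(self):
        rng = np.random.default_rng(0)
        r = 28.0
        specs = [sample_enclosure(rng, r) for _ in range(10_000)]
        s = np.array([sp.s for sp in specs])
        assert s.min() >= 0.10 * r and s.max() <= 0.80 * r
        t = np.array([sp.t for sp in specs])
        assert np.hypot(t[:, 0], t[:, 1]).max() <= 0.8 * r
        eul = np.array([sp.euler for sp in specs])
        assert eul.min() >= 0 and eul.max() < 2 * np.pi
        logc = np.log10([sp.contrast for sp in specs])
        assert kstest(logc, "uniform", args=(-2, 4)).pvalue > 0.01
        assert logc.min() >= np.log10(CONTRAST_RANGE[0])
        assert logc.max() <= np.log10(CONTRAST_RANGE[1])

    def test_background_loguniform(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_background(rng) for _ in range(10_000)])
        assert draws.min() >= 1e-5 and draws.max() <= 1.0
        assert kstest(np.log10(draws), "uniform", args=(-5, 5)).pvalue > 0.01

    def test_seed_determinism(self):
        a = sample_enclosure(np.random.default_rng(42), 28.0)
        b = sample_enclosure(np.random.default_rng(42), 28.0)
        assert a.kind == b.kind and np.array_equal(a.t, b.t) \
            and a.contrast == b.contrast


class TestPerturbField:
    def test_zero_std_identity(self, rng):
        v = np.abs(rng.normal(size=50)) + 0.1
        assert np.array_equal(perturb_field(v, 0.0, rng), v)

    def test_multiplier_statistics(self):
        rng = np.random.default_rng(2)
        v = np.ones(10_000)
        out = perturb_field(v, 1e-2, rng)
        assert out.shape == v.shape
        assert out.mean() == pytest.approx(1.0, abs=3e-4)  # 3 sigma CLT band
        assert (out > 0).all()

    def test_negative_std_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb_field(np.ones(3), -1.0, rng)


class TestBuildPhantom:
    def test_uniform(self, mesh_small):
        ph = build_phantom(mesh_small,
                           PhantomSpec(sigma_bg=0.3, perturb_std=0.0))
        assert np.array_equal(ph.sigma, np.full(mesh_small.n_elements, 0.3))

    def test_sphere_paint(self, mesh_small):
        enc = _spec(s=(8, 8, 8), contrast=10.0)
        ph = build_phantom(mesh_small, PhantomSpec(
            sigma_bg=0.1, enclosures=(enc,), perturb_std=0.0))
        r = np.linalg.norm(mesh_small.centroids, axis=1)
        inside = r <= 7.0  # safely inside (centroid test is exact at 8)
        outside = r >= 9.0
        assert np.allclose(ph.sigma[inside], 1.0)
        assert np.allclose(ph.sigma[outside], 0.1)

    def test_overlap_last_writer_wins(self, mesh_small):
        e1 = _spec(s=(8, 8, 8), contrast=10.0)
        e2 = _spec(s=(5, 5, 5), contrast=0.1)
        ph = build_phantom(mesh_small, PhantomSpec(
            sigma_bg=0.1, enclosures=(e1, e2), perturb_std=0.0))
        r = np.linalg.norm(mesh_small.centroids, axis=1)
        assert np.allclose(ph.sigma[r <= 4.0], 0.01)

    def test_empty_enclosure_warns(self, mesh_small):
        off = _spec(t=(0, 0, 20.0), s=(3, 3, 3), contrast=10.0)
        with pytest.warns(UserWarning):
            build_phantom(mesh_small, PhantomSpec(
                sigma_bg=0.1, enclosures=(off,), perturb_std=0.0))

    def test_deterministic_given_spec(self, mesh_small):
        spec = PhantomSpec(sigma_bg=0.2, enclosures=(_spec(s=(5, 5, 5)),),
                           perturb_std=1e-3, seed=9)
        a = build_phantom(mesh_small, spec)
        b = build_phantom(mesh_small, spec)
        assert np.array_equal(a.sigma, b.sigma)

    def test_strictly_positive(self, mesh_small, rng):
        spec = PhantomSpec(sigma_bg=1e-5,
                           enclosures=(_spec(s=(5, 5, 5), contrast=0.01),),
                           perturb_std=1e-2)
        assert (build_phantom(mesh_small, spec, rng).sigma > 0).all()


class TestRasterize:
    def test_uniform_constant(self, mesh_small):
        ph = build_phantom(mesh_small,
                           PhantomSpec(sigma_bg=0.3, perturb_std=0.0))
        img = rasterize_target(ph)
        assert img.shape == (64, 64)
        assert np.allclose(img, 0.3)

    def test_disc_area(self):
        # centred sphere of radius 8 model units on a radius-28 domain
        spec = PhantomSpec(sigma_bg=0.1,
                           enclosures=(_spec(s=(8, 8, 8), contrast=10.0),),
                           perturb_std=0.0)
        img = rasterize_target(spec, radius=28.0)
        r_px = 8.0 / (2 * 28.0 / 64)
        area = (img > 0.5).sum()
        assert area == pytest.approx(np.pi * r_px ** 2, rel=0.10)

    def test_pixel_convention(self):
        # target centred at +x: the bright pixels sit right of centre,
        # same row as the centre (y-down raster, x rightwards)
        spec = PhantomSpec(sigma_bg=0.1,
                           enclosures=(_spec(t=(14, 0, 0), s=(4, 4, 4),
                                             contrast=10.0),),
                           perturb_std=0.0)
        img = rasterize_target(spec, radius=28.0)
        rows, cols = np.nonzero(img > 0.5)
        assert cols.mean() > 40
        assert rows.mean() == pytest.approx((64 - 1) / 2, abs=1.0)
        c, r = phys_to_pixel((14, 0), 28.0)
        assert (c, r) == (pytest.approx(cols.mean(), abs=1.0),
                          pytest.approx(rows.mean(), abs=1.0))
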