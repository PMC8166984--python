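"""Forward/backprojector pair: geometry, closed-form Radon oracle, adjointness."""

import numpy as np
import pytest

import negmar as nm
from negmar.errors import GeometryError, NonFiniteError

from conftest import dense_matrix


def disk_image(geom, radius, value, center=(0.0, 0.0)):
    x, y = geom.pixel_coords()
    img = ((x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2) * value
    return img.reshape(geom.image_shape)


class TestForwardProject:
    def test_zero_image(self, tiny_geom):
        out = nm.forward_project(np.zeros(tiny_geom.image_shape), tiny_geom)
        assert np.all(out == 0.0)

    def test_disk_matches_analytic_radon(self):
        """Line integrals of a centred disk follow 2*mu*sqrt(r^2 - t^2)."""
        geom = nm.ScanGeometry(
            n_views=16, n_bins=128, bin_spacing=1.0, n_pixels=128, pixel_spacing=1.0
        )
        r, mu = 20.0, 0.02
        sino = nm.forward_project(disk_image(geom, r, mu), geom)
        t = geom.bin_offsets()
        expected = 2 * mu * np.sqrt(np.maximum(r * r - t * t, 0.0))
        inside = np.abs(t) < 0.7 * r
        # per-view RMS tolerance; pixel-centre rasterization is worst at 45 deg
        for v in range(geom.n_views):
            rms = np.sqrt(np.mean((sino[v, inside] - expected[inside]) ** 2))
            assert rms < 0.08 * expected.max()
        # the view-averaged profile is much closer to the closed form
        mean_profile = sino[:, inside].mean(axis=0)
        np.testing.assert_allclose(
            mean_profile, expected[inside], atol=0.03 * expected.max()
        )

    def test_linearity(self, tiny_geom):
        rng = np.random.default_rng(2)
        a = rng.normal(size=tiny_geom.image_shape)
        b = rng.normal(size=tiny_geom.image_shape)
        lhs = nm.forward_project(1.5 * a - 2.0 * b, tiny_geom)
        rhs = 1.5 * nm.forward_project(a, tiny_geom) - 2.0 * nm.forward_project(
            b, tiny_geom
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_geometry_mismatch(self, tiny_geom):
        with pytest.raises(GeometryError):
            nm.forward_project(np.zeros((5, 5)), tiny_geom)

    def test_non_finite_rejected(self, tiny_geom):
        img = np.zeros(tiny_geom.image_shape)
        img[0, 0] = np.nan
        with pytest.raises(NonFiniteError):
            nm.forward_project(img, tiny_geom)


class TestBackproject:
    def test_zero_sinogram(self, tiny_geom):
        out = nm.backproject(np.zeros(tiny_geom.sinogram_shape), tiny_geom)
        assert np.all(out == 0.0)

    def test_single_view_smear_constant_along_ray(self):
        """Backprojecting one uniform view smears it along the ray direction."""
        geom = nm.ScanGeometry(
            n_views=1, n_bins=32, bin_spacing=1.0, n_pixels=16, pixel_spacing=1.0
        )
        img = nm.backproject(np.ones(geom.sinogram_shape), geom)
        # view 0 rays run along y: every column is constant
        np.testing.assert_allclose(img, np.tile(img[:1, :], (16, 1)), atol=1e-12)

    def test_is_exact_transpose_of_forward(self, tiny_geom):
        """Dense-matrix oracle: B == (pi/n_views) * F^T elementwise."""
        fwd = dense_matrix(
            lambda x: nm.forward_project(x, tiny_geom),
            tiny_geom.image_shape,
            tiny_geom.sinogram_shape,
        )
        back = dense_matrix(
            lambda s: nm.backproject(s, tiny_geom),
            tiny_geom.sinogram_shape,
            tiny_geom.image_shape,
        )
        scale = np.pi / tiny_geom.n_views
        assert np.abs(back - scale * fwd.T).max() < 1e-10


class TestAdjointPair:
    def test_fbp_inner_product_identity(self, tiny_geom):
        """<A s, x> == <s, A^T x> on random pairs."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = rng.normal(size=tiny_geom.sinogram_shape)
            x = rng.normal(size=tiny_geom.image_shape)
            lhs = float(np.vdot(nm.fbp(s, tiny_geom), x))
            rhs = float(np.vdot(s, nm.fbp_adjoint(x, tiny_geom)))
            assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_fbp_adjoint_zero_and_linearity(self, tiny_geom):
        assert np.all(nm.fbp_adjoint(np.zeros(tiny_geom.image_shape), tiny_geom) == 0)
        rng = np.random.default_rng(4)
        a = rng.normal(size=tiny_geom.image_shape)
        b = rng.normal(size=tiny_geom.image_shape)
        lhs = nm.fbp_adjoint(3.0 * a + b, tiny_geom)
        rhs = 3.0 * nm.fbp_adjoint(a, tiny_geom) + nm.fbp_adjoint(b, tiny_geom)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestFBP:
    def test_zero_sinogram(self, tiny_geom):
        assert np.all(nm.fbp(np.zeros(tiny_geom.sinogram_shape), tiny_geom) == 0)

    def test_analytic_disk_reconstruction(self):
        """FBP of the closed-form disk sinogram recovers the interior value."""
        geom = nm.ScanGeometry(
            n_views=180, n_bins=128, bin_spacing=1.0, n_pixels=128, pixel_spacing=1.0
        )
        r, mu = 20.0, 0.02
        t = geom.bin_offsets()
        sino = np.tile(
            2 * mu * np.sqrt(np.maximum(r * r - t * t, 0.0)), (geom.n_views, 1)
        )
        rec = nm.fbp(sino, geom)
        x, y = geom.pixel_coords()
        interior = ((x**2 + y**2) <= (0.6 * r) ** 2).reshape(geom.image_shape)
        assert rec[interior].mean() == pytest.approx(mu, rel=0.05)

    def test_round_trip_smooth_phantom(self):
        """FBP(forward(x)) ~ x in the interior for a smooth phantom."""
        geom = nm.ScanGeometry(
            n_views=180, n_bins=128, bin_spacing=1.0, n_pixels=128, pixel_spacing=1.0
        )
        x, y = geom.pixel_coords()
        rho2 = (x**2 + y**2) / 40.0**2
        img = (0.02 * np.exp(-3.0 * rho2)).reshape(geom.image_shape)
        rec = nm.fbp(nm.forward_project(img, geom), geom)
        interior = (np.sqrt(x**2 + y**2) < 40.0).reshape(geom.image_shape)
        err = rec[interior] - img[interior]
        assert np.sqrt(np.mean(err**2)) < 0.10 * np.sqrt(np.mean(img[interior] ** 2))

    def test_matches_independent_fbp_implementation(self):
        """Cross-check against scikit-image's iradon on the disk sinogram."""
        skimage_transform = pytest.importorskip("skimage.transform")
        geom = nm.ScanGeometry(
            n_views=180, n_bins=129, bin_spacing=1.0, n_pixels=129, pixel_spacing=1.0
        )
        r, mu = 20.0, 0.02
        t = geom.bin_offsets()
        profile = 2 * mu * np.sqrt(np.maximum(r * r - t * t, 0.0))
        sino = np.tile(profile, (geom.n_views, 1))
        ours = nm.fbp(sino, geom)
        theirs = skimage_transform.iradon(
            sino.T,
            theta=np.degrees(geom.angles),
            filter_name="ramp",
            circle=True,
            output_size=geom.n_pixels,
        )
        x, y = geom.pixel_coords()
        interior = ((x**2 + y**2) <= (0.6 * r) ** 2).reshape(geom.image_shape)
        assert ours[interior].mean() == pytest.approx(theirs[interior].mean(), rel=0.03)
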