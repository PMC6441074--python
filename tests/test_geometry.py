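"""Ellipse fitting, geodesic corrections, shell-projection correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synmux.geometry import (
    BoutonGeometry,
    ellipse_vs_circle_error,
    fit_ellipse_profile,
    geodesic_circle,
    geodesic_correct_map,
    geodesic_ellipse,
    shell_projection_correct,
    shell_projection_factor,
)
from synmux.maps import HeatMap


def polyline_arc_length(a: float, b: float, x_proj: float, n_segments: int = 1_000_000) -> float:
    """Brute-force oracle: cumulative chord length of a dense ellipse polyline."""
    theta_max = math.asin(min(x_proj / a, 1.0))
    theta = np.linspace(0.0, theta_max, n_segments + 1)
    x = a * np.sin(theta)
    z = b * np.cos(theta)
    return float(np.sum(np.hypot(np.diff(x), np.diff(z))))


def ellipse_mask(a_px: float, b_px: float, shape=(120, 160), centre=None, angle=0.0):
    ny, nx = shape
    cy, cx = centre if centre else (ny / 2, nx / 2)
    yy, xx = np.mgrid[0:ny, 0:nx]
    ct, st_ = math.cos(angle), math.sin(angle)
    xr = ct * (xx - cx) + st_ * (yy - cy)
    yr = -st_ * (xx - cx) + ct * (yy - cy)
    return (xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0


class TestEllipseFit:
    def test_population_mean_bouton_recovered_within_half_pixel(self):
        pixel = 0.05
        mask = ellipse_mask(1.18 / pixel, 0.89 / pixel)
        geom = fit_ellipse_profile(mask, pixel_um=pixel)
        assert geom.a == pytest.approx(1.18, abs=pixel / 2)
        assert geom.b == pytest.approx(0.89, abs=pixel / 2)

    def test_outline_points_fit(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.column_stack([1.18 * np.cos(t), 0.89 * np.sin(t)])
        geom = fit_ellipse_profile(pts)
        assert geom.a == pytest.approx(1.18, rel=1e-6)
        assert geom.b == pytest.approx(0.89, rel=1e-6)

    def test_circle_flags_arbitrary_orientation(self):
        mask = ellipse_mask(20, 20)
        geom = fit_ellipse_profile(mask)
        assert geom.circular
        assert geom.orientation == 0.0
        assert geom.a == pytest.approx(geom.b, rel=0.02)

    def test_aspect_ratio_recovered_across_batch(self):
        """Simulated boutons drawn at a/b = 1.35 return that sample mean."""
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(15):
            b_px = rng.uniform(14, 20)
            geom = fit_ellipse_profile(ellipse_mask(1.35 * b_px, b_px, angle=rng.uniform(0, np.pi)))
            ratios.append(geom.aspect)
        assert np.mean(ratios) == pytest.approx(1.35, abs=0.05)

    def test_collinear_outline_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50)])
        with pytest.raises(ValueError):
            fit_ellipse_profile(pts)

    def test_axis_order_invariant(self):
        with pytest.raises(ValueError):
            BoutonGeometry(a=0.5, b=0.9)


class TestGeodesicCircle:
    def test_centre_maps_to_zero(self):
        assert geodesic_circle(0.0, 0.89) == 0.0

    def test_edge_maps_to_quarter_arc(self):
        b = 0.89
        assert geodesic_circle(b, b) == pytest.approx(math.pi * b / 2, rel=1e-12)

    def test_half_radius_closed_form(self):
        assert geodesic_circle(0.5, 1.0) == pytest.approx(math.pi / 6, rel=1e-12)

    def test_monotone_and_expanding(self):
        x = np.linspace(0, 0.89, 50)
        arc = geodesic_circle(x, 0.89)
        assert np.all(np.diff(arc) > 0)
        assert np.all(arc >= x - 1e-12)

    def test_beyond_radius_rejected(self):
        with pytest.raises(ValueError):
            geodesic_circle(1.0, 0.89)


class TestGeodesicEllipse:
    def test_circle_limit_matches_arcsin(self):
        assert geodesic_ellipse(1.0, 1.0, 1.0) == pytest.approx(math.pi / 2, rel=1e-9)
        for x in (0.2, 0.5, 0.9):
            assert geodesic_ellipse(x, 1.0, 1.0) == pytest.approx(geodesic_circle(x, 1.0), rel=1e-9)

    def test_against_polyline_oracle_spot_value(self):
        oracle = polyline_arc_length(1.5, 1.0, 0.75, n_segments=200_000)
        assert geodesic_ellipse(0.75, 1.5, 1.0) == pytest.approx(oracle, rel=1e-6)
        assert oracle == pytest.approx(0.766, abs=0.001)

    @settings(max_examples=20, deadline=None)
    @given(
        aspect=st.floats(min_value=1.0, max_value=2.0),
        frac=st.floats(min_value=0.05, max_value=0.999),
    )
    def test_monotone_and_at_least_projected(self, aspect, frac):
        a, b = aspect, 1.0
        x = frac * a
        arc = geodesic_ellipse(x, a, b)
        assert arc >= x * (1 - 1e-9)
        assert geodesic_ellipse(min(x * 1.001, a), a, b) >= arc

    def test_beyond_major_axis_rejected(self):
        with pytest.raises(ValueError):
            geodesic_ellipse(1.6, 1.5, 1.0)


class TestEllipseVsCircle:
    def test_circle_has_zero_error(self):
        assert ellipse_vs_circle_error(1.0, 0.8) == pytest.approx(0.0, abs=1e-12)

    def test_conservative_aspect_bounded_by_five_percent(self):
        assert ellipse_vs_circle_error(1.5, 0.5) <= 0.05

    def test_error_grows_with_range(self):
        errs = [ellipse_vs_circle_error(1.5, f) for f in (0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(errs) > 0)


class TestGeodesicCorrectMap:
    def _flat_map(self, geom, pixel=0.05, pad=0.3):
        nx = int(2 * (geom.a + pad) / pixel) | 1  # odd: a pixel sits exactly at the centre
        ny = int(2 * (geom.b + pad) / pixel) | 1
        hm = HeatMap(np.ones((ny, nx)), pixel_um=pixel,
                     origin_um=(-(nx - 1) / 2 * pixel, -(ny - 1) / 2 * pixel))
        return hm

    def test_flat_map_stays_flat_with_stretched_support(self):
        geom = BoutonGeometry(a=1.2, b=0.9)
        hm = self._flat_map(geom)
        gmap = geodesic_correct_map(hm, geom)
        assert np.nanmax(np.abs(gmap.values[gmap.mask] - 1.0)) < 1e-9
        u, v = gmap.axis_coords()
        assert u.max() >= math.pi * geom.a / 2 - gmap.pixel_um
        assert v.max() >= math.pi * geom.b / 2 - gmap.pixel_um

    def test_centre_value_preserved(self):
        geom = BoutonGeometry(a=1.0, b=0.8)
        hm = self._flat_map(geom)
        iy, ix = hm.shape[0] // 2, hm.shape[1] // 2
        hm.values[iy, ix] = 5.0
        gmap = geodesic_correct_map(hm, geom)
        jy, jx = gmap.shape[0] // 2, gmap.shape[1] // 2
        assert gmap.values[jy, jx] == pytest.approx(5.0, rel=0.05)

    def test_corrected_distances_expand(self):
        """A geodesic coordinate is never smaller than its projected source."""
        geom = BoutonGeometry(a=1.0, b=0.8)
        u = np.linspace(0, math.pi * geom.a / 2 - 1e-6, 30)
        x = geom.a * np.sin(u / geom.a)
        assert np.all(u >= x - 1e-12)

    def test_centre_outside_map_rejected(self):
        geom = BoutonGeometry(a=1.0, b=0.8, centre_um=(50.0, 0.0))
        hm = self._flat_map(BoutonGeometry(a=1.0, b=0.8))
        with pytest.raises(ValueError, match="centre"):
            geodesic_correct_map(hm, geom)


def project_uniform_shell(a, b, thickness=0.04, n=400_000, pixel=0.05, seed=0):
    """Monte-Carlo oracle: z-projection of a uniformly labelled ellipsoidal shell."""
    rng = np.random.default_rng(seed)
    # sample surface ~ area-uniform via rejection from the parametric density
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # map sphere to ellipsoid and weight by local area distortion
    xyz = pts * np.array([a, b, b])
    nvec = pts / np.array([a, b, b])
    w = np.linalg.norm(nvec, axis=1) * np.linalg.norm(xyz, axis=1) ** 0  # ~ area weight
    w = np.linalg.norm(pts * np.array([b * b, a * b, a * b]), axis=1)
    keep = rng.random(n) < w / w.max()
    xyz = xyz[keep]
    radial = rng.normal(0, thickness / 2, size=len(xyz))
    xyz = xyz * (1 + radial / np.linalg.norm(xyz, axis=1))[:, None]
    extent_x = a + 0.2
    extent_y = b + 0.2
    nx, ny = int(2 * extent_x / pixel), int(2 * extent_y / pixel)
    img, _, _ = np.histogram2d(
        xyz[:, 1], xyz[:, 0], bins=(ny, nx), range=((-extent_y, extent_y), (-extent_x, extent_x))
    )
    origin = (-extent_x + pixel / 2, -extent_y + pixel / 2)
    return HeatMap(img, pixel_um=pixel, origin_um=origin)


class TestShellProjection:
    def test_centre_factor_is_unity(self):
        geom = BoutonGeometry(a=1.2, b=0.9)
        assert shell_projection_factor(0.0, 0.0, geom) == pytest.approx(1.0, rel=1e-12)

    def test_factor_diverges_at_silhouette(self):
        geom = BoutonGeometry(a=1.0, b=0.8)
        assert np.isinf(shell_projection_factor(1.0, 0.0, geom))

    def test_uniform_spherical_shell_flattens_after_correction(self):
        geom = BoutonGeometry(a=0.9, b=0.9)
        hm = project_uniform_shell(0.9, 0.9)
        corrected = shell_projection_correct(hm, geom, rim_exclusion=0.1)
        xx, yy = hm.pixel_coords()
        rho = np.hypot(xx, yy) / 0.9
        inner = corrected.values[(rho < 0.3) & corrected.mask].mean()
        outer = corrected.values[(rho > 0.55) & (rho < 0.85) & corrected.mask].mean()
        raw_outer = hm.values[(rho > 0.55) & (rho < 0.85)].mean()
        raw_inner = hm.values[rho < 0.3].mean()
        assert raw_outer / raw_inner > 1.15  # projection brightens the edge
        assert outer / inner == pytest.approx(1.0, abs=0.05)

    def test_ratiometric_maps_unchanged_by_construction(self):
        """The projection factor cancels between response and baseline."""
        geom = BoutonGeometry(a=1.0, b=0.8)
        rng = np.random.default_rng(1)
        base = project_uniform_shell(1.0, 0.8, seed=2)
        resp = base.copy_with(values=base.values * 1.5)  # uniform 50% dF/F
        c_base = shell_projection_correct(base, geom)
        c_resp = shell_projection_correct(resp, geom)
        with np.errstate(invalid="ignore", divide="ignore"):
            dff_raw = resp.values / np.clip(base.values, 1e-9, None) - 1
            dff_corr = c_resp.values / np.clip(c_base.values, 1e-9, None) - 1
        m = c_base.mask & (base.values > 5)
        assert np.allclose(dff_corr[m], dff_raw[m], atol=1e-9)
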