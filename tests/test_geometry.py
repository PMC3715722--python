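"""Orientation-field geometry: implied orientation, gradients, quantization,
symmetry, and the signal/noise coherence of annular layouts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from remotetae import (
    DegeneratePointError,
    LayoutGeometry,
    OrientationField,
    apply_symmetry,
    band_step,
    coherence_for_radius,
    distinct_band_orientations,
    implied_orientation,
    local_gradient,
    orientation_distance,
    quantize_field,
    solve_noise_radius,
    test_location as _test_location,
    wrap_orientation,
)


def orientation_of_direction(dx, dy):
    """Independent oracle: orientation of a line direction vector, degrees
    CCW from vertical in [-90, 90)."""
    return wrap_orientation(math.degrees(math.atan2(-dx, dy)))


class TestImpliedOrientation:
    def test_concentric_at_test_site_is_15deg_ccw(self, concentric):
        assert implied_orientation(concentric, _test_location()) == pytest.approx(15.0)

    def test_test_site_cartesian_offsets(self):
        x, y = _test_location()
        assert (round(x, 2), round(y, 2)) == (9.66, 2.59)

    @pytest.mark.parametrize(
        "point, expected",
        [((10.0, 0.0), 0.0), ((0.0, 10.0), -90.0), ((7.0, 7.0), 45.0)],
    )
    def test_concentric_tangent_examples(self, concentric, point, expected):
        assert implied_orientation(concentric, point) == pytest.approx(expected)

    def test_linear_gradient_examples(self, linear5):
        x, y = _test_location()
        assert implied_orientation(linear5, (x + 3.0, y)) == pytest.approx(30.0)
        assert implied_orientation(linear5, (x, y - 10.0)) == pytest.approx(15.0)

    @given(
        phi=st.floats(0.0, 359.99),
        r=st.floats(0.5, 30.0),
    )
    def test_concentric_and_radial_match_tangent_vector_oracle(self, phi, r):
        point = (r * math.cos(math.radians(phi)), r * math.sin(math.radians(phi)))
        # tangent of the circle through `point` (CCW circulation)
        tx, ty = -math.sin(math.radians(phi)), math.cos(math.radians(phi))
        conc = implied_orientation(OrientationField("concentric"), point)
        assert orientation_distance(conc, orientation_of_direction(tx, ty)) < 1e-6
        rad = implied_orientation(OrientationField("radial"), point)
        assert orientation_distance(rad, orientation_of_direction(*point)) < 1e-6

    def test_polar_field_degenerate_at_centre(self, concentric):
        with pytest.raises(DegeneratePointError):
            implied_orientation(concentric, (0.0, 0.0))

    def test_orientations_wrapped_into_halfopen_range(self, concentric):
        pts = np.random.default_rng(0).uniform(-24, 24, size=(1000, 2))
        theta = implied_orientation(concentric, pts)
        assert np.all((theta >= -90.0) & (theta < 90.0))

    def test_wrap_identifies_plus_minus_90(self):
        assert wrap_orientation(90.0) == -90.0
        assert wrap_orientation(-90.0) == -90.0


class TestLocalGradient:
    @pytest.mark.parametrize("r", [1.0, 5.0, 10.0, 20.0])
    def test_concentric_gradient_along_arc(self, concentric, r):
        g = local_gradient(concentric, (r, 0.0))
        assert g == pytest.approx(180.0 / (math.pi * r), abs=1e-9)

    def test_reported_value_at_10deg_eccentricity(self, concentric):
        assert round(local_gradient(concentric, _test_location()), 2) == 5.73

    def test_linear_and_iso(self, linear5):
        assert local_gradient(linear5, (3.0, -7.0)) == 5.0
        assert local_gradient(OrientationField("iso"), (3.0, -7.0)) == 0.0


class TestQuantization:
    def test_full_period_band_is_iso_oriented(self, linear5):
        q = quantize_field(linear5, 36.0)
        assert band_step(q) == pytest.approx(0.0)
        assert len(distinct_band_orientations(q)) == 1
        xs = np.linspace(-24, 24, 101)
        theta = implied_orientation(q, np.stack([xs, np.zeros_like(xs)], axis=-1))
        assert np.allclose(orientation_distance(theta, 15.0), 0.0, atol=1e-9)

    def test_8deg_bands_step_40(self, linear5):
        assert band_step(quantize_field(linear5, 8.0)) == pytest.approx(40.0)

    def test_12deg_bands_three_orientations_60_apart(self, linear5):
        q = quantize_field(linear5, 12.0)
        vals = distinct_band_orientations(q)
        assert len(vals) == 3
        seps = [orientation_distance(a, b) for a in vals for b in vals if a != b]
        assert np.allclose(seps, 60.0)

    def test_anchor_band_centred_on_anchor(self, linear5):
        q = quantize_field(linear5, 8.0)
        x, y = _test_location()
        for dx in (-3.9, 0.0, 3.9):
            assert implied_orientation(q, (x + dx, y)) == pytest.approx(15.0)

    @given(rate=st.floats(0.5, 10.0), width=st.floats(0.5, 20.0))
    def test_adjacent_band_step_and_period(self, rate, width):
        base = OrientationField("linear_gradient", gradient_rate=rate)
        q = quantize_field(base, width)
        x0, y0 = q.anchor_point
        a = implied_orientation(q, (x0, y0))
        b = implied_orientation(q, (x0 + width, y0))
        assert orientation_distance(b - a, rate * width) < 1e-9
        # spatial period of the underlying modulation is 180 / rate
        lin_a = implied_orientation(base, (x0, y0))
        lin_b = implied_orientation(base, (x0 + 180.0 / rate, y0))
        assert orientation_distance(lin_a, lin_b) < 1e-9

    def test_quantize_requires_linear_base(self, concentric):
        with pytest.raises(ValueError):
            quantize_field(concentric, 8.0)


class TestSymmetry:
    def test_mirror_negates_orientation_across_meridian(self, linear5):
        sym = apply_symmetry(linear5, "horizontal")
        x, _ = _test_location()
        theta_src = implied_orientation(sym, (x + 3.0, 5.0))
        theta_mir = implied_orientation(sym, (x + 3.0, -5.0))
        assert theta_src == pytest.approx(30.0)
        assert theta_mir == pytest.approx(-30.0)

    def test_source_hemifield_unchanged(self, linear5):
        sym = apply_symmetry(linear5, "horizontal")
        pts = np.random.default_rng(1).uniform([-24, 0.1], [24, 24], size=(50, 2))
        assert np.allclose(
            implied_orientation(sym, pts), implied_orientation(linear5, pts)
        )

    def test_boundary_orientation_wraps_to_minus_90(self):
        field = OrientationField(
            "linear_gradient",
            gradient_rate=5.0,
            anchor_point=(0.0, 5.0),
            anchor_orientation=-90.0,  # the +/-90 boundary line
        )
        sym = apply_symmetry(field, "horizontal")
        assert implied_orientation(sym, (0.0, -5.0)) == -90.0

    def test_meridian_must_match_gradient_axis(self, linear5):
        with pytest.raises(ValueError):
            apply_symmetry(linear5, "vertical")


class TestCoherenceGeometry:
    def test_printed_radius_gives_90_percent(self, proximal_953):
        coh = coherence_for_radius(proximal_953, 9.53)
        assert coh == pytest.approx(0.902, abs=1e-3)
        assert round(100 * coh) == 90

    def test_annulus_at_occlusion_radius_gives_full_coherence(self, proximal_953):
        assert coherence_for_radius(proximal_953, 4.6) == pytest.approx(1.0)

    def test_annulus_covering_square_gives_zero(self, proximal_953):
        assert coherence_for_radius(proximal_953, proximal_953.max_radius) == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_monotone_non_increasing_in_radius(self, proximal_953):
        radii = np.linspace(4.6, 40.0, 60)
        cohs = [coherence_for_radius(proximal_953, r) for r in radii]
        assert np.all(np.diff(cohs) <= 1e-12)

    def test_agrees_with_monte_carlo_point_count(self, proximal_953, rng):
        """Area integration vs a 1e6-point Monte-Carlo visibility count."""
        pts = rng.uniform(-24.0, 24.0, size=(1_000_000, 2))
        tx, ty = proximal_953.test_point
        d = np.hypot(pts[:, 0] - tx, pts[:, 1] - ty)
        visible = d > 4.6
        for radius in (4.6, 7.0, 9.53, 15.0, 25.0):
            noise = visible & (d <= radius)
            mc = 1.0 - noise.sum() / visible.sum()
            assert coherence_for_radius(proximal_953, radius) == pytest.approx(
                mc, abs=0.003
            )

    def test_solver_inverts_coherence(self, proximal_953, rng):
        for target in rng.uniform(0.05, 0.999, size=20):
            r = solve_noise_radius(proximal_953, target)
            assert coherence_for_radius(proximal_953, r) == pytest.approx(
                target, abs=1e-6
            )
            # round trip in radius as well
            assert solve_noise_radius(
                proximal_953, coherence_for_radius(proximal_953, r)
            ) == pytest.approx(r, abs=0.01)

    def test_solver_boundary_and_errors(self, proximal_953):
        assert solve_noise_radius(proximal_953, 1.0) == pytest.approx(4.6)
        with pytest.raises(ValueError):
            solve_noise_radius(proximal_953, 0.0)
        distal = LayoutGeometry(noise_layout="distal")
        assert solve_noise_radius(distal, 1.0) == pytest.approx(distal.max_radius)

    def test_distal_is_complement_of_proximal(self, proximal_953):
        distal = LayoutGeometry(noise_layout="distal")
        for radius in (6.0, 9.53, 20.0):
            assert coherence_for_radius(distal, radius) == pytest.approx(
                1.0 - coherence_for_radius(proximal_953, radius)
            )

    def test_invalid_radius_rejected(self, proximal_953):
        with pytest.raises(ValueError):
            coherence_for_radius(proximal_953, 3.0)


class TestValidationAndSerialization:
    def test_field_yaml_json_round_trip(self, linear5):
        sym = apply_symmetry(linear5, "horizontal")
        assert OrientationField.from_yaml(sym.to_yaml()) == sym
        assert OrientationField.from_json(sym.to_json()) == sym

    def test_layout_yaml_round_trip(self, proximal_953):
        assert LayoutGeometry.from_yaml(proximal_953.to_yaml()) == proximal_953

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "nope"},
            {"kind": "linear_gradient", "gradient_rate": -1.0},
            {"kind": "quantized_gradient", "band_width": None},
            {"kind": "quantized_gradient", "band_width": -2.0},
            {"kind": "concentric", "symmetry": "about_gradient_axis_meridian"},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OrientationField(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"coherence": 1.5},
            {"test_point": (30.0, 0.0)},
            {"noise_layout": "proximal", "annulus_outer_radius": 2.0},
        ],
    )
    def test_invalid_layouts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LayoutGeometry(**kwargs)
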