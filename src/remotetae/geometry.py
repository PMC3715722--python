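"""Orientation-field geometry for texture adaptation experiments.

Coordinate conventions
----------------------
Positions are in degrees of visual angle, origin at fixation, x rightward
and y upward positive.  Orientations are measured counter-clockwise from
vertical and wrapped into ``[-90, +90)``; all orientation arithmetic is
mod 180 (an orientation is a line, not a vector).  With these conventions
the tangential orientation of a circle centred on fixation equals the
polar angle of the point, so a test location at polar angle 15 deg carries
an implied orientation of +15 deg (counter-clockwise of vertical).

The module provides:

* :class:`OrientationField` — a declarative description of implied
  orientation as a function of position (concentric, radial, linear
  gradient, quantized gradient, or iso-oriented).
* :class:`LayoutGeometry` — the spatial layout of an adapting texture:
  the 48x48 deg element field, the occluded test region, and the
  signal/noise geometry (intermixed, proximal-noise or distal-noise
  annulus arrangements).
* Analytic operations: implied orientation, local orientation gradient,
  gradient quantization, mirror symmetry, and the signal/noise coherence
  produced by a noise annulus of a given outer radius (plus its inverse).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "DegeneratePointError",
    "LayoutGeometry",
    "OrientationField",
    "apply_symmetry",
    "band_step",
    "coherence_for_radius",
    "distinct_band_orientations",
    "implied_orientation",
    "local_gradient",
    "orientation_distance",
    "quantize_field",
    "solve_noise_radius",
    "test_location",
    "wrap_orientation",
]

FIELD_KINDS = ("concentric", "radial", "linear_gradient", "quantized_gradient", "iso")
AXES = ("horizontal", "vertical")
NOISE_LAYOUTS = ("intermixed", "proximal", "distal")
SYMMETRIES = ("none", "about_gradient_axis_meridian")


class DegeneratePointError(ValueError):
    """Raised when a polar field is evaluated at its own centre."""


def wrap_orientation(theta):
    """Wrap orientation(s) into ``[-90, +90)`` degrees from vertical.

    -90 and +90 describe the same line; the canonical representative
    is -90.
    """
    return (np.asarray(theta, dtype=float) + 90.0) % 180.0 - 90.0


def orientation_distance(a, b):
    """Smallest absolute angle, in degrees, between two orientations (mod 180)."""
    d = np.abs(wrap_orientation(np.asarray(a, float) - np.asarray(b, float)))
    return np.minimum(d, 180.0 - d) if np.ndim(d) else min(float(d), 180.0 - float(d))


def test_location(eccentricity: float = 10.0, polar_angle_deg: float = 15.0) -> tuple[float, float]:
    """Cartesian test-site coordinates from polar position.

    The default (eccentricity 10 deg, polar angle pi/12) lands 9.66 deg
    right of and 2.59 deg above fixation.
    """
    phi = math.radians(polar_angle_deg)
    return (eccentricity * math.cos(phi), eccentricity * math.sin(phi))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OrientationField:
    """Implied orientation as a function of visual-field position.

    Parameters
    ----------
    kind:
        ``concentric`` (tangential to circles about `center`), ``radial``,
        ``linear_gradient`` (orientation a linear function of one Cartesian
        coordinate), ``quantized_gradient`` (a linear gradient space-averaged
        within bands of width `band_width`), or ``iso`` (constant).
    center:
        Centre of the polar structure, degrees; default fixation.
    gradient_rate:
        Degrees of orientation change per degree of visual angle along
        `axis` (linear/quantized kinds); must be >= 0.
    axis:
        ``horizontal`` — orientation varies with x; ``vertical`` — with y.
    anchor_point, anchor_orientation:
        The gradient is anchored so that the field evaluates to
        `anchor_orientation` at `anchor_point` (for quantized fields the
        band containing the anchor is centred on it).
    band_width:
        Width of each constant-orientation band, degrees (quantized only).
    symmetry:
        ``about_gradient_axis_meridian`` mirrors the hemifield containing
        `anchor_point` into the other hemifield (see :func:`apply_symmetry`).
    """

    kind: str
    center: tuple[float, float] = (0.0, 0.0)
    gradient_rate: float = 0.0
    axis: str = "horizontal"
    anchor_point: tuple[float, float] = dc_field(default_factory=test_location)
    anchor_orientation: float = 15.0
    band_width: float | None = None
    symmetry: str = "none"

    def __post_init__(self):
        if self.kind not in FIELD_KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if self.symmetry not in SYMMETRIES:
            raise ValueError(f"symmetry must be one of {SYMMETRIES}")
        if self.gradient_rate < 0:
            raise ValueError("gradient_rate must be >= 0")
        if self.kind == "quantized_gradient":
            if self.band_width is None or self.band_width <= 0:
                raise ValueError("quantized_gradient requires band_width > 0")
        if self.symmetry != "none" and self.kind not in ("linear_gradient", "quantized_gradient"):
            raise ValueError("symmetry applies to gradient fields only")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "center": list(self.center),
            "gradient_rate": self.gradient_rate,
            "axis": self.axis,
            "anchor_point": list(self.anchor_point),
            "anchor_orientation": self.anchor_orientation,
            "band_width": self.band_width,
            "symmetry": self.symmetry,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrientationField":
        d = dict(d)
        for key in ("center", "anchor_point"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "OrientationField":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_json(cls, text: str) -> "OrientationField":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class LayoutGeometry:
    """Spatial layout of an adapting texture and its signal/noise geometry.

    The element field is a square of half-width `square_half_width`
    centred on fixation.  Contrast within `occlusion_radius` of
    `test_point` is zeroed and restored over a cosine ramp of width
    `ramp_width`; for visibility accounting an element is treated as not
    visible inside the *effective* occlusion radius
    ``occlusion_radius + ramp_width``.

    `noise_layout` places randomly oriented noise elements either
    intermixed with signal elements (probability ``1 - coherence`` each),
    inside an annulus around the test site (``proximal``), or everywhere
    *except* that annulus (``distal``).
    """

    square_half_width: float = 24.0
    test_point: tuple[float, float] = dc_field(default_factory=test_location)
    occlusion_radius: float = 3.0
    ramp_width: float = 1.6
    noise_layout: str = "intermixed"
    annulus_outer_radius: float | None = None
    coherence: float = 1.0

    def __post_init__(self):
        if self.noise_layout not in NOISE_LAYOUTS:
            raise ValueError(f"noise_layout must be one of {NOISE_LAYOUTS}")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")
        hw = self.square_half_width
        x, y = self.test_point
        if not (abs(x) < hw and abs(y) < hw):
            raise ValueError("test_point must lie inside the square")
        if self.annulus_outer_radius is not None:
            if self.annulus_outer_radius < self.effective_occlusion_radius:
                raise ValueError(
                    "annulus_outer_radius must be >= occlusion_radius + ramp_width"
                )

    @property
    def effective_occlusion_radius(self) -> float:
        return self.occlusion_radius + self.ramp_width

    @property
    def max_radius(self) -> float:
        """Distance from the test point to the farthest square corner."""
        hw = self.square_half_width
        x, y = self.test_point
        return max(
            math.hypot(cx - x, cy - y)
            for cx in (-hw, hw)
            for cy in (-hw, hw)
        )

    def to_dict(self) -> dict:
        return {
            "square_half_width": self.square_half_width,
            "test_point": list(self.test_point),
            "occlusion_radius": self.occlusion_radius,
            "ramp_width": self.ramp_width,
            "noise_layout": self.noise_layout,
            "annulus_outer_radius": self.annulus_outer_radius,
            "coherence": self.coherence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayoutGeometry":
        d = dict(d)
        if "test_point" in d:
            d["test_point"] = tuple(d["test_point"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "LayoutGeometry":
        return cls.from_dict(yaml.safe_load(text))


# --------------------------------------------------------------------------
# field evaluation
# --------------------------------------------------------------------------


def _axis_coord(field: OrientationField, x, y):
    return x if field.axis == "horizontal" else y


def _mirror_mask(field: OrientationField, x, y):
    """True where a point lies in the mirrored (non-source) hemifield.

    A horizontal-axis gradient is symmetric about the horizontal midline
    (y = 0); the source hemifield is the one containing the anchor point,
    so the implied orientation at the test site is unaffected.
    """
    if field.axis == "horizontal":
        src = math.copysign(1.0, field.anchor_point[1])
        return np.asarray(y) * src < 0
    src = math.copysign(1.0, field.anchor_point[0])
    return np.asarray(x) * src < 0


def implied_orientation(field: OrientationField, point) -> float | np.ndarray:
    """Implied orientation of `field` at `point`, degrees CCW of vertical.

    `point` may be a single ``(x, y)`` pair or an ``(..., 2)`` array;
    returned orientations lie in ``[-90, +90)``.

    Raises
    ------
    DegeneratePointError
        If a concentric or radial field is evaluated at its centre, where
        the tangential orientation is undefined.
    """
    pts = np.asarray(point, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    x, y = pts[..., 0], pts[..., 1]

    if field.kind in ("concentric", "radial"):
        dx, dy = x - field.center[0], y - field.center[1]
        if np.any((dx == 0) & (dy == 0)):
            raise DegeneratePointError("polar field evaluated at its centre")
        phi = np.degrees(np.arctan2(dy, dx))
        theta = wrap_orientation(phi if field.kind == "concentric" else phi - 90.0)
    elif field.kind == "iso":
        theta = np.full_like(x, wrap_orientation(field.anchor_orientation))
    else:
        if field.symmetry == "about_gradient_axis_meridian":
            mirrored = _mirror_mask(field, x, y)
        else:
            mirrored = np.zeros_like(x, dtype=bool)
        c = _axis_coord(field, x, y)
        c0 = _axis_coord(field, *field.anchor_point)
        if field.kind == "linear_gradient":
            theta = wrap_orientation(
                field.anchor_orientation + field.gradient_rate * (c - c0)
            )
        else:  # quantized_gradient: bands centred on the anchor coordinate
            k = np.round((c - c0) / field.band_width)
            theta = wrap_orientation(
                field.anchor_orientation + field.gradient_rate * k * field.band_width
            )
        theta = np.where(mirrored, wrap_orientation(-theta), theta)

    return float(theta[0]) if scalar else theta.reshape(np.shape(point)[:-1])


def local_gradient(field: OrientationField, point) -> float:
    """Magnitude of the spatial rate of change of implied orientation.

    For concentric (and radial) fields the gradient is measured along the
    iso-eccentric arc: at eccentricity r it is ``180 / (pi * r)`` degrees
    of orientation per degree of visual angle — 5.73 deg/deg at r = 10.
    Linear gradients return `gradient_rate` everywhere; iso fields 0;
    quantized fields are piecewise constant, so the pointwise gradient
    is 0 (the observer model handles their inter-band structure
    separately).
    """
    if field.kind in ("concentric", "radial"):
        x, y = np.asarray(point, dtype=float)
        r = math.hypot(x - field.center[0], y - field.center[1])
        if r == 0:
            raise DegeneratePointError("polar field evaluated at its centre")
        return 180.0 / (math.pi * r)
    if field.kind == "linear_gradient":
        return float(field.gradient_rate)
    return 0.0


def quantize_field(base: OrientationField, band_width: float) -> OrientationField:
    """Quantize a linear gradient into constant-orientation spatial bands.

    Bands of `band_width` partition the gradient axis with one band
    centred on the anchor point; each band takes the space-average of the
    underlying linear function (its value at the band centre).  Adjacent
    bands therefore differ by ``band_width * gradient_rate`` mod 180.
    A band width equal to the field's spatial period (180/rate) removes
    the modulation entirely, yielding an iso-oriented texture.
    """
    if base.kind != "linear_gradient":
        raise ValueError("quantize_field expects a linear_gradient field")
    if band_width <= 0:
        raise ValueError("band_width must be > 0")
    return replace(base, kind="quantized_gradient", band_width=band_width)


def band_step(field: OrientationField) -> float:
    """Absolute orientation difference between adjacent bands, degrees.

    Computed mod 180 as the circular distance between successive band
    orientations; an iso-oriented quantization (band width = spatial
    period) gives 0.
    """
    if field.kind != "quantized_gradient":
        raise ValueError("band_step requires a quantized_gradient field")
    return float(orientation_distance(field.gradient_rate * field.band_width, 0.0))


def distinct_band_orientations(field: OrientationField, tol: float = 1e-9) -> np.ndarray:
    """Distinct band orientations (mod 180) within one spatial period.

    Enumerates successive bands from the anchor until the orientation
    repeats; e.g. a rate-5 gradient quantized at 12 deg yields three
    orientations mutually separated by 60 deg.
    """
    if field.kind != "quantized_gradient":
        raise ValueError("requires a quantized_gradient field")
    vals = []
    theta0 = float(wrap_orientation(field.anchor_orientation))
    theta = theta0
    for _ in range(10000):
        vals.append(theta)
        theta = float(
            wrap_orientation(theta + field.gradient_rate * field.band_width)
        )
        if orientation_distance(theta, theta0) < tol:
            break
    else:  # irrational step: report one period's worth of bands
        period = 180.0 / field.gradient_rate
        n = int(math.ceil(period / field.band_width))
        vals = vals[:n]
    return np.array(sorted(set(np.round(vals, 9))))


def apply_symmetry(field: OrientationField, meridian: str) -> OrientationField:
    """Return a copy of `field` with reflectional symmetry about a meridian.

    The hemifield containing the anchor point is the source; the opposite
    hemifield becomes its mirror image (positions reflected, orientations
    negated mod 180).  A horizontal-axis gradient is mirrored about the
    horizontal midline and a vertical-axis gradient about the vertical
    midline; requesting the other pairing is an error.
    """
    if meridian not in AXES:
        raise ValueError(f"meridian must be one of {AXES}")
    if meridian != field.axis:
        raise ValueError(
            "meridian must match the gradient axis "
            "(horizontal gradient -> horizontal midline)"
        )
    return replace(field, symmetry="about_gradient_axis_meridian")


# --------------------------------------------------------------------------
# coherence geometry
# --------------------------------------------------------------------------


def _disc_square_area(center: tuple[float, float], radius: float, half_width: float) -> float:
    """Area of disc(center, radius) intersected with the centred square.

    Deterministic 1-D adaptive quadrature of the clipped vertical chord
    length; exact (pi r^2) when the disc lies wholly inside the square.
    """
    if radius <= 0:
        return 0.0
    cx, cy = center
    hw = half_width
    # disc entirely inside the square: closed form
    if (cx - radius >= -hw and cx + radius <= hw
            and cy - radius >= -hw and cy + radius <= hw):
        return math.pi * radius * radius

    def chord(x):
        h = math.sqrt(max(radius * radius - (x - cx) ** 2, 0.0))
        return max(min(cy + h, hw) - max(cy - h, -hw), 0.0)

    lo, hi = max(cx - radius, -hw), min(cx + radius, hw)
    if lo >= hi:
        return 0.0
    # derivative kinks where the circle crosses the top/bottom square edges
    kinks = []
    for edge in (hw, -hw):
        h2 = radius * radius - (edge - cy) ** 2
        if h2 > 0:
            h = math.sqrt(h2)
            kinks.extend(x for x in (cx - h, cx + h) if lo < x < hi)
    area, _ = quad(
        chord, lo, hi, points=sorted(kinks) or None,
        limit=200, epsabs=1e-10, epsrel=1e-10,
    )
    return area


def coherence_for_radius(layout: LayoutGeometry, outer_radius: float) -> float:
    """Structure coherence of a segregated layout with a given annulus radius.

    Coherence is the expected fraction of *visible* elements (those
    outside the effective occlusion radius of the test point, under
    uniform element density on the square) that carry the structured
    orientation.  In the proximal layout noise fills the annulus from the
    effective occlusion radius out to `outer_radius` (clipped to the
    square); the distal layout is the complement, with signal in the
    annulus and noise outside it.
    """
    if layout.noise_layout not in ("proximal", "distal"):
        raise ValueError("coherence_for_radius applies to proximal/distal layouts")
    r0 = layout.effective_occlusion_radius
    if outer_radius < r0 - 1e-12:
        raise ValueError("outer_radius must be >= the effective occlusion radius")
    hw = layout.square_half_width
    occluded = _disc_square_area(layout.test_point, r0, hw)
    visible = (2 * hw) ** 2 - occluded
    annulus = _disc_square_area(layout.test_point, outer_radius, hw) - occluded
    frac_noise = annulus / visible
    if layout.noise_layout == "proximal":
        return 1.0 - frac_noise
    return frac_noise


def solve_noise_radius(layout: LayoutGeometry, target_coherence: float) -> float:
    """Outer annulus radius achieving a target structure coherence.

    Inverts :func:`coherence_for_radius` by root finding on
    ``[effective occlusion radius, max corner distance]``; coherence is
    monotone (non-increasing for proximal layouts, non-decreasing for
    distal), so the root is unique.  Raises if the target lies outside
    the achievable range of the geometry.
    """
    if not 0.0 < target_coherence <= 1.0:
        raise ValueError("target_coherence must lie in (0, 1]")
    r0 = layout.effective_occlusion_radius
    r_max = layout.max_radius
    c_lo = coherence_for_radius(layout, r0)     # 1.0 proximal, 0.0 distal
    c_hi = coherence_for_radius(layout, r_max)  # floor/ceiling of the geometry
    lo, hi = sorted((c_lo, c_hi))
    tol = 1e-9
    if not (lo - tol <= target_coherence <= hi + tol):
        raise ValueError(
            f"target coherence {target_coherence} unreachable: "
            f"geometry spans [{lo:.4f}, {hi:.4f}]"
        )
    f = lambda r: coherence_for_radius(layout, r) - target_coherence
    f_r0, f_rmax = f(r0), f(r_max)
    if abs(f_r0) <= tol:
        return r0
    if abs(f_rmax) <= tol:
        return r_max
    return float(brentq(f, r0, r_max, xtol=1e-10))
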