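"""Texture and test-stimulus synthesis.

Adapting textures are dense fields of 5000 oriented Gabor-like elements
(1 c/deg sinusoidal carrier under a 1.33 deg isotropic Hanning window)
scattered uniformly over a 48x48 deg square.  Signal elements take the
orientation implied by an :class:`~remotetae.geometry.OrientationField`
at their position; noise elements are randomly oriented.  Each rendered
texture is normalised to zero mean and 9% RMS contrast, then the region
around the test site is occluded (contrast zeroed within 3 deg of the
test point and restored over a 1.6 deg quarter-cycle cosine ramp).

Test stimuli are single 2 c/deg Hanning-windowed patches at the test
location with peak contrast 0.25.

Adaptors are dynamic: a fresh element sample every 100 ms frame, with
per-frame sub-seeds spawned deterministically from a master seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .geometry import LayoutGeometry, OrientationField, implied_orientation, test_location

__all__ = [
    "ElementList",
    "StimulusImage",
    "TextureSpec",
    "make_adaptor_sequence",
    "occlusion_window",
    "render_test",
    "render_texture",
    "sample_elements",
]


@dataclass(frozen=True)
class TextureSpec:
    """Full recipe for one adapting texture."""

    field: OrientationField
    layout: LayoutGeometry
    n_elements: int = 5000
    element_sf: float = 1.0          # carrier spatial frequency, cycles/deg
    element_diameter: float = 1.33   # Hanning window support, deg
    rms_contrast: float = 0.09
    pixels_per_degree: int = 15      # 4 arcmin per pixel
    seed: int = 0

    def __post_init__(self):
        if self.n_elements <= 0:
            raise ValueError("n_elements must be > 0")
        if not 0.0 < self.rms_contrast < 0.5:
            raise ValueError("rms_contrast must lie in (0, 0.5)")
        if self.pixels_per_degree < 4:
            raise ValueError("pixels_per_degree must be >= 4")

    def to_dict(self) -> dict:
        return {
            "field": self.field.to_dict(),
            "layout": self.layout.to_dict(),
            "n_elements": self.n_elements,
            "element_sf": self.element_sf,
            "element_diameter": self.element_diameter,
            "rms_contrast": self.rms_contrast,
            "pixels_per_degree": self.pixels_per_degree,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TextureSpec":
        d = dict(d)
        d["field"] = OrientationField.from_dict(d["field"])
        d["layout"] = LayoutGeometry.from_dict(d["layout"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TextureSpec":
        return cls.from_dict(yaml.safe_load(text))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ElementList:
    """Sampled texture elements: positions, orientations, phases, labels."""

    x: np.ndarray            # deg
    y: np.ndarray            # deg
    orientation: np.ndarray  # deg CCW from vertical, [-90, 90)
    phase: np.ndarray        # rad
    label: np.ndarray        # "signal" | "noise"

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_deg": self.x,
                "y_deg": self.y,
                "orientation_deg": self.orientation,
                "phase_rad": self.phase,
                "label": self.label,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ElementList":
        return cls(
            x=df["x_deg"].to_numpy(float),
            y=df["y_deg"].to_numpy(float),
            orientation=df["orientation_deg"].to_numpy(float),
            phase=df["phase_rad"].to_numpy(float),
            label=df["label"].to_numpy(str),
        )

    @classmethod
    def from_csv(cls, path) -> "ElementList":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class StimulusImage:
    """Rendered contrast image on a pixel raster in visual-field coordinates.

    `data[row, col]` holds contrast about a zero background; row 0 is the
    top of the image (largest y).  `origin` gives the (x, y) visual-field
    coordinates of the centre of pixel (0, 0).
    """

    data: np.ndarray
    degrees_per_pixel: float
    origin: tuple[float, float]
    metadata: dict = dc_field(default_factory=dict)

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of (x, y) visual-field coordinates of pixel centres."""
        rows, cols = self.data.shape
        x = self.origin[0] + np.arange(cols) * self.degrees_per_pixel
        y = self.origin[1] - np.arange(rows) * self.degrees_per_pixel
        return np.meshgrid(x, y)

    def to_uint8(self) -> np.ndarray:
        """8-bit export: contrast -1..+1 -> 0..255 with 0 -> 128 (round half up)."""
        v = np.floor(127.5 * (1.0 + self.data) + 0.5)
        return np.clip(v, 0, 255).astype(np.uint8)

    def save_png(self, path) -> None:
        Image.fromarray(self.to_uint8(), mode="L").save(path, format="PNG")

    def save_array(self, path) -> None:
        """Lossless numeric export (.npy)."""
        np.save(path, self.data)


def occlusion_window(r, inner: float = 3.0, ramp: float = 1.6):
    """Radial occlusion profile around the test site.

    0 within `inner` deg; rises as a quarter-cycle cosine ramp
    (sin^2) over `ramp` deg; 1 beyond ``inner + ramp``.
    """
    r = np.asarray(r, dtype=float)
    t = np.clip((r - inner) / ramp, 0.0, 1.0)
    return np.sin(0.5 * math.pi * t) ** 2


def sample_elements(spec: TextureSpec, rng=None) -> ElementList:
    """Sample element positions, orientations, phases and labels.

    Positions are i.i.d. uniform on the square.  Label assignment follows
    the layout: intermixed — i.i.d. signal with probability `coherence`;
    proximal — noise iff the element falls inside the noise annulus
    (between the effective occlusion radius and the outer radius);
    distal — the complement.  Signal elements take the field's implied
    orientation at their position; noise orientations are uniform on
    [-90, 90); phases uniform on [0, 2*pi).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_elements
    layout = spec.layout
    hw = layout.square_half_width
    x = rng.uniform(-hw, hw, n)
    y = rng.uniform(-hw, hw, n)

    if layout.noise_layout == "intermixed":
        signal = rng.random(n) < layout.coherence
    else:
        if layout.annulus_outer_radius is None:
            raise ValueError(f"{layout.noise_layout} layout requires annulus_outer_radius")
        tx, ty = layout.test_point
        d = np.hypot(x - tx, y - ty)
        in_annulus = (d >= layout.effective_occlusion_radius) & (
            d <= layout.annulus_outer_radius
        )
        signal = ~in_annulus if layout.noise_layout == "proximal" else in_annulus

    pts = np.stack([x, y], axis=-1)
    orientation = np.empty(n)
    if signal.any():
        orientation[signal] = np.atleast_1d(
            implied_orientation(spec.field, pts[signal])
        )
    n_noise = int((~signal).sum())
    orientation[~signal] = rng.uniform(-90.0, 90.0, n_noise)
    phase = rng.uniform(0.0, 2.0 * math.pi, n)
    label = np.where(signal, "signal", "noise")
    return ElementList(x=x, y=y, orientation=orientation, phase=phase, label=label)


def _raster(spec: TextureSpec) -> tuple[int, float, float]:
    ppd = spec.pixels_per_degree
    hw = spec.layout.square_half_width
    npx = int(round(2 * hw * ppd))
    dpp = 1.0 / ppd
    # centre of pixel (0, 0): top-left
    x0 = -hw + 0.5 * dpp
    y0 = hw - 0.5 * dpp
    return npx, x0, y0


def _draw_elements(img, elements, sf, diameter, npx, x0, y0, dpp):
    """Accumulate Hanning-windowed gratings into `img` in place.

    Each element touches only a small pixel window, so the loop is over
    elements with vectorised patch arithmetic inside.
    """
    radius = diameter / 2.0
    rpx = int(math.ceil(radius / dpp)) + 1
    for ex, ey, theta, ph in zip(
        elements.x, elements.y, elements.orientation, elements.phase
    ):
        col_c = (ex - x0) / dpp
        row_c = (y0 - ey) / dpp
        c_lo = max(int(math.floor(col_c)) - rpx, 0)
        c_hi = min(int(math.ceil(col_c)) + rpx + 1, npx)
        r_lo = max(int(math.floor(row_c)) - rpx, 0)
        r_hi = min(int(math.ceil(row_c)) + rpx + 1, npx)
        if c_lo >= c_hi or r_lo >= r_hi:
            continue
        px = x0 + np.arange(c_lo, c_hi) * dpp - ex
        py = y0 - np.arange(r_lo, r_hi) * dpp - ey
        dx, dy = np.meshgrid(px, py)
        r = np.hypot(dx, dy)
        w = np.where(r <= radius, np.cos(0.5 * math.pi * r / radius) ** 2, 0.0)
        # carrier varies along the axis perpendicular to the bar orientation;
        # orientation theta = bars along vertical rotated CCW by theta
        th = math.radians(theta)
        u = dx * math.cos(th) + dy * math.sin(th)
        img[r_lo:r_hi, c_lo:c_hi] += w * np.cos(2.0 * math.pi * sf * u + ph)


def render_texture(
    elements: ElementList, spec: TextureSpec, apply_occlusion: bool = True
) -> StimulusImage:
    """Render an element list to a normalised, occluded contrast image.

    Elements are summed additively; the image is mean-subtracted and
    scaled so that RMS contrast over the full square equals
    `spec.rms_contrast`; the occlusion window around the test site is
    applied *after* normalisation (RMS is specified pre-occlusion).
    """
    if len(elements) == 0:
        raise ValueError("cannot render an empty element list")
    npx, x0, y0 = _raster(spec)
    dpp = 1.0 / spec.pixels_per_degree
    img = np.zeros((npx, npx))
    _draw_elements(
        img, elements, spec.element_sf, spec.element_diameter, npx, x0, y0, dpp
    )
    img -= img.mean()
    rms = img.std()
    if rms == 0:
        raise ValueError("degenerate texture: zero contrast energy")
    img *= spec.rms_contrast / rms

    meta = {
        "spec_hash": spec.content_hash(),
        "seed": spec.seed,
        "frame_index": 0,
        "occluded": bool(apply_occlusion),
    }
    if apply_occlusion:
        xx = x0 + np.arange(npx) * dpp
        yy = y0 - np.arange(npx) * dpp
        gx, gy = np.meshgrid(xx, yy)
        tx, ty = spec.layout.test_point
        r = np.hypot(gx - tx, gy - ty)
        img *= occlusion_window(
            r, inner=spec.layout.occlusion_radius, ramp=spec.layout.ramp_width
        )
    return StimulusImage(data=img, degrees_per_pixel=dpp, origin=(x0, y0), metadata=meta)


def render_test(
    orientation: float,
    sf: float = 2.0,
    diameter: float = 1.33,
    peak_contrast: float = 0.25,
    center: tuple[float, float] | None = None,
    pixels_per_degree: int = 15,
    phase: float = 0.0,
    size_degrees: float = 2.0,
) -> StimulusImage:
    """Render a test patch: a windowed sinusoid at the test location.

    With phase 0 the carrier is a cosine at the patch centre, so the peak
    contrast equals `peak_contrast` exactly at the centre.
    """
    if not abs(orientation) < 90:
        raise ValueError("test orientation must satisfy |orientation| < 90")
    if center is None:
        center = test_location()
    dpp = 1.0 / pixels_per_degree
    npx = int(round(size_degrees * pixels_per_degree)) | 1  # odd: centre pixel on centre
    cx, cy = center
    half = (npx - 1) // 2
    x0 = cx - half * dpp
    y0 = cy + half * dpp
    xs = x0 + np.arange(npx) * dpp - cx
    ys = y0 - np.arange(npx) * dpp - cy
    dx, dy = np.meshgrid(xs, ys)
    r = np.hypot(dx, dy)
    radius = diameter / 2.0
    w = np.where(r <= radius, np.cos(0.5 * math.pi * r / radius) ** 2, 0.0)
    th = math.radians(orientation)
    u = dx * math.cos(th) + dy * math.sin(th)
    img = peak_contrast * w * np.cos(2.0 * math.pi * sf * u + phase)
    meta = {"kind": "test", "orientation_deg": orientation, "sf": sf}
    return StimulusImage(data=img, degrees_per_pixel=dpp, origin=(x0, y0), metadata=meta)


def make_adaptor_sequence(
    spec: TextureSpec,
    duration: float,
    refresh: float = 0.1,
    seed: int | None = None,
) -> list[ElementList]:
    """Element lists for one dynamic adaptation period.

    The adaptor is regenerated every `refresh` seconds (100 ms default) to
    avoid afterimage build-up: ``ceil(duration / refresh)`` independent
    samples, with per-frame generators spawned deterministically from the
    master seed.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n_frames = int(math.ceil(duration / refresh))
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    return [
        sample_elements(spec, rng=np.random.default_rng(child))
        for child in master.spawn(n_frames)
    ]
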