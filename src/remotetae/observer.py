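"""Simulated observer: phenomenological adaptation model and 2AFC responses.

The observer adapts to the orientation *implied* at the (occluded) test
location by the surrounding texture structure, producing a repulsive tilt
aftereffect (TAE) whose magnitude is:

``tae = A * coherence**q * G(effective gradient) [+ local term, distal]``

where ``A`` is the peak amplitude (default 2 deg), the gradient tuning
``G`` is a raised cosine peaking at 5 deg of orientation change per deg
of visual angle and vanishing at 0 and 10, and coherence scaling is
linear by default (q = 1).  These defaults encode three empirical
anchors — a ~2 deg TAE for fully coherent concentric structure, peak
sensitivity near the 5 deg/deg gradient, and no effect without an
orientation gradient — with deliberately simple stand-in functional
forms between them; neither the tuning curve nor the coherence law is an
empirically measured shape.

Quantized gradients are readable only while the inter-band orientation
step stays below an ambiguity threshold (default 45 deg, half the 90 deg
orientation-ambiguity limit): a 40 deg step (8 deg bands at rate 5)
leaves the underlying gradient recoverable, a 60 deg step (12 deg bands)
does not, and a band width of one full spatial period yields an
iso-oriented texture with no gradient at all.

Responses follow a lapse-contaminated logistic psychometric function of
test orientation about the shifted point of subjective equality, with
"clockwise" = negative orientation under the CCW-positive convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .geometry import (
    LayoutGeometry,
    OrientationField,
    implied_orientation,
    local_gradient,
    wrap_orientation,
)

__all__ = [
    "AdaptationState",
    "ObserverParams",
    "effective_gradient",
    "gradient_tuning",
    "predicted_tae",
    "simulate_block",
    "simulate_trial",
]

DEFAULT_LEVELS = tuple(np.linspace(-6.0, 6.0, 7))


@dataclass(frozen=True)
class ObserverParams:
    """Tunable parameters of the simulated observer.

    tae_peak_amplitude : deg — TAE for fully coherent structure at the
        preferred gradient.
    tuning_center, tuning_halfwidth : deg orientation / deg space —
        raised-cosine gradient tuning, support
        [center - halfwidth, center + halfwidth].
    coherence_exponent : coherence scaling ``coherence**q`` (1 = linear).
    step_ambiguity_threshold : deg — largest inter-band orientation step
        at which a quantized gradient remains readable.
    local_adaptation_gain : deg — additive PSE shift from signal elements
        adjacent to the test site (distal layouts only), scaled by
        coherence.
    psychometric_slope : deg — logistic slope of the response function.
    lapse_rate : stimulus-independent response probability.
    """

    tae_peak_amplitude: float = 2.0
    tuning_center: float = 5.0
    tuning_halfwidth: float = 5.0
    coherence_exponent: float = 1.0
    step_ambiguity_threshold: float = 45.0
    local_adaptation_gain: float = 0.5
    psychometric_slope: float = 1.5
    lapse_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.tae_peak_amplitude < 0 or self.local_adaptation_gain < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ObserverParams":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class AdaptationState:
    """Summary of the observer's adapted state for one condition."""

    implied_orientation_at_test: float  # deg CCW of vertical
    effective_gradient: float           # deg orientation / deg space
    coherence: float
    layout: str
    predicted_tae: float                # deg, positive = repulsive


def effective_gradient(
    field: OrientationField,
    point,
    sample_spacing: float = 1.0,
    step_ambiguity_threshold: float = 45.0,
) -> float:
    """Orientation gradient the observer can extract at `point`.

    Smooth fields return their analytic local gradient.  Quantized fields
    are evaluated by the inter-band step ``S = band_width * gradient_rate``
    wrapped mod 180: if the step is 0 (mod 180) the quantization removed
    the modulation entirely (iso-oriented texture, gradient 0); if
    ``|S| <= step_ambiguity_threshold`` the underlying rate is readable
    and returned; larger steps are ambiguous (orientation is 180-deg
    periodic) and return 0.

    `sample_spacing` is the probe separation a procedural estimate would
    use; the analytic rules here do not depend on it.
    """
    if field.kind != "quantized_gradient":
        return local_gradient(field, point)
    step = wrap_orientation(field.gradient_rate * field.band_width)
    # wrap_orientation maps to [-90, 90); a step of +90 arrives as -90
    if abs(step) < 1e-9:
        return 0.0
    if abs(step) <= step_ambiguity_threshold:
        return float(field.gradient_rate)
    return 0.0


def gradient_tuning(g: float, center: float = 5.0, halfwidth: float = 5.0) -> float:
    """Raised-cosine gradient tuning: 1 at `center`, 0 outside the support."""
    if abs(g - center) >= halfwidth:
        return 0.0
    return 0.5 * (1.0 + math.cos(math.pi * (g - center) / halfwidth))


def predicted_tae(
    field: OrientationField, layout: LayoutGeometry, params: ObserverParams
) -> AdaptationState:
    """Predict the remote TAE for an adapting configuration.

    Positive values denote repulsion of the perceived test orientation
    away from the implied orientation at the test site.  Proximal noise
    placement behaves exactly like intermixed noise at equal coherence;
    distal layouts gain an additive local-adaptation term from the
    structured elements surrounding the test region.  Reflectional
    symmetry of the adaptor has no effect.
    """
    implied = float(implied_orientation(field, layout.test_point))
    g = effective_gradient(
        field,
        layout.test_point,
        step_ambiguity_threshold=params.step_ambiguity_threshold,
    )
    coh = layout.coherence
    tuning = gradient_tuning(g, params.tuning_center, params.tuning_halfwidth)
    tae = params.tae_peak_amplitude * coh**params.coherence_exponent * tuning
    if layout.noise_layout == "distal":
        tae += params.local_adaptation_gain * coh
    return AdaptationState(
        implied_orientation_at_test=implied,
        effective_gradient=g,
        coherence=coh,
        layout=layout.noise_layout,
        predicted_tae=tae,
    )


def _p_cw(params: ObserverParams, true_pse: float, test_orientation) -> np.ndarray:
    """P(respond 'clockwise') for a test orientation, CCW-positive convention.

    Clockwise = tilted toward negative orientation, so P(CW) decreases
    with test orientation and equals 0.5 at the PSE.
    """
    core = expit((true_pse - np.asarray(test_orientation, float)) / params.psychometric_slope)
    return params.lapse_rate / 2.0 + (1.0 - params.lapse_rate) * core


def simulate_trial(
    params: ObserverParams, true_pse: float, test_orientation: float, rng
) -> str:
    """One 2AFC judgment: ``"CW"`` or ``"CCW"``."""
    return "CW" if rng.random() < float(_p_cw(params, true_pse, test_orientation)) else "CCW"


def simulate_block(
    params: ObserverParams,
    true_pse: float,
    rng,
    levels=DEFAULT_LEVELS,
    reps: int = 10,
    condition_id: str = "",
    block: int = 0,
) -> pd.DataFrame:
    """Simulate one constant-stimuli testing block.

    `reps` presentations of each of the (strictly increasing) `levels`,
    randomly ordered, yielding ``reps * len(levels)`` trial rows with
    columns ``condition_id, block, trial, test_orientation_deg, response``.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.ndim != 1 or len(levels) < 2 or np.any(np.diff(levels) <= 0):
        raise ValueError("levels must be strictly increasing with >= 2 entries")
    order = rng.permutation(np.repeat(levels, reps))
    p = _p_cw(params, true_pse, order)
    responses = np.where(rng.random(len(order)) < p, "CW", "CCW")
    return pd.DataFrame(
        {
            "condition_id": condition_id,
            "block": block,
            "trial": np.arange(len(order)),
            "test_orientation_deg": order,
            "response": responses,
        }
    )
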