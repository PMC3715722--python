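"""Maximum-likelihood psychometric fitting, bootstrap SEs and TAE computation.

Trials from a method-of-constant-stimuli 2AFC task (clockwise /
counter-clockwise judgments of a test orientation) are fitted with a
two-parameter logistic by maximising the Bernoulli likelihood of

``P(CW | theta) = logistic((pse - theta) / slope)``

(CW responses become *less* likely as the test rotates counter-clockwise).
The PSE is the orientation eliciting clockwise and counter-clockwise
responses equally often; the tilt aftereffect is the PSE change relative
to an unadapted baseline, signed so that repulsion away from the implied
adaptor orientation is positive.  Standard errors come from a
nonparametric bootstrap that resamples trials with replacement within
each orientation level (the design is fixed, so levels are strata).

The fitted model carries no lapse term; a small simulation lapse then
acts as a robustness stressor rather than a fitted parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "AmbiguousSignWarning",
    "FittingError",
    "PsychometricFit",
    "SeparationWarning",
    "bootstrap_se",
    "compute_tae",
    "fit_psychometric",
]


class FittingError(RuntimeError):
    """Raised when the trial data cannot constrain a psychometric fit."""


class SeparationWarning(UserWarning):
    """Responses are perfectly ordered; the slope is unidentifiable."""


class AmbiguousSignWarning(UserWarning):
    """TAE sign convention undefined (implied orientation exactly vertical)."""


@dataclass
class PsychometricFit:
    """Fitted logistic psychometric function."""

    pse: float            # deg; orientation of equal CW/CCW proportions
    slope: float          # deg; logistic scale parameter
    log_likelihood: float
    converged: bool
    n_trials: int
    bootstrap_se: float | None = None

    def to_dict(self) -> dict:
        return {
            "pse": self.pse,
            "slope": self.slope,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_trials": self.n_trials,
            "bootstrap_se": self.bootstrap_se,
        }


def _aggregate(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a trial table to per-level (orientation, n, CW count)."""
    if not set(trials["response"]).issubset({"CW", "CCW"}):
        raise ValueError("responses must be 'CW' or 'CCW'")
    grp = (
        trials.assign(cw=(trials["response"] == "CW").astype(int))
        .groupby("test_orientation_deg")["cw"]
        .agg(["size", "sum"])
        .sort_index()
    )
    return (
        grp.index.to_numpy(float),
        grp["size"].to_numpy(float),
        grp["sum"].to_numpy(float),
    )


def _nll(theta, n, k):
    """Negative log-likelihood on (pse, log slope), vectorised over levels."""

    def fun(x):
        pse, log_slope = x
        p = expit((pse - theta) / np.exp(log_slope))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    return fun


def _is_separated(n: np.ndarray, k: np.ndarray) -> bool:
    """Perfectly ordered responses: every level all-CW or all-CCW, with all
    CW levels below all CCW levels (a step function)."""
    p = k / n
    if not np.all((p == 0.0) | (p == 1.0)):
        return False
    return bool(np.all(np.diff(p) <= 0))


def _fit_counts(
    theta: np.ndarray,
    n: np.ndarray,
    k: np.ndarray,
    start: tuple[float, float] | None = None,
    slope_starts=(0.5, 1.5, 5.0),
) -> tuple[float, float, float, bool]:
    """Core MLE on aggregated counts; returns (pse, slope, logL, converged)."""
    fun = _nll(theta, n, k)
    p = k / n
    # data-driven PSE start: orientation of the 50% crossing (interpolated)
    if np.any(p >= 0.5) and np.any(p <= 0.5):
        pse0 = float(np.interp(0.5, p[::-1], theta[::-1]))
    else:
        pse0 = float(np.average(theta, weights=n))
    if start is not None:
        starts = [(start[0], np.log(start[1]))]
    else:
        starts = [(pse0, np.log(s)) for s in slope_starts]
    best = None
    for x0 in starts:
        res = minimize(
            fun,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    pse, log_slope = best.x
    return float(pse), float(np.exp(log_slope)), float(-best.fun), bool(best.success)


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Fit the two-parameter logistic to a trial table by maximum likelihood.

    Deterministic given the trials: counts are aggregated per level and a
    fixed multi-start Nelder-Mead search (slope starts 0.5, 1.5, 5 deg)
    keeps the best likelihood.

    Raises :class:`FittingError` when all responses are identical (the
    PSE is then unbounded).  Complete separation — responses perfectly
    ordered in orientation — leaves the slope unidentifiable: the fit is
    flagged ``converged=False`` with the PSE set to the midpoint between
    the straddling levels, and a :class:`SeparationWarning` is issued.
    """
    theta, n, k = _aggregate(trials)
    if len(theta) < 2:
        raise FittingError("need >= 2 distinct orientation levels")
    total_cw = k.sum()
    if total_cw == 0 or total_cw == n.sum():
        raise FittingError("all responses identical; PSE is unbounded")
    if _is_separated(n, k):
        p = k / n
        last_cw = theta[p == 1.0][-1]
        first_ccw = theta[p == 0.0][0]
        pse = 0.5 * (last_cw + first_ccw)
        warnings.warn(
            "complete separation: slope unidentifiable, PSE set to the "
            "midpoint between straddling levels",
            SeparationWarning,
        )
        return PsychometricFit(
            pse=float(pse),
            slope=float("nan"),
            log_likelihood=0.0,
            converged=False,
            n_trials=int(n.sum()),
        )
    pse, slope, ll, ok = _fit_counts(theta, n, k)
    return PsychometricFit(
        pse=pse,
        slope=slope,
        log_likelihood=ll,
        converged=ok,
        n_trials=int(n.sum()),
    )


def bootstrap_se(
    trials: pd.DataFrame,
    n_boot: int = 1000,
    rng=None,
    max_dropped_fraction: float = 0.1,
) -> float:
    """Bootstrap standard error of the PSE.

    Trials are resampled with replacement *within* each orientation level
    (the constant-stimuli design is fixed), each resample refitted from
    the original estimate, and the SE taken as the standard deviation of
    the refitted PSEs.  Degenerate resamples (all one response, or
    complete separation) are dropped and counted; more than 10% dropped
    raises :class:`FittingError`.
    """
    if rng is None:
        rng = np.random.default_rng()
    fit = fit_psychometric(trials)
    if not fit.converged:
        raise FittingError("bootstrap requires a converged fit on the original data")
    theta, n, k = _aggregate(trials)
    n_int = n.astype(int)
    # within-level resampling of exchangeable binary responses == binomial draw
    k_star = rng.binomial(n_int, k / n, size=(n_boot, len(theta))).astype(float)
    pses = []
    dropped = 0
    for kb in k_star:
        tot = kb.sum()
        if tot == 0 or tot == n.sum() or _is_separated(n, kb):
            dropped += 1
            continue
        pse_b, _, _, _ = _fit_counts(theta, n, kb, start=(fit.pse, fit.slope))
        pses.append(pse_b)
    if dropped > max_dropped_fraction * n_boot:
        raise FittingError(
            f"{dropped}/{n_boot} degenerate bootstrap resamples (> "
            f"{max_dropped_fraction:.0%})"
        )
    return float(np.std(pses, ddof=1))


def compute_tae(
    fit_adapt: PsychometricFit,
    fit_base: PsychometricFit,
    implied_orientation: float,
) -> float:
    """Tilt aftereffect: PSE change relative to baseline, repulsion positive.

    ``tae = sign(implied_orientation) * (pse_adapt - pse_base)`` under the
    CCW-positive convention, so repulsion away from the implied adaptor
    orientation is positive on either side of vertical.  If the implied
    orientation is exactly vertical the sign is undefined: the raw PSE
    difference is returned with an :class:`AmbiguousSignWarning`.
    """
    if not (fit_adapt.converged and fit_base.converged):
        raise FittingError("compute_tae requires two converged fits")
    diff = fit_adapt.pse - fit_base.pse
    if implied_orientation == 0:
        warnings.warn(
            "implied orientation is vertical; returning the raw PSE difference",
            AmbiguousSignWarning,
        )
        return float(diff)
    return float(np.sign(implied_orientation) * diff)
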