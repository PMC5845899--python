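"""Timbre-perception sigmoid fitting and per-subject timbre-level assignment.

Listeners rate morphs between the two instruments on a 1-5 scale
(1 = bassoon percept, 3 = intermediate, 5 = cello percept).  Per voice the
mean percept follows a logistic curve on the morph axis r (fraction of the
*other* instrument, 0 = pure original):

    S(r) = a + (b - a) / (1 + 10^((x50 - r) * m)),   a = 1, b = 5

x50 is the perceptual center (the morph fraction rated midway between the
instruments) and m the slope.  The fitted x50 defines each subject's
*minimum* timbre distance; *intermediate* sits 20 percentage points back
toward the original, and *maximum* is the unmorphed instrument (r = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

A_MIN = 1.0  # rating floor (pure-original percept)
B_MAX = 5.0  # rating ceiling (fully-morphed percept)
MAX_ITER = 200
RSS_TOL = 1e-10


class DegenerateDataError(ValueError):
    """Ratings carry no information about the sigmoid (e.g. all identical)."""


@dataclass(frozen=True)
class SigmoidFit:
    voice: str
    x50: float
    m: float
    rss: float
    n_points: int
    converged: bool
    a: float = A_MIN
    b: float = B_MAX


@dataclass(frozen=True)
class TimbreLevels:
    """Morph fractions realising the three timbre-distance conditions."""

    maximum: float  # 0.0 — original instrument
    intermediate: float  # x50 - 0.20, floored at 0
    minimum: float  # x50 — perceptual center


def sigmoid_value(r, x50: float, m: float):
    """Predicted rating at morph fraction ``r``; vectorised over ``r``."""
    return A_MIN + (B_MAX - A_MIN) / (1.0 + 10.0 ** ((x50 - np.asarray(r)) * m))


def _init_x50(r: np.ndarray, ratings: np.ndarray) -> float:
    """Data-driven start: the morph fraction whose mean rating is nearest the
    scale midpoint (3), i.e. the empirical perceptual center."""
    levels = np.unique(r)
    means = np.array([ratings[r == lv].mean() for lv in levels])
    return float(levels[np.argmin(np.abs(means - 3.0))])


def fit_sigmoid(r, ratings, voice: str = "upper") -> SigmoidFit:
    """Least-squares fit of (x50, m) with the asymptotes fixed at 1 and 5.

    Uses Levenberg-Marquardt (damped Gauss-Newton), initialised at slope
    m = 1 and x50 at the empirical perceptual center, capped at
    :data:`MAX_ITER` residual evaluations with an rss-change tolerance of
    :data:`RSS_TOL`.
    """
    r = np.asarray(r, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    if r.shape != ratings.shape or r.ndim != 1:
        raise ValueError("r and ratings must be equal-length 1-d arrays")
    if len(np.unique(r)) < 4:
        raise ValueError("need ratings at >= 4 distinct morph fractions")
    if np.ptp(ratings) == 0:
        raise DegenerateDataError("all ratings identical; sigmoid unidentifiable")

    x0 = np.array([_init_x50(r, ratings), 1.0])
    res = least_squares(
        lambda p: sigmoid_value(r, p[0], p[1]) - ratings,
        x0, method="lm", max_nfev=MAX_ITER, ftol=RSS_TOL, xtol=1e-12, gtol=1e-12,
    )
    rss = float(np.sum(res.fun ** 2))
    converged = bool(res.status > 0 and np.all(np.isfinite(res.x)))
    return SigmoidFit(voice=voice, x50=float(res.x[0]), m=float(res.x[1]),
                      rss=rss, n_points=len(r), converged=converged)


def assign_timbre_levels(fit: SigmoidFit) -> TimbreLevels:
    """Derive the maximum/intermediate/minimum morph fractions from a fit."""
    if not fit.converged:
        raise ValueError("cannot assign timbre levels from a non-converged fit")
    if not (0.0 < fit.x50 < 1.0):
        raise ValueError(f"x50={fit.x50:.3f} outside the morph axis (0, 1)")
    return TimbreLevels(
        maximum=0.0,
        intermediate=max(0.0, fit.x50 - 0.20),
        minimum=fit.x50,
    )
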