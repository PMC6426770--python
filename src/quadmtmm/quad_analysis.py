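"""Interpretation of a fitted quadratic method-effect curve.

For ``f(t) = b0 + b1 t + b2 t^2`` these helpers report the trait levels
at which the predicted method effect vanishes (roots), the trait level
of peak discrepancy (the vertex, at ``-b1 / (2 b2)``), the predicted
effect there, and evaluation grids for plotting the quadratic against
its nested linear fit.  All quantities are only substantively meaningful
inside the observed trait range, so every summary carries an in-range
flag instead of silently dropping out-of-range values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lms_quadratic import QuadraticStructural

__all__ = [
    "CurveSummary",
    "B2_LINEAR_THRESHOLD",
    "inflection_point",
    "quadratic_roots",
    "extremum_value",
    "predicted_curve",
    "curve_summary",
]

#: below this |b2| the curve is treated as effectively linear
B2_LINEAR_THRESHOLD = 1e-10


class LinearCurveError(ValueError):
    """Raised when |b2| is below the linear threshold."""


def _check_b2(b2: float) -> None:
    if abs(b2) <= B2_LINEAR_THRESHOLD:
        raise LinearCurveError(
            "quadratic coefficient is effectively zero: use the linear parameterization"
        )


def inflection_point(b1: float, b2: float) -> float:
    """Trait level of the curve's extremum, ``-b1 / (2 b2)``."""
    _check_b2(b2)
    return -b1 / (2.0 * b2)


def quadratic_roots(b0: float, b1: float, b2: float) -> list[float]:
    """Real roots of ``b0 + b1 t + b2 t^2``, ascending; [] if none.

    For effectively-zero ``b2`` the single linear root is returned.
    """
    if abs(b2) <= B2_LINEAR_THRESHOLD:
        if b1 == 0:
            return []
        return [-b0 / b1]
    disc = b1 * b1 - 4.0 * b2 * b0
    if abs(disc) < 1e-12:
        return [-b1 / (2.0 * b2)]
    if disc < 0:
        return []
    sq = np.sqrt(disc)
    roots = sorted([(-b1 - sq) / (2.0 * b2), (-b1 + sq) / (2.0 * b2)])
    return [float(r) for r in roots]


def extremum_value(b0: float, b1: float, b2: float) -> float:
    """Predicted method effect at the inflection point (min if b2>0)."""
    _check_b2(b2)
    t_star = inflection_point(b1, b2)
    return float(b0 + b1 * t_star + b2 * t_star * t_star)


def predicted_curve(
    quad: QuadraticStructural | tuple,
    t_min: float,
    t_max: float,
    n_points: int = 101,
    linear_coefs: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Evaluation grid ``(t, quadratic_prediction[, linear_prediction])``.

    ``linear_coefs = (b0_lin, b1_lin)`` adds the nested linear fit's
    prediction for side-by-side plotting.
    """
    if not t_min < t_max:
        raise ValueError("need t_min < t_max")
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    if isinstance(quad, QuadraticStructural):
        b0, b1, b2 = quad.b0, quad.b1, quad.b2
    else:
        b0, b1, b2 = quad
    t = np.linspace(t_min, t_max, n_points)
    frame = pd.DataFrame({"t": t, "quadratic_prediction": b0 + b1 * t + b2 * t * t})
    if linear_coefs is not None:
        frame["linear_prediction"] = linear_coefs[0] + linear_coefs[1] * t
    return frame


@dataclass
class CurveSummary:
    b0: float
    b1: float
    b2: float
    curvature: str  # "u-shaped" | "inverted-u" | "linear"
    inflection: float | None
    extremum: float | None
    roots: list = field(default_factory=list)
    trait_range: tuple | None = None
    inflection_in_range: bool | None = None
    roots_in_range: list = field(default_factory=list)
    grid: pd.DataFrame | None = None


def curve_summary(
    b0: float,
    b1: float,
    b2: float,
    trait_range: tuple[float, float] | None = None,
    n_points: int = 101,
) -> CurveSummary:
    """Full analytic summary of one quadratic method-effect curve."""
    linear = abs(b2) <= B2_LINEAR_THRESHOLD
    roots = quadratic_roots(b0, b1, b2)
    if linear:
        infl = extremum = None
        curvature = "linear"
    else:
        infl = inflection_point(b1, b2)
        extremum = extremum_value(b0, b1, b2)
        curvature = "u-shaped" if b2 > 0 else "inverted-u"
    in_range = lambda t: bool(trait_range[0] <= t <= trait_range[1]) if trait_range else None
    grid = None
    if trait_range is not None:
        grid = predicted_curve((b0, b1, b2), trait_range[0], trait_range[1], n_points)
    return CurveSummary(
        b0=b0,
        b1=b1,
        b2=b2,
        curvature=curvature,
        inflection=infl,
        extremum=extremum,
        roots=roots,
        trait_range=trait_range,
        inflection_in_range=None if (linear or trait_range is None) else in_range(infl),
        roots_in_range=[in_range(r) for r in roots] if trait_range else [],
        grid=grid,
    )
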