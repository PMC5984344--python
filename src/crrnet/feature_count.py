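"""Arctan saturation-curve fitting and tangent-based feature-count choice.

Classification performance as a function of feature-subset size rises
steeply then plateaus.  The curve y = (2s/pi) * arctan(k x) is fit by least
squares (k: horizontal scale, s: asymptote), and the operating subset size is
the point where the curve's tangent slope falls to a chosen value t
(default 0.5), trading subset size against performance:

    x_t = (1/k) * sqrt((2 k s - t pi) / (t pi)),    y_t = (2s/pi) arctan(k x_t)
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

DEFAULT_TANGENT = 0.5


class ArctanFitError(RuntimeError):
    def __init__(self, message: str, last_params=None, residual=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual = residual


@dataclass
class ArctanFit:
    """Fitted scale parameters of y = (2s/pi) * arctan(k x)."""

    k: float
    s: float
    rss: float
    x: np.ndarray
    y: np.ndarray

    def predict(self, x) -> np.ndarray:
        return (2.0 * self.s / np.pi) * np.arctan(self.k * np.asarray(x, dtype=float))

    def slope(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 2.0 * self.s * self.k / (np.pi * (1.0 + self.k**2 * x**2))

    def to_json(self, path, tangent_point: tuple[float, float, int] | None = None) -> None:
        payload = {"k": self.k, "s": self.s, "rss": self.rss}
        if tangent_point is not None:
            payload.update(
                {"x_t": tangent_point[0], "y_t": tangent_point[1], "m": tangent_point[2]}
            )
        with open(path, "w") as fh:
            json.dump(payload, fh)


def fit_arctan(points: Sequence[tuple[float, float]]) -> ArctanFit:
    """Least-squares fit of (k, s) to (subset size, auPRC) points.

    Initialization is k0 = 1, s0 = max(y); iteration stops when the step
    falls below 1e-10 or after 500 evaluations.  A near-zero fitted
    asymptote triggers a degenerate-fit warning.
    """
    pts = [(float(x), float(y)) for x, y in points]
    xs = np.array([x for x, _ in pts])
    ys = np.array([y for _, y in pts])
    if len(np.unique(xs)) < 2:
        raise ValueError("need at least 2 points with distinct x")
    if np.any(xs < 0):
        raise ValueError("subset sizes must be non-negative")

    def residuals(params):
        k, s = params
        return (2.0 * s / np.pi) * np.arctan(k * xs) - ys

    s0 = max(float(ys.max()), 1e-8)
    result = least_squares(
        residuals,
        x0=[1.0, s0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=500,
    )
    rss = float(np.sum(result.fun**2))
    if not result.success:
        raise ArctanFitError(
            f"arctan fit did not converge: {result.message}",
            last_params=tuple(result.x),
            residual=rss,
        )
    k, s = (float(v) for v in result.x)
    if s < 1e-6:
        warnings.warn("degenerate arctan fit: asymptote is ~0", RuntimeWarning, stacklevel=2)
    return ArctanFit(k=k, s=s, rss=rss, x=xs, y=ys)


def select_feature_count(
    fit: ArctanFit, t: float = DEFAULT_TANGENT
) -> tuple[float, float, int]:
    """Tangent point of the fitted curve at slope t, and the feature count.

    Requires 0 < t < 2ks/pi (the slope at the origin); returns
    (x_t, y_t, m) with m = ceil(x_t) since feature counts are integers.
    """
    slope0 = 2.0 * fit.k * fit.s / math.pi
    if not 0 < t < slope0:
        raise ValueError(
            f"tangent t={t:g} must lie in (0, {slope0:g}), the slope at the origin"
        )
    x_t = (1.0 / fit.k) * math.sqrt((2.0 * fit.k * fit.s - t * math.pi) / (t * math.pi))
    y_t = (2.0 * fit.s / math.pi) * math.atan(fit.k * x_t)
    return x_t, y_t, int(math.ceil(x_t))
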