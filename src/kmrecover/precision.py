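"""How coordinate rounding propagates into the recovered quantities.

A raster figure resolves heights to one pixel; a vector (PostScript) figure
resolves them to the decimal precision of the stored coordinates — typically
three decimal places of a printer point, i.e. orders of magnitude finer.

The number at risk, however, is recovered as (roughly) the *reciprocal* of a
jump, so its precision is governed by a ratio of noisy quantities.  For a
cumulative incidence curve drawn on a 0-to-axis_max% axis, the estimate has
the form

    n = [F (c - d) - (b - d)] / (a - b),        F = 100% / axis_max%,

where a, b are the device heights of two adjacent curve points and c, d those
of the axis_max% and 0% landmarks.  With independent uniform rounding errors
of full width ``rounding_range`` on each coordinate (SD = range / sqrt(12)),
the numerator error has variance (F^2 + (F-1)^2 + 1) sigma_e^2, the
denominator 2 sigma_e^2, and they covary through the shared b with
covariance sigma_e^2.  A first-order (delta-method) expansion of the ratio
gives its coefficient of variation; :func:`monte_carlo_ratio_cv` provides the
independent simulation check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_AXIS_FACTOR = 20.0  # 100% / 5%: the common truncated incidence axis


@dataclass(frozen=True)
class ErrorModel:
    """Delta-method ingredients for the ratio n = N / D.

    mu1, mu2: error-free numerator and denominator magnitudes in printer
    points (e.g. ~2000 and ~0.5 for a large trial on a 0-5% axis);
    rounding_range: full width of the per-coordinate uniform rounding error
    in points (0.001 for 3-decimal coordinates, 0.01 for 2);
    axis_factor F: 100% divided by the axis maximum in %, the scale factor
    relating the axis landmarks to the full probability scale.
    """

    mu1: float
    mu2: float
    rounding_range: float
    axis_factor: float = DEFAULT_AXIS_FACTOR
    axis_scale: float = 1.0  # points per unit of the plotted quantity

    def __post_init__(self) -> None:
        if self.mu2 <= 0:
            raise ValueError("mu2 (denominator magnitude) must be positive")
        if self.rounding_range < 0:
            raise ValueError("rounding_range must be non-negative")

    @property
    def sigma_e(self) -> float:
        """Per-coordinate error SD under the uniform rounding model."""
        return self.rounding_range / math.sqrt(12.0)

    @property
    def sigma1_sq(self) -> float:
        f = self.axis_factor
        return (f * f + (f - 1.0) ** 2 + 1.0) * self.sigma_e**2

    @property
    def sigma2_sq(self) -> float:
        return 2.0 * self.sigma_e**2

    @property
    def sigma12(self) -> float:
        return self.sigma_e**2

    @property
    def cv(self) -> float:
        return ratio_cv(self)


def raster_resolution(dpi: float, axis_length_inches: float) -> float:
    """Height resolution (one pixel) on a unit (0, 1) axis of a raster image."""
    if dpi <= 0 or axis_length_inches <= 0:
        raise ValueError("dpi and axis length must be positive")
    return 1.0 / (dpi * axis_length_inches)


def vector_resolution(axis_length_points: float, decimals: int) -> float:
    """Height resolution of PostScript coordinates carrying ``decimals``
    decimal places, on a unit axis of the given length in points."""
    if axis_length_points <= 0:
        raise ValueError("axis length must be positive")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    return 1.0 / (axis_length_points * 10.0**decimals)


def ratio_cv(model: ErrorModel) -> float:
    """Delta-method coefficient of variation of the ratio N / D.

    CV^2 = sigma1^2/mu1^2 + sigma2^2/mu2^2 - 2 sigma12/(mu1 mu2); exactly
    linear in ``rounding_range``.
    """
    cv_sq = (
        model.sigma1_sq / model.mu1**2
        + model.sigma2_sq / model.mu2**2
        - 2.0 * model.sigma12 / (model.mu1 * model.mu2)
    )
    return math.sqrt(max(cv_sq, 0.0))


def monte_carlo_ratio_cv(
    model: ErrorModel, n_draws: int = 1_000_000, seed: int | None = 0
) -> float:
    """Simulation estimate of the ratio CV, the independent check on
    :func:`ratio_cv`.

    Draws independent uniform rounding errors on the four coordinates
    (a, b: adjacent curve heights; c, d: axis landmarks), forms the composite
    numerator and denominator errors, and returns sd(R)/mean(R) of the ratio.
    """
    if model.rounding_range == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    half = model.rounding_range / 2.0
    f = model.axis_factor
    e = rng.uniform(-half, half, size=(4, n_draws))  # rows: a, b, c, d
    num = model.mu1 + f * e[2] - (f - 1.0) * e[3] - e[1]
    den = model.mu2 + e[0] - e[1]
    r = num / den
    return float(np.std(r) / np.mean(r))


def n_precision_report(table, model: ErrorModel) -> "np.ndarray":
    """Per-row expected SD of the recovered n under the rounding model.

    For each row the denominator magnitude is that row's jump expressed in
    printer points and the numerator the prior height in the same numerator
    units; SD = CV * n_j.  Returns an array aligned with the table rows.
    """
    from dataclasses import replace

    s_prev = np.concatenate([[1.0], table.km_heights()[:-1]])
    jumps = s_prev * np.asarray(table.d) / np.asarray(table.n)
    sds = []
    for j in range(table.k):
        mu2 = jumps[j] * model.axis_scale
        mu1 = table.d[j] * s_prev[j] * model.axis_scale
        row_model = replace(model, mu1=mu1, mu2=mu2)
        sds.append(ratio_cv(row_model) * table.n[j])
    return np.asarray(sds)
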