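"""Affine map between device (printer-point) and data (time, probability) axes.

Each axis is calibrated independently from two user-supplied anchors — for
example "device x 72 is t = 0, device x 216 is t = 5".  Published survival
axes are orthogonal, so no rotation or shear is modelled.  The y slope may be
negative: PostScript files exported from PDF viewers are often described with
vertical positions measured from the top of the page, and the anchors resolve
the orientation per file without any global convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import CalibrationError

logger = logging.getLogger(__name__)

AnchorPair = tuple[tuple[float, float], tuple[float, float]]  # ((dev, data), (dev, data))


@dataclass(frozen=True)
class _AxisMap:
    slope: float  # data units per device point
    intercept: float

    def forward(self, device: float) -> float:
        return self.slope * device + self.intercept

    def inverse(self, data: float) -> float:
        return (data - self.intercept) / self.slope


@dataclass(frozen=True)
class AxisCalibration:
    """Invertible per-axis affine map, built by :func:`calibrate`."""

    x_anchors: AnchorPair
    y_anchors: AnchorPair
    x_map: _AxisMap
    y_map: _AxisMap

    @property
    def x_scale(self) -> float:
        """Device points per unit of time (signed)."""
        return 1.0 / self.x_map.slope

    @property
    def y_scale(self) -> float:
        """Device points per unit of plotted probability/hazard (signed)."""
        return 1.0 / self.y_map.slope


def _fit_axis(anchors: AnchorPair, axis: str) -> _AxisMap:
    (dev0, dat0), (dev1, dat1) = anchors
    if dev0 == dev1:
        raise CalibrationError(f"degenerate calibration: identical device {axis} anchors ({dev0})")
    if dat0 == dat1:
        raise CalibrationError(f"degenerate calibration: identical data {axis} anchors ({dat0})")
    slope = (dat1 - dat0) / (dev1 - dev0)
    return _AxisMap(slope, dat0 - slope * dev0)


def calibrate(x_anchor_pairs: AnchorPair, y_anchor_pairs: AnchorPair) -> AxisCalibration:
    """Build the device<->data map from two anchors per axis.

    Anchor order is irrelevant.  A negative y slope (from-top device
    coordinates) is permitted and expected for many exported files.
    """
    return AxisCalibration(
        x_anchors=tuple(tuple(a) for a in x_anchor_pairs),  # type: ignore[arg-type]
        y_anchors=tuple(tuple(a) for a in y_anchor_pairs),  # type: ignore[arg-type]
        x_map=_fit_axis(x_anchor_pairs, "x"),
        y_map=_fit_axis(y_anchor_pairs, "y"),
    )


def device_to_data(point: tuple[float, float], calib: AxisCalibration) -> tuple[float, float]:
    """Map a device point to (t, S).  Extrapolation is allowed but logged."""
    t = calib.x_map.forward(point[0])
    s = calib.y_map.forward(point[1])
    if not -0.05 <= s <= 1.05:
        logger.info("device point %s maps outside the unit band: S=%.4f", point, s)
    return (t, s)


def data_to_device(point: tuple[float, float], calib: AxisCalibration) -> tuple[float, float]:
    """Inverse of :func:`device_to_data` (round-trips to 1e-9)."""
    return (calib.x_map.inverse(point[0]), calib.y_map.inverse(point[1]))
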