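"""Visual-field to superior-colliculus tissue mapping and stimulus scaling.

The macaque SC represents the contralateral visual field on a retinotopic
motor map with strong foveal magnification.  The canonical log-polar mapping
used here takes a visual point at eccentricity ``R`` (degrees of visual
angle, dva) and polar angle ``theta`` (degrees from the horizontal meridian)
to anatomical coordinates (X, Y) in millimetres of tissue::

    X = 1.1 * ln( sqrt(R^2 + 1.8 R cos(theta) + 0.81) / 0.9 )
    Y = 1.8 * atan2( R sin(theta), R cos(theta) + 0.9 )

Along the horizontal meridian (theta = 0) this collapses to
``X = 1.1 ln((R + 0.9) / 0.9)``, whose derivative ``1.1 / (R + 0.9)`` is the
local linear magnification in mm/dva: tissue per degree shrinks with
eccentricity, so a fixed-size stimulus occupies ever less of the map as it
moves out.  "Scaled" stimulus sets invert this: the disc diameter at each
eccentricity is chosen so its image on the map has the same tissue extent as
a reference disc, yielding a constant point image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "VisualPoint",
    "CollicularPoint",
    "ScalingSpec",
    "SpeedEstimate",
    "visual_to_collicular",
    "collicular_x",
    "linear_magnification",
    "collicular_extent",
    "scaled_diameter",
    "scaled_diameter_series",
    "slope_to_collicular_speed",
]

# Mapping constants (mm and dva); single canonical macaque map.
_A = 1.1   # mm, magnification scale
_E0 = 0.9  # dva, foveal offset


@dataclass(frozen=True)
class VisualPoint:
    """A point in the visual field: eccentricity in dva, polar angle in degrees."""

    eccentricity: float
    polar_angle: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.polar_angle):
            raise ValueError("polar angle must be finite")
        if self.eccentricity < 0:
            raise ValueError(f"eccentricity must be >= 0, got {self.eccentricity}")


@dataclass(frozen=True)
class CollicularPoint:
    """A point on the SC map: mm along the horizontal-meridian axis and orthogonal."""

    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class ScalingSpec:
    """Reference disc defining the constant-point-image scaling.

    ``rounding`` is the number of decimals applied to the solved diameter
    (the experimental stimulus table uses 2); ``None`` keeps the exact
    root-finding solution.
    """

    ref_eccentricity: float = 2.0
    ref_diameter: float = 0.1
    rounding: int | None = 2

    def __post_init__(self) -> None:
        if self.ref_diameter <= 0:
            raise ValueError("reference diameter must be positive")
        if self.ref_eccentricity <= self.ref_diameter / 2:
            raise ValueError("reference disc must not straddle the fovea")


def visual_to_collicular(point: VisualPoint) -> CollicularPoint:
    """Map a visual-field point to SC tissue coordinates in mm."""
    r = point.eccentricity
    if r < 0:
        raise ValueError("eccentricity must be >= 0")
    th = math.radians(point.polar_angle)
    x = _A * math.log(math.sqrt(r * r + 2 * _E0 * r * math.cos(th) + _E0 * _E0) / _E0)
    y = 1.8 * math.atan2(r * math.sin(th), r * math.cos(th) + _E0)
    return CollicularPoint(x_mm=x, y_mm=y)


def collicular_x(r: float | np.ndarray) -> float | np.ndarray:
    """Horizontal-meridian map position X(R) in mm (theta = 0 shortcut)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("eccentricity must be >= 0")
    out = _A * np.log((r + _E0) / _E0)
    return float(out) if out.ndim == 0 else out


def linear_magnification(r: float | np.ndarray) -> float | np.ndarray:
    """Local magnification dX/dR in mm/dva along the horizontal meridian."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("eccentricity must be >= 0")
    out = _A / (r + _E0)
    return float(out) if out.ndim == 0 else out


def collicular_extent(ecc: float, diameter: float) -> float:
    """SC image length (mm) of a disc of given diameter centred at ``ecc``."""
    if ecc - diameter / 2 < 0:
        raise ValueError("disc extends across the fovea")
    return collicular_x(ecc + diameter / 2) - collicular_x(ecc - diameter / 2)


def scaled_diameter(ecc: float, spec: ScalingSpec = ScalingSpec()) -> float:
    """Disc diameter at ``ecc`` whose SC image length matches the reference disc.

    Solves X(ecc + d/2) - X(ecc - d/2) = reference extent by bracketed
    root-finding on d in (0, 2*ecc), then rounds per ``spec.rounding``.
    """
    if ecc <= 0:
        raise ValueError("eccentricity must be positive")
    target = collicular_extent(spec.ref_eccentricity, spec.ref_diameter)

    def gap(d: float) -> float:
        return collicular_extent(ecc, d) - target

    lo, hi = 1e-12, 2 * ecc - 1e-12
    if gap(hi) < 0:
        raise ArithmeticError(f"no extent-matched diameter in (0, {2 * ecc}) dva")
    d = brentq(gap, lo, hi, xtol=1e-9)
    if spec.rounding is not None:
        d = round(d, spec.rounding)
    return float(d)


def scaled_diameter_series(
    eccentricities: tuple[float, ...] = (2, 3, 4, 5, 6, 8, 10),
    spec: ScalingSpec = ScalingSpec(),
) -> list[float]:
    """Extent-matched diameters for a set of target eccentricities."""
    return [scaled_diameter(e, spec) for e in eccentricities]


@dataclass(frozen=True)
class SpeedEstimate:
    """Tissue-speed conversion of an SRT-eccentricity slope, with its convention."""

    speed_cm_per_s: float
    convention: str
    per_target: dict = field(default_factory=dict)


def slope_to_collicular_speed(
    slope_ms_per_dva: float,
    target_eccentricities: tuple[float, ...] = (2, 3, 4, 5, 6, 8, 10),
    convention: str = "chord",
) -> SpeedEstimate:
    """Convert an SRT slope (ms/dva) into a traversal speed on the SC map.

    Under the default ``"chord"`` convention, each target contributes the
    fovea-to-target map distance X(R) divided by the time slope * R, i.e.
    the mean speed of a scan covering the whole chord; the per-target speeds
    are averaged arithmetically.  The ``"local"`` convention instead uses
    the local magnification dX/dR / slope at each target.  1 mm/ms equals
    100 cm/s.
    """
    if slope_ms_per_dva <= 0:
        raise ValueError("slope must be positive")
    if len(target_eccentricities) == 0:
        raise ValueError("target set must not be empty")
    per: dict[float, float] = {}
    for r in target_eccentricities:
        if convention == "chord":
            mm_per_ms = collicular_x(r) / (slope_ms_per_dva * r)
        elif convention == "local":
            mm_per_ms = linear_magnification(r) / slope_ms_per_dva
        else:
            raise ValueError(f"unknown convention {convention!r}")
        per[float(r)] = float(mm_per_ms * 100.0)
    return SpeedEstimate(
        speed_cm_per_s=float(np.mean(list(per.values()))),
        convention=convention,
        per_target=per,
    )
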