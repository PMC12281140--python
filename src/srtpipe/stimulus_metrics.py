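"""Contrast and luminance arithmetic for the stimulus sets.

Targets are white discs on a grey background; the contrast manipulation in
the modified Step task uses three luminance levels on a dimmed background.
Weber contrast (L - Lb)/Lb is the natural measure for increments on a
uniform background; Michelson contrast (L - Lb)/(L + Lb) is reported when
comparing with grating studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LuminancePair",
    "StimulusSpec",
    "weber_contrast",
    "michelson_contrast",
    "log_units_above_background",
    "TARGET_LUMINANCE",
    "CONTRAST_LUMINANCES",
    "STEP_BACKGROUND",
    "MODIFIED_STEP_BACKGROUND",
]

# Printed photometric design values, cd/m^2.
TARGET_LUMINANCE = 243.7
CONTRAST_LUMINANCES = {"low": 74.57, "medium": 124.66, "high": 243.7}
STEP_BACKGROUND = 60.0
MODIFIED_STEP_BACKGROUND = 30.7

_GROUPS = frozenset({"Equal", "Scaled"})
_ROLES = frozenset({"fixation", "target", "flash"})


@dataclass(frozen=True)
class LuminancePair:
    """Target and background luminance in cd/m^2; both must be positive."""

    target: float
    background: float

    def __post_init__(self) -> None:
        if self.target <= 0 or self.background <= 0:
            raise ValueError("luminances must be positive")


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus of the experimental design (position, size, luminance, role)."""

    eccentricity: float
    diameter: float
    luminance: float = TARGET_LUMINANCE
    group: str = "Equal"
    role: str = "target"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {sorted(_GROUPS)}")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {sorted(_ROLES)}")

    def to_dict(self) -> dict:
        return {
            "eccentricity_dva": self.eccentricity,
            "diameter_dva": self.diameter,
            "luminance_cd_m2": self.luminance,
            "group": self.group,
            "role": self.role,
        }


def weber_contrast(pair: LuminancePair) -> float:
    """(L - Lb) / Lb."""
    return (pair.target - pair.background) / pair.background


def michelson_contrast(pair: LuminancePair) -> float:
    """(L - Lb) / (L + Lb); in [0, 1] for an increment on a positive background."""
    denom = pair.target + pair.background
    if denom <= 0:
        raise ValueError("degenerate luminance sum")
    return (pair.target - pair.background) / denom


def log_units_above_background(pair: LuminancePair, convention: str = "weber") -> float:
    """Stimulus strength in log10 units above the background.

    The default convention is log10 of the Weber contrast; ``"ratio"``
    instead takes log10(L / Lb).
    """
    if convention == "weber":
        w = weber_contrast(pair)
        if w <= 0:
            raise ValueError("Weber contrast must be positive for log units")
        return math.log10(w)
    if convention == "ratio":
        return math.log10(pair.target / pair.background)
    raise ValueError(f"unknown convention {convention!r}")
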