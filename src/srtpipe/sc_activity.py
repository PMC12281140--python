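"""Collicular point-image activity model.

Stimulus discs on the horizontal meridian are projected through the foveal
magnification onto a 1-D SC tissue axis, giving a compact "afferent image"
whose length shrinks with eccentricity for fixed-size stimuli but stays
constant for extent-matched (Scaled) stimuli.  SC population activity is
modelled as the convolution of that afferent image with a homogeneous
Gaussian connectivity kernel: each neuron integrates afferent input under a
Gaussian weight of fixed tissue width, which corresponds to receptive
fields that grow with eccentricity in visual space.

Predictions exercised by the tests: equal-size stimuli evoke progressively
weaker peaks toward the periphery, extent-matched stimuli evoke equal peaks
everywhere, and the activated population width is set by the kernel (hence
nearly constant) whenever the stimulus image is small against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sc_map import ScalingSpec, collicular_x, scaled_diameter

__all__ = [
    "CollicularGrid",
    "AfferentInput",
    "ConnectivityKernel",
    "ActivityProfile",
    "make_grid",
    "project_stimulus",
    "compute_activity",
    "profile_summary",
    "stimulus_set_profiles",
]

DEFAULT_SPACING_MM = 0.005
DEFAULT_MAX_ECC_DVA = 15.0
DEFAULT_KERNEL_SIGMA_MM = 0.5


@dataclass(frozen=True)
class CollicularGrid:
    """Uniform 1-D discretization of the SC horizontal-meridian axis (mm)."""

    positions: np.ndarray
    spacing: float

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class AfferentInput:
    grid: CollicularGrid
    activity: np.ndarray  # nonnegative, per grid cell


@dataclass(frozen=True)
class ConnectivityKernel:
    """Homogeneous Gaussian connectivity function; width in mm of tissue."""

    width_sigma: float = DEFAULT_KERNEL_SIGMA_MM
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width_sigma <= 0:
            raise ValueError("kernel width must be positive")


@dataclass(frozen=True)
class ActivityProfile:
    grid: CollicularGrid
    activity: np.ndarray
    peak: float
    population_width: float  # FWHM in mm


def make_grid(
    spacing: float = DEFAULT_SPACING_MM,
    max_ecc: float = DEFAULT_MAX_ECC_DVA,
    pad_mm: float = 1.5,
) -> CollicularGrid:
    """Grid covering [0, X(max_ecc)] plus a pad so profile tails (and the
    half-max crossings of peripheral stimuli) stay inside the axis."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    extent = collicular_x(max_ecc) + pad_mm
    n = int(np.ceil(extent / spacing)) + 1
    return CollicularGrid(positions=np.arange(n) * spacing, spacing=spacing)


def project_stimulus(ecc: float, diameter: float, grid: CollicularGrid) -> AfferentInput:
    """Rasterize the SC image of a disc as a unit-height indicator.

    The image occupies [X(ecc - d/2), X(ecc + d/2)]; edge cells receive
    their fractional coverage so total image mass is exact regardless of
    where the interval falls relative to the grid (the images are only a
    handful of cells long).
    """
    if diameter < 0:
        raise ValueError("diameter must be nonnegative")
    act = np.zeros(len(grid))
    if diameter == 0:
        return AfferentInput(grid=grid, activity=act)
    if ecc - diameter / 2 <= 0:
        raise ValueError("stimulus extends across the fovea")
    lo = collicular_x(ecc - diameter / 2)
    hi = collicular_x(ecc + diameter / 2)
    h = grid.spacing
    cell_lo = grid.positions - h / 2
    cell_hi = grid.positions + h / 2
    overlap = np.clip(np.minimum(cell_hi, hi) - np.maximum(cell_lo, lo), 0.0, None)
    act = overlap / h
    return AfferentInput(grid=grid, activity=act)


def _gaussian_kernel(sigma: float, spacing: float) -> np.ndarray:
    half = int(np.ceil(5.0 * sigma / spacing))
    x = np.arange(-half, half + 1) * spacing
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def compute_activity(afferent: AfferentInput, kernel: ConnectivityKernel) -> ActivityProfile:
    """Convolve the afferent image with the normalized connectivity kernel."""
    grid = afferent.grid
    if kernel.width_sigma < 2 * grid.spacing:
        raise ValueError("kernel narrower than 2 grid steps is unresolvable")
    k = kernel.amplitude * _gaussian_kernel(kernel.width_sigma, grid.spacing)
    half = (len(k) - 1) // 2
    act = np.convolve(afferent.activity, k, mode="full")[half : half + len(grid)]
    peak = float(act.max())
    width = _fwhm_interp(grid.positions, act) if peak > 0 else 0.0
    return ActivityProfile(grid=grid, activity=act, peak=peak, population_width=width)


def _fwhm_interp(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM of a unimodal sampled profile by linear interpolation."""
    half = y.max() / 2.0
    i = int(np.argmax(y))
    above = y >= half
    # walk outward from the peak to the first sub-half samples
    l = i
    while l > 0 and above[l - 1]:
        l -= 1
    r = i
    while r < len(y) - 1 and above[r + 1]:
        r += 1
    if l == 0 or r == len(y) - 1:
        raise ValueError("profile does not fall below half max inside the grid")
    xl = x[l - 1] + (x[l] - x[l - 1]) * (half - y[l - 1]) / (y[l] - y[l - 1])
    xr = x[r] + (x[r + 1] - x[r]) * (half - y[r]) / (y[r + 1] - y[r])
    return float(xr - xl)


def profile_summary(profile: ActivityProfile) -> tuple[float, float]:
    """(peak, population FWHM) of a nonzero activity profile."""
    if profile.peak <= 0:
        raise ValueError("all-zero activity profile")
    return profile.peak, profile.population_width


def stimulus_set_profiles(
    eccentricities: tuple[float, ...] = (2, 3, 4, 5, 6, 8, 10),
    stimulus_set: str = "Equal",
    kernel: ConnectivityKernel = ConnectivityKernel(),
    grid: CollicularGrid | None = None,
) -> list[ActivityProfile]:
    """Activity profiles for the Equal (fixed 0.1 dva) or Scaled stimulus set.

    The Scaled set uses the unrounded extent-matched diameters, i.e. the
    constant-point-image construction itself rather than the 2-dp stimulus
    table, so its peaks are equal up to grid resolution.
    """
    if grid is None:
        grid = make_grid()
    profiles = []
    unrounded = ScalingSpec(rounding=None)
    for ecc in eccentricities:
        if stimulus_set == "Equal":
            d = 0.1
        elif stimulus_set == "Scaled":
            d = scaled_diameter(ecc, unrounded)
        else:
            raise ValueError(f"unknown stimulus set {stimulus_set!r}")
        profiles.append(compute_activity(project_stimulus(ecc, d, grid), kernel))
    return profiles
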