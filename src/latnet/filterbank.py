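"""Parameterized V1-like basis filters.

The basis emulates simple-cell receptive fields measured in mouse primary
visual cortex: single-subfield ON and OFF cells plus two-subfield ON/OFF
cells in which one subfield dominates.  Each subfield is an isotropic 2-D
Gaussian; two-subfield cells place the stronger subfield at +separation/2
and the weaker (half amplitude, opposite sign) at -separation/2 along an
axis whose direction steps through 0..315 deg in 45-deg increments.  The
default construction yields 18 filters: 1 ON + 1 OFF + 8 strong-ON + 8
strong-OFF.

A filter's *preferred orientation* (the orientation of an edge it responds
to best) is the axis orthogonal to the subfield-separation axis, defined
modulo 180 deg.  Single-subfield filters are unoriented (NaN).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubfieldSpec",
    "FilterBank",
    "build_v1_basis",
    "build_gabor_bank",
    "effective_filter_radius",
]

logger = logging.getLogger(__name__)

#: filter class labels
ON = "ON"
OFF = "OFF"
ONOFF_STRONG_ON = "ONOFF_strongON"
ONOFF_STRONG_OFF = "ONOFF_strongOFF"


@dataclass(frozen=True)
class SubfieldSpec:
    """One Gaussian subfield of a receptive field.

    Parameters
    ----------
    polarity : {"ON", "OFF"}
        Sign of the subfield (ON is positive, OFF negative).
    sigma : float
        Standard deviation of the isotropic Gaussian, in degrees.
    amplitude : float
        Peak absolute amplitude (dimensionless, > 0).
    center : (float, float)
        (x, y) offset of the subfield center from the filter center,
        in degrees; x rightward, y downward.
    """

    polarity: str
    sigma: float
    amplitude: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.polarity not in (ON, OFF):
            raise ValueError(f"polarity must be ON or OFF, got {self.polarity!r}")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")

    def render(self, grid_size: int, deg_per_px: float) -> np.ndarray:
        """Evaluate the signed Gaussian on an odd square pixel grid."""
        half = grid_size // 2
        coords = (np.arange(grid_size) - half) * deg_per_px
        xx, yy = np.meshgrid(coords, coords)  # row index = y (downward)
        cx, cy = self.center
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        g = self.amplitude * np.exp(-d2 / (2.0 * self.sigma**2))
        return g if self.polarity == ON else -g


@dataclass
class FilterBank:
    """A set of 2-D spatial filters with per-filter metadata.

    Attributes
    ----------
    filters : (n_filters, grid, grid) ndarray
        Filter kernels on an odd square pixel grid.
    classes : list of str
        Per-filter class label.
    relative_orientation : (n_filters,) ndarray
        Direction (deg, 0..315) of the stronger subfield's displacement for
        two-subfield filters; NaN for single-subfield ones.
    preferred_orientation : (n_filters,) ndarray
        Edge orientation (deg, mod 180) the filter prefers; NaN if
        unoriented.
    deg_per_px : float
        Spatial scale of the grid.
    """

    filters: np.ndarray
    classes: list[str]
    relative_orientation: np.ndarray
    preferred_orientation: np.ndarray
    deg_per_px: float
    name: str = "v1"
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.filters.shape[0]

    @property
    def grid_size(self) -> int:
        return self.filters.shape[1]

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    def oriented_mask(self) -> np.ndarray:
        """Boolean mask of filters with a defined preferred orientation."""
        return ~np.isnan(self.preferred_orientation)


def _check_grid(grid_size: int) -> None:
    if grid_size % 2 == 0 or grid_size < 1:
        raise ValueError(f"grid_size must be odd and positive, got {grid_size}")


def _off_grid_warning(spec: SubfieldSpec, grid_size: int, deg_per_px: float) -> None:
    half_extent = (grid_size // 2) * deg_per_px
    cx, cy = spec.center
    if max(abs(cx), abs(cy)) > half_extent:
        logger.warning(
            "subfield center %s deg falls outside the %dx%d grid (half-extent %.2f deg)",
            spec.center, grid_size, grid_size, half_extent,
        )


def build_v1_basis(
    grid_size: int = 15,
    deg_per_px: float = 1.0,
    sigma_on: float = 0.5 * 4.2,
    sigma_off: float = 0.5 * 4.8,
    separation: float = 5.0,
    weak_amp_ratio: float = 0.5,
) -> FilterBank:
    """Build the default 18-filter simple-cell basis.

    Subfield sigmas default to half the measured average subfield sizes
    (4.2 deg ON, 4.8 deg OFF); the two subfields of ON/OFF cells sit 5 deg
    apart, weaker subfield at half the stronger one's amplitude.  Subfields
    combine additively on a zero background; no post-hoc normalization.

    Returns a :class:`FilterBank` with 1 ON + 1 OFF + 8 strong-ON + 8
    strong-OFF filters at default parameters.
    """
    _check_grid(grid_size)
    if deg_per_px <= 0:
        raise ValueError("deg_per_px must be positive")

    filters: list[np.ndarray] = []
    classes: list[str] = []
    rel_ori: list[float] = []
    pref_ori: list[float] = []

    def add(subfields: list[SubfieldSpec], cls: str, rel: float) -> None:
        for sf in subfields:
            _off_grid_warning(sf, grid_size, deg_per_px)
        kern = sum(sf.render(grid_size, deg_per_px) for sf in subfields)
        filters.append(kern)
        classes.append(cls)
        rel_ori.append(rel)
        pref_ori.append((rel + 90.0) % 180.0 if not math.isnan(rel) else math.nan)

    # single-subfield cells
    add([SubfieldSpec(ON, sigma_on, 1.0)], ON, math.nan)
    add([SubfieldSpec(OFF, sigma_off, 1.0)], OFF, math.nan)

    # two-subfield cells: stronger subfield displaced +separation/2 along
    # the axis at angle theta, weaker at -separation/2
    for cls in (ONOFF_STRONG_ON, ONOFF_STRONG_OFF):
        strong_on = cls == ONOFF_STRONG_ON
        for theta in np.arange(0.0, 360.0, 45.0):
            rad = math.radians(theta)
            dx, dy = math.cos(rad), math.sin(rad)
            c_strong = (0.5 * separation * dx, 0.5 * separation * dy)
            c_weak = (-0.5 * separation * dx, -0.5 * separation * dy)
            if strong_on:
                subs = [
                    SubfieldSpec(ON, sigma_on, 1.0, c_strong),
                    SubfieldSpec(OFF, sigma_off, weak_amp_ratio, c_weak),
                ]
            else:
                subs = [
                    SubfieldSpec(OFF, sigma_off, 1.0, c_strong),
                    SubfieldSpec(ON, sigma_on, weak_amp_ratio, c_weak),
                ]
            add(subs, cls, float(theta))

    return FilterBank(
        filters=np.stack(filters),
        classes=classes,
        relative_orientation=np.array(rel_ori),
        preferred_orientation=np.array(pref_ori),
        deg_per_px=deg_per_px,
        name="v1",
        params=dict(
            grid_size=grid_size, deg_per_px=deg_per_px, sigma_on=sigma_on,
            sigma_off=sigma_off, separation=separation,
            weak_amp_ratio=weak_amp_ratio,
        ),
    )


def build_gabor_bank(
    grid_size: int = 15,
    deg_per_px: float = 1.0,
    wavelengths: tuple[float, ...] = (8.0,),
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    phases: tuple[float, ...] = (0.0, 90.0),
    envelope_sigma: float = 3.0,
) -> FilterBank:
    """Build a standard Gabor bank (cosine carrier x Gaussian envelope).

    One filter per (wavelength, orientation, phase) combination.  The
    carrier varies along the axis orthogonal to `orientation`, so the
    filter's preferred edge orientation equals `orientation`.
    """
    _check_grid(grid_size)
    if not (wavelengths and orientations and phases):
        raise ValueError("each parameter list needs at least one value")
    for lam in wavelengths:
        if lam <= 2.0 * deg_per_px:
            raise ValueError(
                f"wavelength {lam} <= 2*deg_per_px={2 * deg_per_px}: aliased"
            )

    half = grid_size // 2
    coords = (np.arange(grid_size) - half) * deg_per_px
    xx, yy = np.meshgrid(coords, coords)

    filters, classes, rel_ori, pref_ori = [], [], [], []
    for lam in wavelengths:
        for theta in orientations:
            rad = math.radians(theta)
            # carrier axis orthogonal to the preferred edge orientation
            u = xx * math.sin(rad) + yy * math.cos(rad)
            env = np.exp(-(xx**2 + yy**2) / (2.0 * envelope_sigma**2))
            for phase in phases:
                kern = env * np.cos(2.0 * math.pi * u / lam + math.radians(phase))
                filters.append(kern)
                classes.append("gabor")
                rel_ori.append(float(theta))
                pref_ori.append(float(theta) % 180.0)

    return FilterBank(
        filters=np.stack(filters),
        classes=classes,
        relative_orientation=np.array(rel_ori),
        preferred_orientation=np.array(pref_ori),
        deg_per_px=deg_per_px,
        name="gabor",
        params=dict(
            grid_size=grid_size, deg_per_px=deg_per_px,
            wavelengths=list(wavelengths), orientations=list(orientations),
            phases=list(phases), envelope_sigma=envelope_sigma,
        ),
    )


def effective_filter_radius(bank: FilterBank, threshold_frac: float = 0.05) -> float:
    """Mean effective radius (degrees) of a bank's filters.

    Per filter, pixels with |intensity| above ``threshold_frac`` times the
    filter's maximum |intensity| contribute area ``A`` (pixel count times
    deg_per_px^2); the effective radius is ``sqrt(A / pi)``.  Returns the
    mean radius over the bank.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    if bank.n_filters == 0:
        raise ValueError("empty filter bank")
    radii = []
    px_area = bank.deg_per_px**2
    for kern in bank.filters:
        mag = np.abs(kern)
        area = np.count_nonzero(mag > threshold_frac * mag.max()) * px_area
        radii.append(math.sqrt(area / math.pi))
    return float(np.mean(radii))
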