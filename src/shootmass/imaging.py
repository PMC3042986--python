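"""Projected shoot area from three-view plant images.

High-throughput phenotyping platforms photograph each plant from three
orthogonal positions (one top view, two side views 90° apart) against a
roughly uniform blue background.  The shoot is separated from the background
in hue space: the RGB image is converted to the hue-saturation-intensity
(HSI) colour model, pixels whose hue falls in a green band (and whose
saturation clears a small floor) are classed as plant, the plant pixels are
counted per view, converted to mm² with a per-view calibration factor, and
the three calibrated areas are summed into the *projected shoot area* — the
area covariate of the biomass models in :mod:`shootmass.models`.

The HSI transform is the classic inverse-cosine definition:

    I = (R + G + B) / 3
    S = 1 - min(R, G, B) / I                     (0 for black pixels)
    H = theta            if B <= G
        360° - theta     if B > G

with theta = arccos( ((R-G) + (R-B)) / 2 / sqrt((R-G)² + (R-B)(G-B)) ).
Achromatic pixels (S = 0) are assigned hue 0 by convention.  Green foliage
sits near 120°, the blue screen near 240°, so a hue band such as the default
[60°, 180°] cleanly separates the two.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from skimage import morphology
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, InputError

__all__ = [
    "VIEW_NAMES",
    "HSIImage",
    "ViewTriplet",
    "ProjectedShootArea",
    "rgb_to_hsi",
    "segment_by_hue",
    "count_plant_pixels",
    "projected_shoot_area",
    "HsiSegmenter",
    "DEFAULT_PLANT_BAND",
    "DEFAULT_SATURATION_FLOOR",
]

VIEW_NAMES = ("top", "side0", "side90")

#: Default hue interval (degrees) classed as plant: green foliage vs. blue screen.
DEFAULT_PLANT_BAND = (60.0, 180.0)
#: Default saturation floor rejecting near-achromatic pixels whose hue is noise.
DEFAULT_SATURATION_FLOOR = 0.15


@dataclasses.dataclass(frozen=True)
class HSIImage:
    """Per-pixel hue (degrees, [0, 360)), saturation and intensity (both [0, 1])."""

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if not (self.hue.shape == self.saturation.shape == self.intensity.shape):
            raise InputError("hue, saturation and intensity must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.hue.shape


@dataclasses.dataclass(frozen=True)
class ViewTriplet:
    """The three views of one plant plus mm²-per-pixel calibration per view.

    Calibration factors differ between top and side cameras (different
    working distances), so each view carries its own positive factor.
    """

    top: np.ndarray
    side0: np.ndarray
    side90: np.ndarray
    calibration: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.calibration) != len(VIEW_NAMES):
            raise ConfigurationError("calibration needs one factor per view")
        if any(not np.isfinite(c) or c <= 0 for c in self.calibration):
            raise ConfigurationError("calibration factors must be positive")

    def view(self, name: str) -> np.ndarray:
        try:
            return {"top": self.top, "side0": self.side0, "side90": self.side90}[name]
        except KeyError:
            raise InputError(f"unknown view {name!r}; expected one of {VIEW_NAMES}") from None

    def calibration_for(self, name: str) -> float:
        return self.calibration[VIEW_NAMES.index(name)]


@dataclasses.dataclass(frozen=True)
class ProjectedShootArea:
    """Per-view pixel counts and calibrated areas; ``total_mm2`` is their sum."""

    per_view_pixels: dict[str, int]
    per_view_mm2: dict[str, float]
    total_mm2: float


def _as_rgb_array(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise InputError(f"expected an RGB array of shape (H, W, 3), got {arr.shape}")
    return arr.astype(np.float64)


def rgb_to_hsi(img: np.ndarray) -> HSIImage:
    """Convert an 8-bit RGB image to the HSI colour model.

    Parameters
    ----------
    img : ndarray of shape (H, W, 3)
        Channel intensities in [0, 255].

    Returns
    -------
    HSIImage with hue in degrees [0, 360), saturation and intensity in [0, 1].
    """
    arr = _as_rgb_array(img) / 255.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    intensity = total / 3.0

    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(den > 0, num / den, 1.0)
    theta = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(saturation > 0, hue, 0.0) % 360.0
    return HSIImage(hue=hue, saturation=np.clip(saturation, 0.0, 1.0), intensity=intensity)


def _normalize_band(plant_band) -> list[tuple[float, float]]:
    if plant_band is None:
        raise ConfigurationError("plant_band must not be empty")
    band = list(plant_band)
    if not band:
        raise ConfigurationError("plant_band must not be empty")
    if np.isscalar(band[0]):
        band = [tuple(band)]
    intervals: list[tuple[float, float]] = []
    for iv in band:
        if len(iv) != 2:
            raise ConfigurationError(f"hue interval must be (low, high), got {iv!r}")
        lo, hi = float(iv[0]), float(iv[1])
        if not (0.0 <= lo < 360.0) or not (0.0 <= hi <= 360.0):
            raise ConfigurationError(f"hue bounds must lie in [0, 360), got {iv!r}")
        intervals.append((lo, hi))
    return intervals


def segment_by_hue(
    hsi: HSIImage,
    plant_band=DEFAULT_PLANT_BAND,
    saturation_floor: float = DEFAULT_SATURATION_FLOOR,
    min_object_size: int = 0,
) -> np.ndarray:
    """Threshold the hue image into a boolean plant mask.

    A pixel is plant iff its hue lies inside ``plant_band`` (one interval or a
    sequence of intervals, degrees; an interval with low > high wraps through
    0°) and its saturation is at least ``saturation_floor``.  Optionally,
    connected plant components smaller than ``min_object_size`` pixels are
    dropped (off by default — the imaging protocol assumes a clean blue
    screen, so no morphological cleanup is applied unless requested).
    """
    intervals = _normalize_band(plant_band)
    if not 0.0 <= saturation_floor <= 1.0:
        raise ConfigurationError("saturation_floor must lie in [0, 1]")
    hue = hsi.hue
    mask = np.zeros(hue.shape, dtype=bool)
    for lo, hi in intervals:
        if lo <= hi:
            mask |= (hue >= lo) & (hue <= hi)
        else:  # wrap-around interval, e.g. (330, 30)
            mask |= (hue >= lo) | (hue <= hi)
    if saturation_floor > 0:
        mask &= hsi.saturation >= saturation_floor
    if min_object_size > 0:
        mask = morphology.remove_small_objects(mask, min_size=int(min_object_size))
    return mask


def count_plant_pixels(mask: np.ndarray) -> int:
    """Number of plant-classified pixels in a boolean mask."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        raise InputError("mask must be boolean")
    return int(arr.sum())


def projected_shoot_area(
    views: ViewTriplet,
    plant_band=DEFAULT_PLANT_BAND,
    saturation_floor: float = DEFAULT_SATURATION_FLOOR,
    view_subset: Sequence[str] | None = None,
    min_object_size: int = 0,
) -> ProjectedShootArea:
    """Segment, count and calibrate each selected view; sum into total mm².

    ``view_subset`` defaults to all three views.  Passing
    ``("side0", "side90")`` reproduces the two-side-only variant (the top
    view normally corrects for leaves hidden behind one another in the side
    views, so dropping it is expected to degrade accuracy slightly).
    """
    subset = tuple(view_subset) if view_subset is not None else VIEW_NAMES
    if not subset:
        raise InputError("view_subset must not be empty")
    per_pixels: dict[str, int] = {}
    per_mm2: dict[str, float] = {}
    for name in subset:
        img = views.view(name)
        mask = segment_by_hue(
            rgb_to_hsi(img), plant_band, saturation_floor, min_object_size
        )
        n = count_plant_pixels(mask)
        per_pixels[name] = n
        per_mm2[name] = n * views.calibration_for(name)
    return ProjectedShootArea(
        per_view_pixels=per_pixels,
        per_view_mm2=per_mm2,
        total_mm2=float(sum(per_mm2.values())),
    )


class HsiSegmenter(TransformerMixin, BaseEstimator):
    """Stateless hue-band plant segmenter with a sklearn transformer surface.

    Parameters
    ----------
    plant_band : (low, high) or sequence of (low, high), degrees
        Hue interval(s) classed as plant.
    saturation_floor : float in [0, 1]
        Minimum saturation for a pixel to count as plant.
    min_object_size : int
        If positive, remove connected plant components smaller than this.

    ``transform`` maps one RGB array (H, W, 3) to a boolean mask, or a list
    of RGB arrays to a list of masks.  ``fit`` only validates parameters.
    """

    def __init__(
        self,
        plant_band=DEFAULT_PLANT_BAND,
        saturation_floor: float = DEFAULT_SATURATION_FLOOR,
        min_object_size: int = 0,
    ):
        self.plant_band = plant_band
        self.saturation_floor = saturation_floor
        self.min_object_size = min_object_size

    def fit(self, X=None, y=None) -> "HsiSegmenter":
        _normalize_band(self.plant_band)
        if not 0.0 <= self.saturation_floor <= 1.0:
            raise ConfigurationError("saturation_floor must lie in [0, 1]")
        self.n_features_in_ = 3  # RGB channels
        return self

    def _segment_one(self, img: np.ndarray) -> np.ndarray:
        return segment_by_hue(
            rgb_to_hsi(img),
            self.plant_band,
            self.saturation_floor,
            self.min_object_size,
        )

    def transform(self, X):
        self.fit()
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return self._segment_one(X)
        if isinstance(X, Iterable):
            return [self._segment_one(np.asarray(img)) for img in X]
        raise InputError("X must be an RGB array or an iterable of RGB arrays")
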