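"""DWI container and pre-fit reduction steps.

A raw acquisition holds one magnitude volume per b value and gradient
direction.  Before model fitting the direction axis is averaged out, the
series is spatially smoothed, and each voxel's decay curve is expressed as a
fraction of its own b=0 signal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: converts a full-width-at-half-maximum to a Gaussian standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def validate_b_values(b_values: np.ndarray) -> np.ndarray:
    """Check a b-value schedule: non-negative, strictly increasing, starts at 0."""
    b = np.asarray(b_values, dtype=float)
    if b.ndim != 1 or b.size < 2:
        raise ValueError("b-value schedule must be a 1-D sequence of at least 2 values")
    if np.any(b < 0):
        raise ValueError("b values must be non-negative")
    if np.any(np.diff(b) <= 0):
        raise ValueError("b values must be strictly increasing")
    if b[0] != 0:
        raise ValueError("b-value schedule must start at b=0")
    return b


@dataclass
class DWISeries:
    """A diffusion-weighted series on a voxel grid.

    ``signal`` is ``(X, Y, Z, B)`` after direction averaging, or
    ``(X, Y, Z, B, n_directions)`` for raw multi-direction data.  Values are
    magnitude data and therefore non-negative.
    """

    signal: np.ndarray
    b_values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    brain_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.b_values = validate_b_values(self.b_values)
        if self.signal.ndim not in (4, 5):
            raise ValueError("signal must be 4-D (x,y,z,b) or 5-D (x,y,z,b,direction)")
        if self.signal.shape[3] != self.b_values.size:
            raise ValueError(
                f"b axis length {self.signal.shape[3]} does not match schedule "
                f"length {self.b_values.size}"
            )
        if np.nanmin(self.signal) < 0:
            raise ValueError("magnitude DWI signal must be non-negative")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive floats")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.signal.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.signal.shape[:3]:
                raise ValueError("brain_mask shape does not match the spatial grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def has_directions(self) -> bool:
        return self.signal.ndim == 5


def average_directions(dwi: DWISeries) -> DWISeries:
    """Arithmetic mean over the gradient-direction axis."""
    if not dwi.has_directions:
        raise ValueError("series has no direction axis to average")
    if dwi.signal.shape[4] < 1:
        raise ValueError("direction axis is empty")
    return replace(dwi, signal=dwi.signal.mean(axis=4))


def normalize_to_b0(dwi: DWISeries) -> DWISeries:
    """Divide each voxel's series by its own b=0 signal.

    Voxels whose b=0 signal is not strictly positive cannot be normalized;
    they are dropped from the brain mask (logged) rather than raising.  On a
    multi-direction series each direction is divided by its own b=0 volume.
    """
    if dwi.has_directions:
        b0 = dwi.signal[..., 0, :]                      # (x, y, z, dir)
        ok = np.all(b0 > 0, axis=-1)
        div = b0[..., None, :]
    else:
        b0 = dwi.signal[..., 0]
        ok = b0 > 0
        div = b0[..., None]
    dropped = int(np.count_nonzero(dwi.brain_mask & ~ok))
    if dropped:
        logger.warning("normalize_to_b0: dropping %d voxels with non-positive b=0 signal", dropped)
    out = np.zeros_like(dwi.signal)
    np.divide(dwi.signal, div, out=out, where=div > 0)
    return replace(dwi, signal=out, brain_mask=dwi.brain_mask & ok)


def gaussian_smooth(
    data: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float],
    mode: str = "nearest",
) -> np.ndarray:
    """Separable spatial Gaussian smoothing of a 3-D map or 4-D series.

    The kernel width is ``fwhm_mm`` in every spatial direction; anisotropic
    voxels get per-axis widths in voxel units.  ``fwhm_mm = 0`` is the
    identity.  Boundary handling replicates edge voxels (``nearest``) so a
    constant field passes through unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    arr = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return arr.copy()
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm]
    if arr.ndim == 3:
        return ndimage.gaussian_filter(arr, sigma=sigma_vox, mode=mode)
    # smooth each trailing volume independently
    sigma = sigma_vox + [0.0] * (arr.ndim - 3)
    return ndimage.gaussian_filter(arr, sigma=sigma, mode=mode)


def gaussian_smooth_masked(
    map3d: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float],
    mask: np.ndarray,
) -> np.ndarray:
    """Normalized-convolution smoothing of a map with invalid (NaN) voxels.

    Valid voxels are weighted by the smoothed mask so NaNs neither propagate
    nor darken the neighbourhood; output stays NaN outside the mask.
    """
    m = np.asarray(mask, dtype=bool) & np.isfinite(map3d)
    filled = np.where(m, map3d, 0.0)
    num = gaussian_smooth(filled, fwhm_mm, voxel_size_mm)
    den = gaussian_smooth(m.astype(float), fwhm_mm, voxel_size_mm)
    out = np.full_like(num, np.nan)
    np.divide(num, den, out=out, where=m & (den > 0))
    return out


def smooth_series(dwi: DWISeries, fwhm_mm: float) -> DWISeries:
    """Spatially smooth every b-value (and direction) volume of a series."""
    return replace(dwi, signal=gaussian_smooth(dwi.signal, fwhm_mm, dwi.voxel_size_mm))


def preprocess_series(
    dwi: DWISeries,
    fwhm_mm: float = 8.0,
    order: str = "smooth_then_fit",
) -> DWISeries:
    """Standard reduction: average directions, smooth, normalize to b=0.

    ``order="fit_then_smooth"`` skips the series smoothing here so that maps
    can be smoothed after fitting instead (sensitivity-analysis path).
    """
    if order not in ("smooth_then_fit", "fit_then_smooth"):
        raise ValueError(f"unknown processing order {order!r}")
    out = average_directions(dwi) if dwi.has_directions else dwi
    if order == "smooth_then_fit":
        out = smooth_series(out, fwhm_mm)
    return normalize_to_b0(out)
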