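"""Leaf ROI segmentation, mean-spectrum extraction and spectral noise QC.

The ROI is found by thresholding the band nearest 800 nm, where leaf
tissue (high NIR plateau) and background contrast most strongly, and
keeping the largest connected component.  The per-leaf spectrum is the
arithmetic mean over ROI pixels.  The noise metric is the deviation
between a raw spectrum and its Savitzky-Golay smoothing, summarised as
an RMS over an analysis window (400-700 nm by default) — large values
in 400-500 nm flag the poor blue-region SNR of halogen-only lighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from skimage.measure import label as cc_label

from .envi import HyperCube

__all__ = [
    "LeafSample",
    "NoiseReport",
    "SegmentationError",
    "segment_roi",
    "mean_spectrum",
    "sg_deviation",
]

MIN_ROI_PIXELS = 50
SEGMENTATION_BAND_NM = 800.0
DEFAULT_THRESHOLD = 0.35
MAX_LEAF_FRACTION = 0.9  # sanity bound: a leaf should not fill the frame


class SegmentationError(ValueError):
    pass


@dataclass
class LeafSample:
    """One leaf: ROI mask, mean spectrum and experimental metadata."""

    mask: np.ndarray
    spectrum: np.ndarray
    stage: str
    treatment: int
    plant_id: int
    replicate_idx: int


@dataclass
class NoiseReport:
    """Savitzky-Golay deviation series and its RMS over a window."""

    deviation: np.ndarray
    wavelengths: np.ndarray
    rms: float
    window: tuple[float, float]


def segment_roi(cube: HyperCube, threshold: float = DEFAULT_THRESHOLD,
                band_nm: float = SEGMENTATION_BAND_NM,
                min_pixels: int = MIN_ROI_PIXELS) -> np.ndarray:
    """Threshold the band nearest ``band_nm``, keep the largest component."""
    band = cube.data[:, :, cube.band_index(band_nm)]
    fg = band > threshold
    if not fg.any():
        raise SegmentationError(
            f"no pixel exceeds threshold {threshold} at {band_nm} nm; empty mask"
        )
    labels = cc_label(fg)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    frac = mask.mean()
    if frac > MAX_LEAF_FRACTION:
        warnings.warn(
            f"segmented ROI covers {frac:.0%} of the frame; threshold {threshold} "
            "is likely too low", stacklevel=2)
    if mask.sum() < min_pixels:
        raise SegmentationError(
            f"largest component has {int(mask.sum())} px < min_pixels={min_pixels}"
        )
    return mask


def mean_spectrum(cube: HyperCube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of reflectance over ``mask`` pixels."""
    if mask.shape != cube.data.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} != frame {cube.data.shape[:2]}")
    if not mask.any():
        raise SegmentationError("cannot average over an empty mask")
    return cube.data[mask].mean(axis=0).astype(np.float64)


def sg_deviation(spectrum: np.ndarray, wavelengths: np.ndarray,
                 window_nm: tuple[float, float] = (400.0, 700.0),
                 sg_window: int = 11, sg_order: int = 2) -> NoiseReport:
    """Raw-minus-smoothed deviation restricted to ``window_nm`` and its RMS."""
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError(f"sg_window must be odd and > sg_order, got {sg_window}, {sg_order}")
    wavelengths = np.asarray(wavelengths, dtype=float)
    if window_nm[0] < wavelengths[0] - 1e-9 or window_nm[1] > wavelengths[-1] + 1e-9:
        raise ValueError(
            f"analysis window {window_nm} lies outside the wavelength range "
            f"({wavelengths[0]:.0f}-{wavelengths[-1]:.0f} nm)"
        )
    smooth = savgol_filter(np.asarray(spectrum, dtype=float), sg_window, sg_order)
    dev = np.asarray(spectrum, dtype=float) - smooth
    sel = (wavelengths >= window_nm[0]) & (wavelengths <= window_nm[1])
    dev_w = dev[sel]
    return NoiseReport(
        deviation=dev_w,
        wavelengths=wavelengths[sel],
        rms=float(np.sqrt(np.mean(dev_w**2))),
        window=tuple(window_nm),
    )
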