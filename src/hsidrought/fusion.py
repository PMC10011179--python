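"""Spectroscopy-image combination and young/mature subsample fusion.

*Combination* standardises the EW-spectrum block and the CNN
image-feature block separately (statistics fitted on the calibration
set only, so the two blocks are commensurate) and concatenates them,
spectral block first.  *Fusion* concatenates the combined vectors of a
young leaf and the mature leaf from the same plant and replicate into a
single multi-stage sample sharing one treatment label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .envi import HyperCube
from .ris import RIS

__all__ = [
    "FeatureVector",
    "FusedSample",
    "PairingError",
    "make_ris_stack",
    "BlockStandardizer",
    "combine",
    "fuse",
]


class PairingError(ValueError):
    pass


@dataclass
class FeatureVector:
    """Per-leaf feature vector: standardized EW spectra then image features."""

    spectral: np.ndarray
    image: np.ndarray
    stage: str
    label: int
    plant_id: int
    replicate_idx: int

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.spectral, self.image])

    def __post_init__(self) -> None:
        self.spectral = np.asarray(self.spectral, dtype=float)
        self.image = np.asarray(self.image, dtype=float)
        if not (np.all(np.isfinite(self.spectral)) and np.all(np.isfinite(self.image))):
            raise ValueError("feature vectors must be finite")


@dataclass
class FusedSample:
    """Young-then-mature concatenation for one (plant, replicate)."""

    vector: np.ndarray
    label: int
    plant_id: int
    replicate_idx: int


def make_ris_stack(cube: HyperCube, mask: np.ndarray, ris: RIS | list[float],
                   out_hw: int = 32) -> np.ndarray:
    """Crop the ROI bounding box of each RIS band into a CNN input stack.

    Background pixels are zeroed by the mask before cropping; each band
    is bilinearly resized to ``out_hw`` x ``out_hw``.  Channels follow
    the RIS order (reference image first).
    """
    wls = ris.wavelengths if isinstance(ris, RIS) else list(ris)
    spacing = np.min(np.diff(cube.wavelengths)) if cube.n_bands > 1 else np.inf
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    if not rows.any():
        raise ValueError("empty mask: nothing to crop")
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    channels = []
    for wl in wls:
        b = cube.band_index(wl)
        if abs(cube.wavelengths[b] - wl) > spacing:
            raise ValueError(f"RIS wavelength {wl} nm not present in cube")
        img = cube.data[:, :, b] * mask
        crop = img[r0 : r1 + 1, c0 : c1 + 1].astype(np.float64)
        channels.append(resize(crop, (out_hw, out_hw), order=1, mode="edge",
                               anti_aliasing=False, preserve_range=True))
    return np.stack(channels, axis=0)


class BlockStandardizer:
    """Per-coordinate standardisation fitted on the calibration set.

    Zero-variance coordinates are mapped to 0 and flagged in
    ``qc_zero_variance_``.
    """

    def fit(self, X: np.ndarray) -> "BlockStandardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.qc_zero_variance_ = [int(i) for i in np.flatnonzero(sd == 0)]
        if self.qc_zero_variance_:
            warnings.warn(
                f"{len(self.qc_zero_variance_)} zero-variance feature(s) standardized to 0",
                stacklevel=2)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        if self.qc_zero_variance_:
            Z[:, self.qc_zero_variance_] = 0.0
        return Z


def combine(spectral: np.ndarray, image_features: np.ndarray,
            spectral_scaler: BlockStandardizer | None = None,
            image_scaler: BlockStandardizer | None = None) -> np.ndarray:
    """Concatenate (standardized) spectral and image blocks, spectral first.

    Pass scalers fitted on the calibration set; ``None`` means the block
    is used as-is (already standardized or deliberately raw).
    """
    spectral = np.atleast_2d(np.asarray(spectral, dtype=float))
    image_features = np.atleast_2d(np.asarray(image_features, dtype=float))
    if spectral_scaler is not None:
        spectral = spectral_scaler.transform(spectral)
    if image_scaler is not None:
        image_features = image_scaler.transform(image_features)
    if image_features.size == 0:
        return spectral
    return np.hstack([spectral, image_features])


def fuse(young: FeatureVector, mature: FeatureVector) -> FusedSample:
    """Concatenate a young/mature pair into one sample (young block first)."""
    if young.stage != "young" or mature.stage != "mature":
        raise PairingError(f"expected a (young, mature) pair, got ({young.stage}, {mature.stage})")
    for attr in ("plant_id", "replicate_idx", "label"):
        a, b = getattr(young, attr), getattr(mature, attr)
        if a != b:
            raise PairingError(f"{attr} mismatch between pair halves: {a} != {b}")
    return FusedSample(
        vector=np.concatenate([young.vector, mature.vector]),
        label=young.label, plant_id=young.plant_id, replicate_idx=young.replicate_idx,
    )
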