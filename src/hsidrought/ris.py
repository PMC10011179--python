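"""Reflectance-image-set (RIS) selection.

The RIS supplies the CNN's input channels: the EW band image with the
highest ReliefF weight (the *reference image*) plus up to four further
EW band images that are weakly correlated (|r| <= 0.3) both with the
reference and with each other.  Candidates are admitted by a greedy
container scan over Pearson correlations between in-leaf pixel values,
ranked by |r| against the reference, then superposed one by one; the
stack depth k that maximises the downstream spectra-plus-image-features
classification accuracy fixes the final RIS (ties favour fewer images).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .envi import HyperCube

__all__ = [
    "CorrMatrix",
    "RIS",
    "image_correlation",
    "average_image_correlation",
    "greedy_container",
    "superposition_search",
    "write_corr_heatmap",
]

CORR_THRESHOLD = 0.3
MAX_MEMBERS = 4


@dataclass
class CorrMatrix:
    """Pearson correlations between EW band images (diagonal 1, symmetric)."""

    r: np.ndarray
    wavelengths: np.ndarray
    qc_zero_variance: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")


@dataclass
class RIS:
    """Ordered image-set wavelengths, reference first."""

    reference_wl: float
    member_wls: list[float]
    accuracy_trace: list[float] = field(default_factory=list)

    @property
    def wavelengths(self) -> list[float]:
        return [self.reference_wl] + list(self.member_wls)

    @property
    def k_selected(self) -> int:
        return 1 + len(self.member_wls)

    def to_dict(self) -> dict:
        return {
            "reference_wl": float(self.reference_wl),
            "member_wls": [float(w) for w in self.member_wls],
            "k_selected": self.k_selected,
            "accuracy_trace": [float(a) for a in self.accuracy_trace],
        }


def image_correlation(cube: HyperCube, mask: np.ndarray,
                      ew_indices: Sequence[int]) -> CorrMatrix:
    """Pearson r between the in-mask pixel vectors of each EW band pair.

    A zero-variance band image yields undefined correlations; these are
    recorded as 0 and the band flagged in ``qc_zero_variance``.
    """
    ew_indices = np.asarray(ew_indices, dtype=int)
    if mask.sum() < 2:
        raise ValueError("correlation needs at least 2 in-mask pixels")
    V = cube.data[mask][:, ew_indices].astype(np.float64)  # (n_px, k)
    sd = V.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (V - V.mean(axis=0)) / sd_safe
    r = (Z.T @ Z) / V.shape[0]
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrMatrix(r=r, wavelengths=cube.wavelengths[ew_indices],
                      qc_zero_variance=[int(z) for z in zero])


def average_image_correlation(cubes: Sequence[HyperCube], masks: Sequence[np.ndarray],
                              ew_indices: Sequence[int]) -> CorrMatrix:
    """Correlation matrix averaged over samples (more stable than a
    single randomly chosen leaf; pass one cube to reproduce the
    single-sample protocol)."""
    mats = [image_correlation(c, m, ew_indices) for c, m in zip(cubes, masks)]
    r = np.mean([m.r for m in mats], axis=0)
    np.fill_diagonal(r, 1.0)
    qc = sorted({z for m in mats for z in m.qc_zero_variance})
    return CorrMatrix(r=r, wavelengths=mats[0].wavelengths, qc_zero_variance=qc)


def write_corr_heatmap(corr: CorrMatrix, prefix: str) -> None:
    """Write the EW-image correlation matrix as ``<prefix>.csv`` and a
    heat-map ``<prefix>.png`` (wavelengths label both axes)."""
    import csv

    labels = [f"{w:.1f}" for w in corr.wavelengths]
    with open(prefix + ".csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm"] + labels)
        for lab, row in zip(labels, corr.r):
            writer.writerow([lab] + [f"{v:.6f}" for v in row])
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.r, vmin=-1, vmax=1, cmap="RdBu_r")
    step = max(1, len(labels) // 12)
    ax.set_xticks(range(0, len(labels), step), labels[::step], rotation=90, fontsize=6)
    ax.set_yticks(range(0, len(labels), step), labels[::step], fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("EW reflectance-image correlations")
    fig.tight_layout()
    fig.savefig(prefix + ".png", dpi=120)
    plt.close(fig)


def greedy_container(corr: CorrMatrix, reference_idx: int,
                     threshold: float = CORR_THRESHOLD,
                     max_members: int = MAX_MEMBERS) -> list[int]:
    """Greedy scan admitting mutually weakly correlated band images.

    Starting from the container holding only the reference, scan the
    remaining EWs in ascending index order and admit an image iff its
    |r| against *every* image already in the container (reference
    included) is <= ``threshold``; stop after ``max_members`` admissions.
    Admitted members are then ranked by |r| with the reference,
    ascending (ties by index).  Returns matrix indices, reference first.
    """
    R = corr.r
    n = R.shape[0]
    if not 0 <= reference_idx < n:
        raise ValueError(f"reference index {reference_idx} outside 0..{n - 1}")
    container = [reference_idx]
    for j in range(n):
        if j == reference_idx or len(container) - 1 >= max_members:
            continue
        if all(abs(R[j, m]) <= threshold for m in container):
            container.append(j)
    members = sorted(container[1:], key=lambda j: (abs(R[j, reference_idx]), j))
    return [reference_idx] + members


def superposition_search(spectra: np.ndarray, labels: np.ndarray,
                         candidate_order: Sequence[float],
                         feature_extractor: Callable[[int], np.ndarray],
                         evaluator: Callable[[np.ndarray, np.ndarray], float]) -> RIS:
    """Pick the stack depth k maximising spectra+image-feature accuracy.

    ``feature_extractor(k)`` must return image features for all samples
    from a stack of the first k candidate images; ``evaluator(X, y)``
    scores the concatenated spectra+features (e.g. SVM CV accuracy).
    Ties resolve to the smaller k.
    """
    candidate_order = list(candidate_order)
    if not candidate_order:
        raise ValueError("candidate_order must start with the reference image")
    trace: list[float] = []
    best_k, best_acc = 1, -np.inf
    for k in range(1, len(candidate_order) + 1):
        feats = feature_extractor(k)
        acc = float(evaluator(np.hstack([spectra, feats]), labels))
        trace.append(acc)
        if acc > best_acc:
            best_k, best_acc = k, acc
    return RIS(reference_wl=float(candidate_order[0]),
               member_wls=[float(w) for w in candidate_order[1:best_k]],
               accuracy_trace=trace)
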