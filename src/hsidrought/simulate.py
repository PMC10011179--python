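"""Synthetic leaf hypercube generator.

Emulates the spectral phenomenology of tomato leaves under graded
drought stress as seen by a 272-band 400-1000 nm push-broom imager:

* a low visible baseline (chlorophyll absorption) with a convex green
  peak near 560 nm whose height *increases* with stress level,
* a red-edge reflectance rise near 730 nm that *blue-shifts* (moves to
  shorter wavelengths) with stress,
* a high, flat NIR plateau over 780-1000 nm,
* a smooth young-vs-mature profile difference, and
* optional high-frequency noise restricted to 400-500 nm emulating the
  poor blue-region signal-to-noise ratio of halogen-only illumination
  (``blue_light=False``).

The generator is the test bed for the whole pipeline: every stage
downstream of data acquisition can be exercised against known ground
truth (true masks, true stress labels, true young/mature pairing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .envi import HyperCube, ReferencePair

__all__ = [
    "SimParams",
    "SyntheticDataset",
    "base_spectrum",
    "render_cube",
    "make_reference_frames",
    "frame_raw",
    "generate_dataset",
    "make_band_signal_dataset",
    "make_disjoint_stage_dataset",
]

STAGES = ("young", "mature")
TREATMENTS = ("well", "reduced", "deficient")  # stress levels 0, 1, 2


@dataclass
class SimParams:
    """Knobs of the synthetic leaf model (wavelengths in nm, reflectance in [0, 1])."""

    n_bands: int = 272
    wl_range: tuple[float, float] = (400.0, 1000.0)
    visible_baseline: float = 0.06
    green_peak_center: float = 560.0
    green_peak_width: float = 28.0
    green_peak_amp: float = 0.10
    green_peak_gain_per_level: float = 0.04
    rededge_center: float = 730.0
    rededge_width: float = 12.0
    rededge_blueshift_per_level: float = 8.0
    nir_level: float = 0.55
    stage_offset: float = 0.02
    mature_green_scale: float = 0.7
    pixel_noise_sd: float = 0.01
    blue_noise_sd: float = 0.05
    blue_light: bool = True
    sample_gain_sd: float = 0.03
    leaf_shape: tuple[int, int] = (40, 24)  # ellipse full axes in pixels
    frame_size: tuple[int, int] = (64, 64)  # (lines, samples)
    background_reflectance: float = 0.02
    ripple_amplitude: float = 0.02
    full_scale: float = 4000.0
    dark_level: float = 80.0
    seed: int = 0

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_range[0], self.wl_range[1], self.n_bands)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def base_spectrum(level: int, stage: str, params: SimParams | None = None) -> np.ndarray:
    """Noiseless leaf reflectance for a stress ``level`` in {0, 1, 2}.

    Reflectance at the green peak is non-decreasing in ``level`` and the
    red-edge inflection moves to shorter wavelengths by
    ``rededge_blueshift_per_level`` nm per level.  Mature leaves get a
    damped green peak and a smooth low-frequency profile offset.
    """
    if level not in (0, 1, 2):
        raise ValueError(f"stress level must be 0, 1 or 2, got {level!r}")
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    p = params or SimParams()
    wl = p.wavelengths()

    green_scale = p.mature_green_scale if stage == "mature" else 1.0
    amp = (p.green_peak_amp + level * p.green_peak_gain_per_level) * green_scale
    green = amp * np.exp(-0.5 * ((wl - p.green_peak_center) / p.green_peak_width) ** 2)

    center = p.rededge_center - level * p.rededge_blueshift_per_level
    rededge = (p.nir_level - p.visible_baseline) * _sigmoid((wl - center) / p.rededge_width)

    spectrum = p.visible_baseline + green + rededge
    if stage == "mature":
        # fixed smooth perturbation distinguishing the mature profile
        spectrum = spectrum + p.stage_offset * np.sin(2.0 * np.pi * (wl - p.wl_range[0]) / 600.0)
    return np.clip(spectrum, 0.0, 1.2)


def red_edge_position(spectrum: np.ndarray, wavelengths: np.ndarray,
                      window: tuple[float, float] = (680.0, 780.0)) -> float:
    """Wavelength of the maximal first difference within ``window`` (nm)."""
    sel = (wavelengths >= window[0]) & (wavelengths <= window[1])
    idx = np.flatnonzero(sel)
    deriv = np.diff(spectrum[idx]) / np.diff(wavelengths[idx])
    mid = 0.5 * (wavelengths[idx][1:] + wavelengths[idx][:-1])
    return float(mid[np.argmax(deriv)])


def _ellipse_mask(frame: tuple[int, int], axes: tuple[int, int]) -> np.ndarray:
    h, w = frame
    a, b = axes[0] / 2.0, axes[1] / 2.0
    if axes[0] >= w or axes[1] >= h:
        raise ValueError(f"leaf ellipse {axes} does not fit in frame {frame}")
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def render_cube(spectrum: np.ndarray, params: SimParams, rng_seed: int) -> tuple[HyperCube, np.ndarray]:
    """Paint ``spectrum`` into an elliptical leaf on a dark background.

    In-mask pixels carry the spectrum plus i.i.d. Gaussian noise of sd
    ``pixel_noise_sd``; with ``blue_light=False`` extra i.i.d. noise of
    sd ``blue_noise_sd`` is added to bands below 500 nm.  Returns the
    reflectance cube and the ground-truth leaf mask.
    """
    p = params
    wl = p.wavelengths()
    if spectrum.shape != wl.shape:
        raise ValueError(f"spectrum length {spectrum.size} != n_bands {p.n_bands}")
    rng = np.random.default_rng(rng_seed)
    mask = _ellipse_mask(p.frame_size, p.leaf_shape)
    h, w = p.frame_size
    # flat, slightly tilted dark background (well below leaf NIR levels)
    bg = p.background_reflectance * (1.0 + 0.5 * (wl - wl[0]) / (wl[-1] - wl[0]))
    data = np.broadcast_to(bg, (h, w, p.n_bands)).copy()
    n_in = int(mask.sum())
    leaf = np.broadcast_to(spectrum, (n_in, p.n_bands)).copy()
    if p.pixel_noise_sd > 0:
        leaf += rng.normal(0.0, p.pixel_noise_sd, size=leaf.shape)
    if not p.blue_light and p.blue_noise_sd > 0:
        blue = wl < 500.0
        leaf[:, blue] += rng.normal(0.0, p.blue_noise_sd, size=(n_in, int(blue.sum())))
    data[mask] = leaf
    data = np.clip(data, 0.0, 1.2)
    cube = HyperCube(data.astype(np.float32), wl, {"seed": rng_seed, "calibrated": True})
    return cube, mask


def make_reference_frames(params: SimParams) -> ReferencePair:
    """Per-column white/dark reference spectra ``(samples, bands)``.

    The white frame sits near the sensor's full scale with a smooth
    spatial ripple (lamp non-uniformity); the dark frame is a small
    offset with its own faint ripple.  White > dark everywhere.
    """
    p = params
    rng = np.random.default_rng(p.seed + 7_777)
    w = p.frame_size[1]
    cols = np.arange(w)
    ripple = 1.0 + p.ripple_amplitude * np.sin(2.0 * np.pi * cols / max(w, 2))
    band_shape = 1.0 - 0.1 * np.linspace(0, 1, p.n_bands)  # mild spectral roll-off
    white = 0.95 * p.full_scale * ripple[:, None] * band_shape[None, :]
    dark = p.dark_level * (1.0 + 0.1 * p.ripple_amplitude * np.cos(2.0 * np.pi * cols / max(w, 2)))[:, None]
    dark = np.broadcast_to(dark, (w, p.n_bands)).copy()
    dark += rng.normal(0.0, 1e-3 * p.dark_level, size=dark.shape)
    pair = ReferencePair(white=white, dark=dark)
    if not np.all(pair.white > pair.dark):
        raise ValueError("degenerate references: white must exceed dark at every pixel-band")
    return pair


def frame_raw(reflectance: HyperCube, refs: ReferencePair) -> HyperCube:
    """Invert the calibration: raw counts = dark + R * (white - dark)."""
    white, dark = refs.as_column_refs()
    raw = dark[None, :, :] + reflectance.data.astype(np.float64) * (white - dark)[None, :, :]
    meta = dict(reflectance.meta)
    meta["calibrated"] = False
    return HyperCube(raw.astype(np.float32), reflectance.wavelengths, meta)


@dataclass
class SyntheticDataset:
    """Paired young/mature labelled cubes plus shared reference frames."""

    cubes: list[HyperCube]
    truth_masks: list[np.ndarray]
    labels: np.ndarray          # stress level 0/1/2 per cube
    stages: list[str]           # 'young' | 'mature' per cube
    plant_ids: np.ndarray
    replicate_idx: np.ndarray
    refs: ReferencePair
    params: SimParams = field(default_factory=SimParams)

    def __len__(self) -> int:
        return len(self.cubes)

    def stage_indices(self, stage: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.stages) if s == stage])

    def pair_key(self, i: int) -> tuple[int, int]:
        return int(self.plant_ids[i]), int(self.replicate_idx[i])


def generate_dataset(design: tuple[int, int, int], params: SimParams | None = None,
                     seed: int | None = None, as_raw: bool = False) -> SyntheticDataset:
    """Generate ``design[c]`` young/mature pairs per stress class ``c``.

    Every ``(plant_id, replicate_idx)`` occurs exactly once per stage, so
    young/mature pairing is total.  Plants carry three replicate leaves,
    mirroring a three-leaves-per-plant sampling design.  With
    ``as_raw=True`` cubes are framed into raw counts through the
    reference pair (the calibration step then has real work to do).
    """
    p = params or SimParams()
    if seed is not None:
        p = replace(p, seed=seed)
    if any(c < 1 for c in design):
        raise ValueError("per-class counts must be >= 1")
    rng = np.random.default_rng(p.seed)
    refs = make_reference_frames(p)
    cubes: list[HyperCube] = []
    masks: list[np.ndarray] = []
    labels, stages, plants, reps = [], [], [], []
    for level, count in enumerate(design):
        for j in range(count):
            plant = 1000 * level + j // 3
            rep = j % 3
            # per-pair biological variation, shared across the two stages
            gain = 1.0 + rng.normal(0.0, p.sample_gain_sd)
            for stage in STAGES:
                spec = base_spectrum(level, stage, p) * gain
                cube_seed = int(rng.integers(0, 2**31 - 1))
                cube, mask = render_cube(np.clip(spec, 0.0, 1.2), p, cube_seed)
                if as_raw:
                    cube = frame_raw(cube, refs)
                cubes.append(cube)
                masks.append(mask)
                labels.append(level)
                stages.append(stage)
                plants.append(plant)
                reps.append(rep)
    return SyntheticDataset(
        cubes=cubes, truth_masks=masks, labels=np.array(labels), stages=stages,
        plant_ids=np.array(plants), replicate_idx=np.array(reps), refs=refs, params=p,
    )


def make_band_signal_dataset(n_per_class: int, n_bands: int = 100,
                             informative: tuple[int, ...] = (7, 23, 48, 61, 90),
                             effect: float = 1.0, noise_sd: float = 1.0,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Spectra-matrix benchmark: class signal confined to a few bands.

    Informative bands get a mean shift of ``level * effect``; all other
    bands are pure ``N(0, noise_sd)`` noise.  Used to study whether the
    genetic-algorithm selector recovers the informative set.
    """
    rng = np.random.default_rng(seed)
    n = 3 * n_per_class
    X = rng.normal(0.0, noise_sd, size=(n, n_bands))
    y = np.repeat(np.arange(3), n_per_class)
    for b in informative:
        X[:, b] += y * effect
    perm = rng.permutation(n)
    return X[perm], y[perm]


def make_disjoint_stage_dataset(n_per_class: int, n_bands: int = 60,
                                young_bands: tuple[int, ...] = (5, 6, 7),
                                mature_bands: tuple[int, ...] = (40, 41, 42),
                                effect: float = 0.9, noise_sd: float = 1.0,
                                seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired young/mature feature matrices with class signal in disjoint bands.

    The young matrix discriminates class 0 vs {1,2}; the mature matrix
    discriminates class 2 vs {0,1}.  Neither stage alone can fully
    separate the three classes; their fusion can.  Returns
    ``(X_young, X_mature, y)`` with rows paired.
    """
    rng = np.random.default_rng(seed)
    n = 3 * n_per_class
    y = np.repeat(np.arange(3), n_per_class)
    Xy = rng.normal(0.0, noise_sd, size=(n, n_bands))
    Xm = rng.normal(0.0, noise_sd, size=(n, n_bands))
    for b in young_bands:
        Xy[:, b] += np.where(y == 0, 0.0, effect)  # separates well-watered
    for b in mature_bands:
        Xm[:, b] += np.where(y == 2, effect, 0.0)  # separates deficient
    perm = rng.permutation(n)
    return Xy[perm], Xm[perm], y[perm]
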