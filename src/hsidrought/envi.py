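"""ENVI-dialect hypercube I/O and white/dark reflectance calibration.

A hypercube is stored as a raw binary file plus a text ``.hdr`` sidecar
carrying ``samples, lines, bands, data type, interleave, byte order``
and a ``wavelength = { ... }`` list in nanometres.  In memory the cube
is always ``(lines, samples, bands)`` regardless of the on-disk
interleave (BIL, BIP or BSQ).

Reflectance calibration follows the standard white/dark correction

    I_c = (I_r - I_d) / (I_w - I_d)

where ``I_r`` is the raw leaf scan and ``I_w``/``I_d`` are white-board
and shutter-closed reference scans.  For a push-broom sensor the
references are per-column spectra broadcast along the scan (line) axis;
3-D reference scans are averaged over lines first.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HyperCube",
    "ReferencePair",
    "EnviFormatError",
    "CalibrationError",
    "read_envi",
    "write_envi",
    "calibrate",
]

# ENVI numeric type codes used here
_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

REFLECTANCE_MAX = 1.2  # clip ceiling after calibration (specular highlights)


class EnviFormatError(ValueError):
    """Header/binary inconsistency; message names the offending field."""


class CalibrationError(ValueError):
    """Raised when white == dark at some pixel-band."""


@dataclass
class HyperCube:
    """A ``(lines, samples, bands)`` cube with per-band wavelengths in nm."""

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise EnviFormatError(f"data must be 3-D (lines, samples, bands), got {self.data.ndim}-D")
        if self.data.shape[2] != self.wavelengths.size:
            raise EnviFormatError(
                f"bands: data has {self.data.shape[2]} bands but wavelength list has "
                f"{self.wavelengths.size} entries"
            )
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise EnviFormatError("wavelength: list must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class ReferencePair:
    """White (``I_w``) and dark (``I_d``) reference frames.

    Either ``(samples, bands)`` per-column spectra or full
    ``(lines, samples, bands)`` scans (averaged over lines on use).
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.white.shape != self.dark.shape:
            raise EnviFormatError(
                f"reference shapes differ: white {self.white.shape} vs dark {self.dark.shape}"
            )

    def as_column_refs(self) -> tuple[np.ndarray, np.ndarray]:
        """Collapse 3-D scans to per-column ``(samples, bands)`` spectra."""
        if self.white.ndim == 3:
            return self.white.mean(axis=0), self.dark.mean(axis=0)
        return self.white, self.dark


def _format_hdr(cube: HyperCube, interleave: str, dtype_code: int) -> str:
    lines, samples, bands = cube.data.shape
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    return (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )


def _parse_hdr(text: str) -> dict:
    fields: dict = {}
    # collapse { ... } blocks spanning lines, then parse key = value
    text = text.replace("\r\n", "\n")
    buf = ""
    in_block = False
    lines_out = []
    for line in text.split("\n"):
        if in_block:
            buf += " " + line
            if "}" in line:
                lines_out.append(buf)
                in_block = False
            continue
        if "{" in line and "}" not in line:
            buf = line
            in_block = True
        else:
            lines_out.append(line)
    for line in lines_out:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def write_envi(cube: HyperCube, path: str, interleave: str = "bil") -> None:
    """Write ``path`` (raw binary) and ``path + '.hdr'``."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviFormatError(f"interleave: unknown value {interleave!r}")
    data = cube.data
    dtype_code = _DTYPE_CODES.get(data.dtype)
    if dtype_code is None:
        data = data.astype(np.float32)
        dtype_code = 4
    if interleave == "bip":
        ondisk = data  # (lines, samples, bands)
    elif interleave == "bil":
        ondisk = data.transpose(0, 2, 1)  # (lines, bands, samples)
    else:  # bsq
        ondisk = data.transpose(2, 0, 1)  # (bands, lines, samples)
    with open(path, "wb") as fh:
        fh.write(np.ascontiguousarray(ondisk).tobytes())
    with open(path + ".hdr", "w") as fh:
        fh.write(_format_hdr(cube, interleave, dtype_code))


def read_envi(path: str) -> HyperCube:
    """Read a cube written by :func:`write_envi` (or a compatible tool)."""
    hdr_path = path + ".hdr" if os.path.exists(path + ".hdr") else os.path.splitext(path)[0] + ".hdr"
    if not os.path.exists(hdr_path):
        raise EnviFormatError(f"header: no .hdr sidecar found for {path!r}")
    fields = _parse_hdr(open(hdr_path).read())
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise EnviFormatError(f"{key}: missing from header")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _DTYPES:
        raise EnviFormatError(f"data type: unsupported code {code}")
    interleave = fields["interleave"].lower()
    if "wavelength" not in fields:
        raise EnviFormatError("wavelength: missing from header")
    wl_text = fields["wavelength"].strip().strip("{}").strip()
    wavelengths = np.array([float(v) for v in wl_text.split(",") if v.strip()])
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"wavelength: header declares bands={bands} but wavelength list has {wavelengths.size}"
        )
    raw = np.fromfile(path, dtype=_DTYPES[code])
    expected = lines * samples * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"bands: binary holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise EnviFormatError(f"interleave: unknown value {interleave!r}")
    return HyperCube(np.ascontiguousarray(data), wavelengths, {"interleave": interleave})


def calibrate(raw: HyperCube, refs: ReferencePair, clip: bool = True) -> HyperCube:
    """White/dark correction ``I_c = (I_r - I_d)/(I_w - I_d)``.

    Out-of-range values are clipped to ``[0, 1.2]`` and the clip count
    recorded in ``meta['qc_clipped']``.
    """
    white, dark = refs.as_column_refs()
    denom = white - dark
    bad = denom <= 0
    if np.any(bad):
        coord = tuple(int(c) for c in np.argwhere(bad)[0])
        raise CalibrationError(
            f"white == dark at (sample, band)={coord}; cannot calibrate"
        )
    refl = (raw.data.astype(np.float64) - dark[None, :, :]) / denom[None, :, :]
    n_clipped = 0
    if clip:
        n_clipped = int(np.sum((refl < 0) | (refl > REFLECTANCE_MAX)))
        # reflectance fits 32-bit floats once clipped to [0, 1.2]
        refl = np.clip(refl, 0.0, REFLECTANCE_MAX).astype(np.float32)
    meta = dict(raw.meta)
    meta.update({"calibrated": True, "qc_clipped": n_clipped})
    return HyperCube(refl, raw.wavelengths, meta)
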