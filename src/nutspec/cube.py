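"""Hyperspectral cube container, ENVI-dialect I/O, and radiometric calibration.

A :class:`HyperCube` holds a ``lines x pixels x bands`` grid together with its
wavelength vector (nm) and a processing ``stage`` tag (``raw`` sensor counts,
``reflectance`` after two-point calibration, or ``absorbance`` after the
log10(1/R) transform). Cubes are exchanged on disk in the classic ENVI
dialect: a plain-text ``key = value`` header next to a flat little-endian
binary file in BSQ, BIL or BIP interleave.

The two-point calibration converts raw counts to relative reflectance with a
dark-current frame (lamps off, scanner entry covered) and a white-reference
frame (PTFE tile at operating conditions):

    R = (raw - dark) / (white - dark)

Both frames are reduced to per-pixel-column medians across scan lines before
use, which suppresses shot noise in single-frame references.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

STAGES = ("raw", "reflectance", "absorbance")

#: ENVI numeric data-type codes -> numpy dtypes (little-endian)
_ENVI_DTYPES = {
    1: np.dtype("<u1"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
    14: np.dtype("<i8"),
    15: np.dtype("<u8"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """Image cube in ``lines x pixels x bands`` order with its wavelength grid."""

    data: np.ndarray
    wavelengths: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"bands dimension {self.data.shape[2]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationFrames:
    """Dark-current and white-reference frames matching a raw cube's geometry."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark)
        self.white = np.asarray(self.white)
        for name in ("dark", "white"):
            arr = getattr(self, name)
            if not np.issubdtype(arr.dtype, np.floating):
                setattr(self, name, arr.astype(np.float64))
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white frames must share a shape")


def _parse_header(text: str) -> dict:
    """Parse ENVI ``key = value`` header text, honouring {...} list values."""
    # collapse multi-line { ... } blocks first
    text = re.sub(
        r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text, flags=re.S
    )
    fields: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI" or line.startswith(";"):
            continue
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def _parse_float_list(raw: str) -> np.ndarray:
    body = raw.strip().lstrip("{").rstrip("}")
    items = [s for s in re.split(r"[,\s]+", body) if s]
    return np.asarray([float(s) for s in items])


def read_cube(header_path: str | Path, data_path: str | Path | None = None) -> HyperCube:
    """Read an ENVI-dialect cube into ``lines x pixels x bands`` order.

    ``data_path`` defaults to the header path with its extension dropped
    (``scene.hdr`` -> ``scene.dat`` if present, else ``scene``).
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())

    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise ValueError(f"{header_path}: header missing required field {key!r}")
    if "wavelength" not in fields:
        raise ValueError(f"{header_path}: header missing wavelength list")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    type_code = int(fields["data type"])
    if type_code not in _ENVI_DTYPES:
        raise ValueError(f"{header_path}: unsupported data type code {type_code}")
    byte_order = int(fields.get("byte order", "0"))
    if byte_order != 0:
        raise ValueError(f"{header_path}: only little-endian (byte order 0) supported")

    wavelengths = _parse_float_list(fields["wavelength"])
    if wavelengths.size != bands:
        raise ValueError(
            f"{header_path}: header declares {bands} bands but wavelength list "
            f"has {wavelengths.size} entries"
        )

    if data_path is None:
        stem = header_path.with_suffix("")
        data_path = stem.with_suffix(".dat") if stem.with_suffix(".dat").exists() else stem
    raw = np.fromfile(data_path, dtype=_ENVI_DTYPES[type_code])
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"{data_path}: file holds {raw.size} values, header implies {expected}"
        )

    if interleave == "bsq":  # (bands, lines, samples)
        grid = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        grid = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (lines, samples, bands)
        grid = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"{header_path}: unknown interleave {interleave!r}")

    stage = fields.get("stage", "raw")
    return HyperCube(np.ascontiguousarray(grid, dtype=np.float64), wavelengths, stage)


def write_cube(
    cube: HyperCube,
    header_path: str | Path,
    data_path: str | Path | None = None,
    dtype: str = "float64",
) -> tuple[Path, Path]:
    """Write a cube as an ENVI-dialect header + flat BSQ binary (little-endian)."""
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    data_path = Path(data_path)

    np_dtype = np.dtype(dtype).newbyteorder("<")
    if np_dtype not in _DTYPE_CODES:
        raise ValueError(f"dtype {dtype!r} has no ENVI type code")
    lines, samples, bands = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{nutspec cube, stage {cube.stage}}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np_dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"stage = {cube.stage}\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    header_path.write_text(header)
    cube.data.transpose(2, 0, 1).astype(np_dtype).tofile(data_path)
    return header_path, data_path


def _reduce_frame(frame: np.ndarray) -> np.ndarray:
    """Median of a reference frame across scan lines -> (pixels, bands).

    Frames that are constant across lines (common for synthetic or
    pre-averaged references) short-circuit the median.
    """
    if frame.shape[0] == 1 or (
        np.array_equal(frame[0], frame[-1]) and np.array_equal(frame[0], frame[frame.shape[0] // 2])
    ):
        return np.array(frame[0])
    return np.median(frame, axis=0)


def calibrate_reflectance(
    raw: HyperCube,
    frames: CalibrationFrames,
    clip: tuple[float, float] = (1e-4, 1.5),
) -> HyperCube:
    """Two-point calibration of a raw cube to relative reflectance.

    The dark and white frames are reduced to per-pixel-column medians across
    lines, then R = (raw - dark) / (white - dark) is computed per pixel and
    band and clipped to ``clip`` (defaults keep >100 % specular glints while
    avoiding log blow-ups from dead pixels downstream).
    """
    if raw.stage != "raw":
        raise ValueError(f"expected a raw cube, got stage {raw.stage!r}")
    # reference frames may be stored pre-reduced as a single line
    if frames.dark.shape[1:] != raw.shape[1:] or frames.dark.shape[0] not in (1, raw.shape[0]):
        raise ValueError(
            f"frame shape {frames.dark.shape} does not match cube {raw.shape}"
        )
    dark = _reduce_frame(frames.dark)
    white = _reduce_frame(frames.white)
    span = white - dark
    bad = np.nonzero(~np.all(span > 0, axis=0))[0]
    if bad.size:
        raise ValueError(
            "white - dark is non-positive after median smoothing in bands "
            f"{bad.tolist()} (wavelengths {raw.wavelengths[bad].tolist()})"
        )
    refl = (raw.data - dark[None, :, :]) / span[None, :, :]
    refl = np.clip(refl, clip[0], clip[1])
    return HyperCube(refl, raw.wavelengths.copy(), "reflectance")


def to_absorbance(cube: HyperCube) -> HyperCube:
    """Transform a reflectance cube to apparent absorbance A = log10(1/R)."""
    if cube.stage != "reflectance":
        raise ValueError(f"expected a reflectance cube, got stage {cube.stage!r}")
    absorb = -np.log10(cube.data)
    if not np.all(np.isfinite(absorb)):
        raise ValueError("absorbance is not finite; reflectance must be clipped > 0")
    return HyperCube(absorb, cube.wavelengths.copy(), "absorbance")


def subset_bands(cube: HyperCube, min_nm: float = 950.0, max_nm: float = 1650.0) -> HyperCube:
    """Keep only bands with ``min_nm <= wavelength <= max_nm`` (inclusive).

    The extremes of the acquired range are typically dominated by detector
    noise; the informative subrange is retained for all downstream analysis.
    """
    if min_nm >= max_nm:
        raise ValueError("min_nm must be below max_nm")
    keep = (cube.wavelengths >= min_nm) & (cube.wavelengths <= max_nm)
    if not keep.any():
        raise ValueError(
            f"no bands in [{min_nm}, {max_nm}] nm; cube covers "
            f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}] nm"
        )
    return HyperCube(cube.data[:, :, keep].copy(), cube.wavelengths[keep].copy(), cube.stage)


def absorbance_from_raw(
    raw: HyperCube,
    frames: CalibrationFrames,
    min_nm: float | None = 950.0,
    max_nm: float | None = 1650.0,
) -> HyperCube:
    """Convenience chain: calibrate -> absorbance -> optional band subset."""
    cube = to_absorbance(calibrate_reflectance(raw, frames))
    if min_nm is not None and max_nm is not None:
        cube = subset_bands(cube, min_nm, max_nm)
    return cube
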