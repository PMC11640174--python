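"""Hyperspectral cube I/O and radiometric calibration.

A cube is a ``height x width x bands`` array with an ascending wavelength
axis. Raw sensor counts are converted to reflectance against companion
white-reference and dark-current frames:

    R_s = (R_raw - R_b) / (R_w - R_b)

computed elementwise per band. Cubes are serialized in a pinned ENVI
dialect: a text ``.hdr`` with a ``wavelength = {...}`` list plus a raw
binary file, band-sequential (BSQ) little-endian float32 on write, with
band-interleaved-by-line (BIL) additionally accepted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralCube",
    "MeanSpectrum",
    "calibrate_reflectance",
    "extract_mean_spectrum",
    "trim_bands",
    "read_envi_cube",
    "write_envi_cube",
]

#: band-edge channels dropped by default at each end (951 -> 943)
DEFAULT_TRIM_LOW = 4
DEFAULT_TRIM_HIGH = 4


@dataclass
class SpectralCube:
    """Reflectance or raw-count image cube with its wavelength grid.

    Parameters
    ----------
    data
        Array of shape ``(height, width, bands)``.
    wavelengths_nm
        Strictly increasing vector of length ``bands``.
    kind
        ``"raw"`` for sensor counts, ``"reflectance"`` after calibration;
        companion frames use ``"white"`` / ``"dark"``.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (h, w, bands), got shape {self.data.shape}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {self.wavelengths_nm.size} does not match "
                f"band axis {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance", "white", "dark"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class MeanSpectrum:
    """Per-band mean over a sample's foreground pixels."""

    sample_id: str
    values: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_count: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")
        if self.values.shape != self.wavelengths_nm.shape:
            raise ValueError("values/wavelengths length mismatch")


def _frame_to_vector(frame) -> np.ndarray:
    """Reduce a companion frame (vector, 2-D line, or cube) to a per-band mean."""
    if isinstance(frame, SpectralCube):
        arr = frame.data
    else:
        arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 1:
        return arr
    # average over all pixel axes, keep the trailing band axis
    return arr.reshape(-1, arr.shape[-1]).mean(axis=0)


def calibrate_reflectance(raw: SpectralCube, white, dark) -> SpectralCube:
    """Convert raw counts to reflectance: ``(raw - dark) / (white - dark)``.

    ``white`` and ``dark`` may be per-band vectors, 2-D frames, or cubes;
    frames with pixel axes are averaged per band first. Values outside
    [0, 1] are retained (clipping would bias downstream pretreatments) but
    trigger a warning.
    """
    w = _frame_to_vector(white)
    b = _frame_to_vector(dark)
    if w.shape != (raw.n_bands,) or b.shape != (raw.n_bands,):
        raise ValueError("white/dark frames do not match the cube's band axis")
    denom = w - b
    bad = np.nonzero(denom == 0)[0]
    if bad.size:
        raise ValueError(
            f"white equals dark at band index {bad[0]} "
            f"({raw.wavelengths_nm[bad[0]]:.1f} nm): degenerate denominator"
        )
    refl = (raw.data - b) / denom
    if np.any(refl < 0) or np.any(refl > 1):
        warnings.warn(
            "reflectance outside [0, 1] after calibration; values retained unclipped",
            stacklevel=2,
        )
    return SpectralCube(refl, raw.wavelengths_nm.copy(), kind="reflectance")


def extract_mean_spectrum(
    cube: SpectralCube, mask: np.ndarray, sample_id: str = ""
) -> MeanSpectrum:
    """Per-band arithmetic mean over the masked (foreground) pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial axes")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no foreground pixels to average")
    values = cube.data[mask].mean(axis=0)
    return MeanSpectrum(sample_id, values, cube.wavelengths_nm.copy(), n)


def trim_bands(obj, trim_low: int = DEFAULT_TRIM_LOW, trim_high: int = DEFAULT_TRIM_HIGH):
    """Drop unstable edge channels: ``trim_low`` at the short-wavelength end,
    ``trim_high`` at the long end. Accepts a cube, a mean spectrum, or an
    ``(X, wavelengths)`` pair of arrays; returns the same type."""
    if trim_low < 0 or trim_high < 0:
        raise ValueError("trim counts must be non-negative")

    def _sl(n: int) -> slice:
        if trim_low + trim_high >= n:
            raise ValueError(f"cannot trim {trim_low}+{trim_high} channels from {n}")
        return slice(trim_low, n - trim_high)

    if isinstance(obj, SpectralCube):
        s = _sl(obj.n_bands)
        return SpectralCube(obj.data[:, :, s], obj.wavelengths_nm[s], kind=obj.kind)
    if isinstance(obj, MeanSpectrum):
        s = _sl(len(obj.values))
        return MeanSpectrum(obj.sample_id, obj.values[s], obj.wavelengths_nm[s], obj.pixel_count)
    X, wl = obj
    X = np.asarray(X)
    wl = np.asarray(wl)
    s = _sl(X.shape[-1])
    return X[..., s], wl[s]


# ---------------------------------------------------------------------------
# ENVI dialect codec
# ---------------------------------------------------------------------------

_DTYPE_CODE = {4: np.dtype("<f4"), 5: np.dtype("<f8")}


def write_envi_cube(cube: SpectralCube, path) -> None:
    """Write ``<path>.hdr`` + ``<path>.img`` (BSQ, little-endian float32)."""
    path = Path(path)
    h, w, b = cube.shape
    wl = ", ".join(f"{v:.6f}" for v in cube.wavelengths_nm)
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)
    # BSQ: band-major on disk
    bsq = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0), dtype="<f4")
    bsq.tofile(path.with_suffix(".img"))


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    in_braces = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if "{" in val and "}" not in val:
            buf = [val]
            in_braces = True
        else:
            fields[key] = val
    return fields


def read_envi_cube(path) -> SpectralCube:
    """Read an ENVI header/binary pair written by :func:`write_envi_cube`.

    BSQ and BIL interleaves are accepted; the ``wavelength`` field is
    required and must match the declared band count.
    """
    path = Path(path)
    hdr_path = path.with_suffix(".hdr")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
    except KeyError as e:
        raise ValueError(f"ENVI header missing required field {e}") from None
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError(f"unsupported interleave {interleave!r} (BSQ/BIL only)")
    dtype = _DTYPE_CODE.get(int(fields.get("data type", 4)))
    if dtype is None:
        raise ValueError("unsupported ENVI data type (float32/float64 only)")
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength field")
    wl_str = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(v) for v in wl_str.split(",") if v.strip()])
    if wavelengths.size != b:
        raise ValueError(
            f"wavelength list length {wavelengths.size} does not match bands = {b}"
        )
    raw = np.fromfile(path.with_suffix(".img"), dtype=dtype)
    if raw.size != h * w * b:
        raise ValueError("binary size does not match header dimensions")
    if interleave == "bsq":
        data = np.moveaxis(raw.reshape(b, h, w), 0, 2)
    else:  # bil: line-major, band, sample
        data = np.moveaxis(raw.reshape(h, b, w), 1, 2)
    kind = fields.get("cube kind", "reflectance")
    return SpectralCube(np.ascontiguousarray(data, dtype=np.float64), wavelengths, kind=kind)
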