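"""Detector geometry, Ewald-sphere mapping, bad-pixel masks and binning.

Conventions (fixed throughout the package):

* The X-ray beam travels along **+z**; the detector is a single flat panel in
  the plane ``z = camera_length``.
* The fast-scan axis maps to **+x**, the slow-scan axis to **+y**.
* Pixel indices are 0-based; a pixel's laboratory position is the position of
  its *centre*; membership of a pixel in a laboratory-frame rectangle is
  decided by its centre.
* Units: laboratory coordinates in mm, wavelength in Angstrom, reciprocal
  vectors in 1/Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DetectorGeometry",
    "MaskSpec",
    "ReciprocalPeak",
    "pixel_to_lab",
    "lab_to_pixel",
    "map_peaks_to_reciprocal",
    "lab_mask_to_pixel_ranges",
    "build_static_mask",
    "build_bad_pixel_mask",
    "bin_image",
    "load_geometry",
    "save_geometry",
]

#: slack (mm) used when testing whether a pixel centre lies on the boundary of
#: a laboratory-frame rectangle, so exact boundaries are not lost to rounding
_LAB_EPS_MM = 1e-9


@dataclass(frozen=True)
class DetectorGeometry:
    """Single-panel detector description.

    Parameters
    ----------
    n_fast, n_slow:
        Pixel counts along the fast and slow scan axes.
    pixel_size:
        Pixel edge length in mm.
    camera_length:
        Sample-to-detector distance along the beam, mm.
    beam_centre_fast, beam_centre_slow:
        Beam-centre pixel coordinates (fractional values allowed).
    wavelength:
        Radiation wavelength in Angstrom.
    """

    n_fast: int
    n_slow: int
    pixel_size: float
    camera_length: float
    beam_centre_fast: float
    beam_centre_slow: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.n_fast < 1 or self.n_slow < 1:
            raise ValueError("detector must have at least one pixel per axis")
        if not (self.pixel_size > 0 and self.camera_length > 0 and self.wavelength > 0):
            raise ValueError("pixel_size, camera_length and wavelength must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Image array shape, (n_slow, n_fast): slow is the leading axis."""
        return (self.n_slow, self.n_fast)

    @property
    def panels(self) -> list["DetectorGeometry"]:
        # single-panel instrument; a list leaves room for segmented detectors
        return [self]


@dataclass
class MaskSpec:
    """Bad-region specification: pixel rectangles, laboratory rectangles and a
    sentinel pixel value (the detector writes 65535 into unusable pixels)."""

    pixel_rect_regions: list[tuple[int, int, int, int]] = field(default_factory=list)
    lab_rect_regions: list[tuple[float, float, float, float]] = field(default_factory=list)
    sentinel_value: int = 65535

    def __post_init__(self) -> None:
        for f0, f1, s0, s1 in self.pixel_rect_regions:
            if f0 > f1 or s0 > s1:
                raise ValueError("pixel mask rectangle has min > max")
        for x0, x1, y0, y1 in self.lab_rect_regions:
            if x0 > x1 or y0 > y1:
                raise ValueError("lab mask rectangle has min > max")


@dataclass
class ReciprocalPeak:
    """A detector peak mapped onto the Ewald sphere.

    ``q`` is the scattering vector in 1/Angstrom; by construction
    ``|q + z/lambda| = 1/lambda``.
    """

    q: np.ndarray
    intensity: float
    source_peak: object = None


def pixel_to_lab(geometry: DetectorGeometry, fast, slow) -> np.ndarray:
    """Laboratory coordinates (mm) of pixel centres.

    Accepts scalars or arrays; returns an array of shape ``(..., 3)``.
    """
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    if not (np.all(np.isfinite(fast)) and np.all(np.isfinite(slow))):
        raise ValueError("non-finite pixel coordinates")
    x = (fast - geometry.beam_centre_fast) * geometry.pixel_size
    y = (slow - geometry.beam_centre_slow) * geometry.pixel_size
    z = np.broadcast_to(geometry.camera_length, np.broadcast_shapes(x.shape, y.shape))
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def lab_to_pixel(geometry: DetectorGeometry, x, y) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pixel_to_lab` for in-plane coordinates (mm)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fast = x / geometry.pixel_size + geometry.beam_centre_fast
    slow = y / geometry.pixel_size + geometry.beam_centre_slow
    return fast, slow


def map_peaks_to_reciprocal(peaks: Sequence, geometry: DetectorGeometry) -> list[ReciprocalPeak]:
    """Map detector peaks to reciprocal space via the Ewald construction.

    For a peak at laboratory position ``p``, the scattered beam direction is
    ``s = p/|p|`` and ``q = (s - z)/lambda``, with the nominal wavelength and
    zero wavelength spread.  Input ordering is preserved.
    """
    out: list[ReciprocalPeak] = []
    inv_lam = 1.0 / geometry.wavelength
    for pk in peaks:
        p = pixel_to_lab(geometry, pk.fast, pk.slow)
        norm = float(np.linalg.norm(p))
        if norm == 0.0:
            raise ValueError("peak at the sample position has no scattering direction")
        s_hat = p / norm
        q = (s_hat - np.array([0.0, 0.0, 1.0])) * inv_lam
        out.append(ReciprocalPeak(q=q, intensity=float(pk.intensity), source_peak=pk))
    return out


def lab_mask_to_pixel_ranges(
    geometry: DetectorGeometry, lab_rect: tuple[float, float, float, float]
) -> tuple[int, int, int, int] | None:
    """Convert an axis-aligned laboratory rectangle (mm) to a pixel range.

    Returns the minimal inclusive pixel rectangle ``(fast_min, fast_max,
    slow_min, slow_max)`` containing every pixel whose centre lies inside the
    rectangle, or ``None`` when no pixel qualifies.  Done once per geometry,
    not per frame.
    """
    x0, x1, y0, y1 = lab_rect
    if x0 > x1 or y0 > y1:
        raise ValueError("rectangle has min > max")
    p = geometry.pixel_size
    eps = _LAB_EPS_MM / p
    f0 = math.ceil(x0 / p + geometry.beam_centre_fast - eps)
    f1 = math.floor(x1 / p + geometry.beam_centre_fast + eps)
    s0 = math.ceil(y0 / p + geometry.beam_centre_slow - eps)
    s1 = math.floor(y1 / p + geometry.beam_centre_slow + eps)
    f0, f1 = max(f0, 0), min(f1, geometry.n_fast - 1)
    s0, s1 = max(s0, 0), min(s1, geometry.n_slow - 1)
    if f0 > f1 or s0 > s1:
        return None
    return (f0, f1, s0, s1)


def build_static_mask(mask_spec: MaskSpec, geometry: DetectorGeometry) -> np.ndarray:
    """Frame-independent part of the bad-pixel mask (rectangles only)."""
    bad = np.zeros(geometry.shape, dtype=bool)
    for f0, f1, s0, s1 in mask_spec.pixel_rect_regions:
        f0c, f1c = max(f0, 0), min(f1, geometry.n_fast - 1)
        s0c, s1c = max(s0, 0), min(s1, geometry.n_slow - 1)
        if f0c <= f1c and s0c <= s1c:
            bad[s0c : s1c + 1, f0c : f1c + 1] = True
    for rect in mask_spec.lab_rect_regions:
        rng = lab_mask_to_pixel_ranges(geometry, rect)
        if rng is not None:
            f0, f1, s0, s1 = rng
            bad[s0 : s1 + 1, f0 : f1 + 1] = True
    return bad


def build_bad_pixel_mask(
    image: np.ndarray, mask_spec: MaskSpec, geometry: DetectorGeometry
) -> np.ndarray:
    """Boolean mask, True where a pixel is bad.

    A pixel is bad iff its value equals the sentinel, or it lies inside any
    pixel rectangle, or inside any laboratory rectangle (converted to pixel
    ranges).  The returned buffer can be reused across frames of one run by
    recomputing only the sentinel component.
    """
    image = np.asarray(image)
    if image.shape != geometry.shape:
        raise ValueError(f"image shape {image.shape} != geometry shape {geometry.shape}")
    bad = build_static_mask(mask_spec, geometry)
    bad |= image == mask_spec.sentinel_value
    return bad


def bin_image(
    image: np.ndarray, factor: int, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sum pixel readout values in ``factor`` x ``factor`` squares.

    Output dimensions are ``ceil(n/factor)`` (edge blocks may be partial).
    Each output pixel is the sum of its *unmasked* member pixels and is
    masked iff any member pixel is masked.  ``factor=1`` is the identity.
    """
    if int(factor) != factor or factor <= 0:
        raise ValueError("binning factor must be a positive integer")
    factor = int(factor)
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if mask is None:
        mask = np.zeros(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape mismatch")
    if factor == 1:
        return image.copy(), mask.copy()

    acc = image.astype(np.float64, copy=False) * ~mask
    i0 = np.arange(0, image.shape[0], factor)
    i1 = np.arange(0, image.shape[1], factor)
    summed = np.add.reduceat(np.add.reduceat(acc, i0, axis=0), i1, axis=1)
    nbad = np.add.reduceat(np.add.reduceat(mask.astype(np.int64), i0, axis=0), i1, axis=1)
    out_mask = nbad > 0
    if np.issubdtype(image.dtype, np.integer):
        summed = summed.astype(np.int64)
    return summed, out_mask


# ---------------------------------------------------------------------------
# plain-text geometry files

_SCALARS = {
    "wavelength_A": "wavelength",
    "clen_mm": "camera_length",
    "pixel_size_mm": "pixel_size",
    "beam_centre_fast_px": "beam_centre_fast",
    "beam_centre_slow_px": "beam_centre_slow",
    "n_fast": "n_fast",
    "n_slow": "n_slow",
}


def load_geometry(path) -> tuple[DetectorGeometry, MaskSpec]:
    """Read a ``key = value`` geometry file (see :func:`save_geometry`)."""
    values: dict[str, float] = {}
    spec = MaskSpec()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if not _:
                raise ValueError(f"malformed geometry line: {raw!r}")
            if key in _SCALARS:
                values[_SCALARS[key]] = float(val)
            elif key == "mask_rect_px":
                spec.pixel_rect_regions.append(tuple(int(x) for x in val.split()))
            elif key == "mask_rect_lab_mm":
                spec.lab_rect_regions.append(tuple(float(x) for x in val.split()))
            elif key == "mask_value":
                spec.sentinel_value = int(val)
            else:
                raise ValueError(f"unknown geometry key {key!r}")
    missing = set(_SCALARS.values()) - set(values)
    if missing:
        raise ValueError(f"geometry file missing keys: {sorted(missing)}")
    geom = DetectorGeometry(
        n_fast=int(values["n_fast"]),
        n_slow=int(values["n_slow"]),
        pixel_size=values["pixel_size"],
        camera_length=values["camera_length"],
        beam_centre_fast=values["beam_centre_fast"],
        beam_centre_slow=values["beam_centre_slow"],
        wavelength=values["wavelength"],
    )
    return geom, spec


def save_geometry(path, geometry: DetectorGeometry, mask_spec: MaskSpec | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"wavelength_A = {geometry.wavelength!r}\n")
        fh.write(f"clen_mm = {geometry.camera_length!r}\n")
        fh.write(f"pixel_size_mm = {geometry.pixel_size!r}\n")
        fh.write(f"beam_centre_fast_px = {geometry.beam_centre_fast!r}\n")
        fh.write(f"beam_centre_slow_px = {geometry.beam_centre_slow!r}\n")
        fh.write(f"n_fast = {geometry.n_fast}\n")
        fh.write(f"n_slow = {geometry.n_slow}\n")
        if mask_spec is not None:
            for r in mask_spec.pixel_rect_regions:
                fh.write("mask_rect_px = " + " ".join(str(int(v)) for v in r) + "\n")
            for r in mask_spec.lab_rect_regions:
                fh.write("mask_rect_lab_mm = " + " ".join(repr(float(v)) for v in r) + "\n")
            fh.write(f"mask_value = {mask_spec.sentinel_value}\n")
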