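"""Reflection prediction from an oriented cell, and intensity integration.

For a still (no rotation during exposure) a reflection is predicted when its
reciprocal-lattice point lies close enough to the Ewald sphere.  Closeness is
measured by the excitation error ``e = |q + z/lambda| - 1/lambda`` and
accepted within a band ``|e| <= e_max_abs + e_max_rel * |q|`` — the minimal
still-diffraction convention of a tolerance that widens linearly with
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DetectorGeometry, lab_to_pixel
from .lattice import UnitCell

__all__ = ["Reflection", "IntegrationOptions", "predict_reflections", "integrate", "classify_hit"]


@dataclass
class Reflection:
    h: int
    k: int
    l: int
    q: np.ndarray
    excitation_error: float
    fast: float
    slow: float
    intensity: float = 0.0
    sigma: float = 0.0
    flag: str = "ok"  # ok | off-detector | masked


@dataclass
class IntegrationOptions:
    e_max_abs: float = 0.001  # 1/A
    e_max_rel: float = 0.002  # fraction of |q|
    d_min: float = 2.0  # A
    d_max: float | None = None
    peak_radius: float = 4.0  # px
    bg_inner: float = 5.0
    bg_outer: float = 7.0

    def __post_init__(self) -> None:
        if not self.bg_outer > self.bg_inner > self.peak_radius:
            raise ValueError("require bg_outer > bg_inner > peak_radius")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")


def predict_reflections(
    cell: UnitCell, geometry: DetectorGeometry, options: IntegrationOptions | None = None
) -> list[Reflection]:
    """Reflections whose reciprocal points lie within the excitation band.

    The cell must be oriented (lab frame).  The scattered direction
    ``(q + z/lambda)`` normalized is projected onto the detector plane;
    reflections landing outside the panel are flagged ``off-detector``.
    """
    if options is None:
        options = IntegrationOptions()
    if abs(cell.volume) < 1e-9:
        raise ValueError("degenerate cell")
    lam = geometry.wavelength
    inv_lam = 1.0 / lam

    lens = [float(np.linalg.norm(cell.basis[:, i])) for i in range(3)]
    hmax, kmax, lmax = (int(np.floor(L / options.d_min)) + 1 for L in lens)
    hh, kk, ll = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = hkl @ cell.reciprocal_matrix.T
    qlen = np.linalg.norm(q, axis=1)
    keep = qlen <= 1.0 / options.d_min
    if options.d_max is not None:
        keep &= qlen >= 1.0 / options.d_max
    hkl, q, qlen = hkl[keep], q[keep], qlen[keep]

    centre = q + np.array([0.0, 0.0, inv_lam])
    e = np.linalg.norm(centre, axis=1) - inv_lam
    near = np.abs(e) <= options.e_max_abs + options.e_max_rel * qlen
    hkl, q, qlen, e, centre = hkl[near], q[near], qlen[near], e[near], centre[near]

    out: list[Reflection] = []
    for i in range(hkl.shape[0]):
        sz = centre[i, 2]
        if sz <= 1e-12:
            fast = slow = float("nan")
            flag = "off-detector"
        else:
            scale = geometry.camera_length / sz
            fast, slow = lab_to_pixel(geometry, centre[i, 0] * scale, centre[i, 1] * scale)
            fast, slow = float(fast), float(slow)
            on = 0.0 <= fast <= geometry.n_fast - 1 and 0.0 <= slow <= geometry.n_slow - 1
            flag = "ok" if on else "off-detector"
        out.append(
            Reflection(
                h=int(hkl[i, 0]),
                k=int(hkl[i, 1]),
                l=int(hkl[i, 2]),
                q=q[i],
                excitation_error=float(e[i]),
                fast=fast,
                slow=slow,
                flag=flag,
            )
        )
    return out


def integrate(
    image: np.ndarray,
    reflections: list[Reflection],
    mask: np.ndarray | None,
    options: IntegrationOptions | None = None,
) -> list[Reflection]:
    """Measure intensities at the predicted positions.

    ``intensity`` is the sum of (pixel - local background) over a disc of
    ``peak_radius``; the background is the *median* of the [bg_inner,
    bg_outer] annulus (robust against neighbouring spots), and ``sigma``
    combines counting statistics with the annulus variance.  Reflections
    whose disc overlaps a bad pixel, or whose box leaves the detector, are
    flagged instead of measured.
    """
    if options is None:
        options = IntegrationOptions()
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.zeros(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_slow, n_fast = image.shape
    r_out = int(np.ceil(options.bg_outer))
    out: list[Reflection] = []
    for refl in reflections:
        r = Reflection(**{**refl.__dict__})
        if refl.flag != "ok" or not np.isfinite(refl.fast):
            out.append(r)
            continue
        f0, s0 = int(round(refl.fast)), int(round(refl.slow))
        if (
            f0 - r_out < 0
            or f0 + r_out >= n_fast
            or s0 - r_out < 0
            or s0 + r_out >= n_slow
        ):
            r.flag = "off-detector"
            out.append(r)
            continue
        win = np.s_[s0 - r_out : s0 + r_out + 1, f0 - r_out : f0 + r_out + 1]
        sub = image[win]
        bad = mask[win]
        sl, fa = np.indices(sub.shape)
        rad = np.hypot(fa + (f0 - r_out) - refl.fast, sl + (s0 - r_out) - refl.slow)
        disc = rad <= options.peak_radius
        ann = (rad >= options.bg_inner) & (rad <= options.bg_outer) & ~bad
        if np.any(disc & bad):
            r.flag = "masked"
            out.append(r)
            continue
        if ann.sum() < 3:
            r.flag = "masked"
            out.append(r)
            continue
        bg = float(np.median(sub[ann]))
        bg_var = float(np.var(sub[ann]))
        n_px = int(disc.sum())
        r.intensity = float(np.sum(sub[disc]) - n_px * bg)
        r.sigma = float(np.sqrt(max(np.sum(sub[disc]), 0.0) + n_px * bg_var))
        out.append(r)
    return out


def classify_hit(peaks: list, min_peaks: int = 15) -> bool:
    """A frame is a hit when the peak search found at least ``min_peaks`` spots."""
    return len(peaks) >= min_peaks
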