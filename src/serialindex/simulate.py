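"""Synthetic still-pattern generator with known ground truth.

Patterns are generated as the exact dual of the prediction stage: a cell is
rotated to a uniformly random orientation, the reciprocal-lattice points
within an excitation-error band of the Ewald sphere are projected onto the
detector, and optional positional jitter, dropped peaks and spurious peaks
emulate an imperfect peak search.  Frames are rendered as Poisson background
plus Gaussian spots, so the whole pipeline — peak search, indexing,
prediction, integration — is testable without real detector data.

Physical realism deliberately stops at geometry: intensities are
exponentially distributed (no structure factors, polarization or
partiality), and the point spread is an isotropic Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DetectorGeometry, MaskSpec, build_static_mask
from .lattice import UnitCell, cell_from_parameters
from .peaks import Peak
from .predict import IntegrationOptions, predict_reflections

__all__ = [
    "SimulatedPattern",
    "default_geometry",
    "LYSOZYME_CELL",
    "random_orientation",
    "simulate_peaks",
    "render_frame",
    "make_run",
]

#: tetragonal lysozyme-like reference cell (a, b, c, alpha, beta, gamma)
LYSOZYME_CELL = (79.2, 79.2, 38.0, 90.0, 90.0, 90.0)


def default_geometry() -> DetectorGeometry:
    """Desk-scale single-panel geometry used by the synthetic studies.

    512x512 pixels of 0.1 mm at 60 mm camera length and 1.0332 A (12 keV)
    reaches ~1.9 A in the detector corner; with the default excitation band
    this yields a few tens of reflections per still for the lysozyme-like
    cell, matching a realistic well-exposed pattern.
    """
    return DetectorGeometry(
        n_fast=512,
        n_slow=512,
        pixel_size=0.1,
        camera_length=60.0,
        beam_centre_fast=256.0,
        beam_centre_slow=256.0,
        wavelength=1.0332,
    )


@dataclass
class SimulatedPattern:
    true_cell: UnitCell  # oriented, lab frame
    peaks: list[Peak]
    hkls: list[tuple[int, int, int] | None]  # None marks a spurious peak
    frame: np.ndarray | None
    seed: int


def random_orientation(seed) -> np.ndarray:
    """Uniformly random proper rotation matrix (via unit quaternions)."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(4)
    w, x, y, z = u / np.linalg.norm(u)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def simulate_peaks(
    cell_params=LYSOZYME_CELL,
    orientation: np.ndarray | None = None,
    geometry: DetectorGeometry | None = None,
    sim_tolerance: IntegrationOptions | None = None,
    n_false: int = 0,
    pos_jitter: float = 0.0,
    drop_fraction: float = 0.0,
    seed: int = 0,
    intensity_scale: float = 1000.0,
) -> SimulatedPattern:
    """Generate the peak list of one still with known cell and orientation.

    The tolerance options mirror :class:`IntegrationOptions`, so prediction
    and simulation are exact duals: simulated peaks (before jitter and
    dropping) are precisely the ``flag == "ok"`` predictions of the oriented
    truth cell.
    """
    geometry = geometry or default_geometry()
    # A narrow excitation band keeps the Ewald-mapped peak positions close
    # to exact reciprocal-lattice points: these are the package's noise-free
    # reference conditions.  Widen it (or mirror IntegrationOptions) to
    # emulate the partiality width that integration assumes.
    sim_tolerance = sim_tolerance or IntegrationOptions(
        e_max_abs=2e-4, e_max_rel=0.0, d_min=3.0
    )
    rng = np.random.default_rng(seed)
    if orientation is None:
        orientation = random_orientation(rng.integers(0, 2**31 - 1))
    base = cell_from_parameters(*cell_params)
    oriented = UnitCell(orientation @ base.basis)

    refs = [r for r in predict_reflections(oriented, geometry, sim_tolerance) if r.flag == "ok"]
    keep = [r for r in refs if rng.random() >= drop_fraction]
    peaks: list[Peak] = []
    hkls: list[tuple[int, int, int] | None] = []
    for r in keep:
        fast = r.fast + (rng.standard_normal() * pos_jitter if pos_jitter > 0 else 0.0)
        slow = r.slow + (rng.standard_normal() * pos_jitter if pos_jitter > 0 else 0.0)
        fast = float(np.clip(fast, 0, geometry.n_fast - 1))
        slow = float(np.clip(slow, 0, geometry.n_slow - 1))
        peaks.append(
            Peak(
                fast=fast,
                slow=slow,
                intensity=float(rng.exponential(intensity_scale)),
                snr=0.0,
                n_pixels=1,
            )
        )
        hkls.append((r.h, r.k, r.l))
    for _ in range(n_false):
        peaks.append(
            Peak(
                fast=float(rng.uniform(0, geometry.n_fast - 1)),
                slow=float(rng.uniform(0, geometry.n_slow - 1)),
                intensity=float(rng.exponential(intensity_scale)),
                snr=0.0,
                n_pixels=1,
            )
        )
        hkls.append(None)
    order = rng.permutation(len(peaks))
    peaks = [peaks[i] for i in order]
    hkls = [hkls[i] for i in order]
    return SimulatedPattern(true_cell=oriented, peaks=peaks, hkls=hkls, frame=None, seed=seed)


def render_frame(
    pattern: SimulatedPattern,
    geometry: DetectorGeometry | None = None,
    spot_sigma: float = 1.2,
    spot_counts: float | None = None,
    background_mean: float = 10.0,
    mask_spec: MaskSpec | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Render a pattern as a uint16 frame.

    Poisson background plus deterministic Gaussian spots (each spot deposits
    ``round`` of its profile, integrating to the peak intensity up to tail
    truncation at 4 sigma).  Masked pixels are set to the sentinel value.
    """
    geometry = geometry or default_geometry()
    rng = np.random.default_rng(pattern.seed if seed is None else seed)
    img = rng.poisson(background_mean, size=geometry.shape).astype(np.float64)
    half = int(np.ceil(4 * spot_sigma))
    norm = 2 * np.pi * spot_sigma**2
    for pk in pattern.peaks:
        amp = spot_counts if spot_counts is not None else pk.intensity
        f0, s0 = int(round(pk.fast)), int(round(pk.slow))
        s_lo, s_hi = max(s0 - half, 0), min(s0 + half, geometry.n_slow - 1)
        f_lo, f_hi = max(f0 - half, 0), min(f0 + half, geometry.n_fast - 1)
        if s_lo > s_hi or f_lo > f_hi:
            continue
        sl, fa = np.mgrid[s_lo : s_hi + 1, f_lo : f_hi + 1]
        prof = amp / norm * np.exp(
            -((fa - pk.fast) ** 2 + (sl - pk.slow) ** 2) / (2 * spot_sigma**2)
        )
        img[s_lo : s_hi + 1, f_lo : f_hi + 1] += np.rint(prof)
    sentinel = mask_spec.sentinel_value if mask_spec is not None else 65535
    img = np.clip(img, 0, min(sentinel - 1, 65534)).astype(np.uint16)
    if mask_spec is not None:
        img[build_static_mask(mask_spec, geometry)] = sentinel
    return img


def make_run(
    n_frames: int,
    hit_fraction: float,
    geometry: DetectorGeometry | None = None,
    cell_params=LYSOZYME_CELL,
    seed: int = 0,
    render: bool = True,
    background_mean: float = 10.0,
    spot_counts: float | None = 4000.0,
    mask_spec: MaskSpec | None = None,
    **sim_kwargs,
) -> tuple[list[np.ndarray | None], pd.DataFrame, list[SimulatedPattern | None]]:
    """A seeded sequence of hit and blank frames with a ground-truth manifest.

    Returns ``(frames, manifest, patterns)``; blanks have ``patterns[i] is
    None`` and (when rendered) a background-only frame.  The manifest has one
    row per frame: frame id, hit flag, simulated peak count and seed.
    """
    if not 0.0 <= hit_fraction <= 1.0:
        raise ValueError("hit_fraction must lie in [0, 1]")
    geometry = geometry or default_geometry()
    master = np.random.default_rng(seed)
    frames: list[np.ndarray | None] = []
    patterns: list[SimulatedPattern | None] = []
    rows = []
    for i in range(n_frames):
        frame_seed = int(master.integers(0, 2**31 - 1))
        is_hit = bool(master.random() < hit_fraction)
        if is_hit:
            pat = simulate_peaks(
                cell_params=cell_params, geometry=geometry, seed=frame_seed, **sim_kwargs
            )
        else:
            pat = None
        if render:
            if pat is not None:
                frame = render_frame(
                    pat,
                    geometry,
                    spot_counts=spot_counts,
                    background_mean=background_mean,
                    mask_spec=mask_spec,
                )
            else:
                blank = SimulatedPattern(
                    true_cell=cell_from_parameters(*cell_params),
                    peaks=[],
                    hkls=[],
                    frame=None,
                    seed=frame_seed,
                )
                frame = render_frame(
                    blank, geometry, background_mean=background_mean, mask_spec=mask_spec
                )
            if pat is not None:
                pat.frame = frame
        else:
            frame = None
        frames.append(frame)
        patterns.append(pat)
        rows.append(
            {
                "frame_id": i,
                "is_hit": is_hit,
                "n_peaks": len(pat.peaks) if pat is not None else 0,
                "seed": frame_seed,
            }
        )
    manifest = pd.DataFrame(rows)
    return frames, manifest, patterns
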