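"""peakfinder8-style Bragg-peak search with precomputed radial statistics.

The search thresholds each pixel against the background statistics of its
radial annulus around the beam centre, because the background of a still
diffraction image varies much faster radially than circumferentially.  The
pixel-to-annulus assignment depends only on the detector geometry and the
static mask, so it is computed once per run and reused for every frame.

A fast variant estimates each annulus's mean and standard deviation from at
most ``fast_sample_size`` randomly chosen pixels instead of the whole ring;
the sample positions are drawn once per annulus map (seeded), not per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import DetectorGeometry

__all__ = [
    "AnnulusMap",
    "RadialStats",
    "Peak",
    "PeakSearchOptions",
    "build_annulus_map",
    "radial_stats",
    "peakfinder8_search",
    "write_peaks",
    "read_peaks",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class Peak:
    """A found spot: background-subtracted centroid and summed intensity."""

    fast: float
    slow: float
    intensity: float
    snr: float
    n_pixels: int


@dataclass
class PeakSearchOptions:
    min_snr: float = 6.0
    adc_threshold: float = 10.0
    min_pix: int = 2
    max_pix: int = 200
    fast_mode: bool = False
    fast_sample_size: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_pix > self.max_pix:
            raise ValueError("min_pix must not exceed max_pix")
        if self.fast_sample_size < 2:
            raise ValueError("fast_sample_size must be at least 2")


@dataclass
class AnnulusMap:
    """Per-pixel annulus assignment (-1 for bad/off-range pixels)."""

    annulus_index: np.ndarray
    n_annuli: int
    annulus_width: float
    _sample_cache: dict = field(default_factory=dict, repr=False)

    def sample_indices(self, options: PeakSearchOptions) -> list[np.ndarray]:
        """Flat pixel indices sampled per annulus for fast-mode statistics.

        Drawn once (without replacement, seeded) per (seed, size) pair and
        cached, so every frame of a run sees the same sample positions.
        """
        key = (options.rng_seed, options.fast_sample_size)
        if key not in self._sample_cache:
            rng = np.random.default_rng(options.rng_seed)
            flat = self.annulus_index.ravel()
            order = np.argsort(flat, kind="stable")
            sorted_ann = flat[order]
            bounds = np.searchsorted(sorted_ann, np.arange(self.n_annuli + 1))
            samples = []
            for a in range(self.n_annuli):
                members = order[bounds[a] : bounds[a + 1]]
                if members.size > options.fast_sample_size:
                    members = rng.choice(members, size=options.fast_sample_size, replace=False)
                samples.append(np.sort(members))
            self._sample_cache[key] = samples
        return self._sample_cache[key]


@dataclass
class RadialStats:
    """Per-annulus background statistics after outlier rejection."""

    mean: np.ndarray
    sigma: np.ndarray
    n_used: np.ndarray
    usable: np.ndarray


def build_annulus_map(
    geometry: DetectorGeometry,
    mask: np.ndarray | None = None,
    annulus_width: float = 1.0,
) -> AnnulusMap:
    """Assign every good pixel to a thin annulus around the beam centre.

    ``annulus_index = floor(radius_px / annulus_width)``; bad pixels get -1.
    """
    if annulus_width <= 0:
        raise ValueError("annulus_width must be positive")
    slow, fast = np.indices(geometry.shape)
    r = np.hypot(fast - geometry.beam_centre_fast, slow - geometry.beam_centre_slow)
    idx = np.floor(r / annulus_width).astype(np.int32)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != geometry.shape:
            raise ValueError("mask shape mismatch")
        idx[mask] = -1
    n_annuli = int(idx.max()) + 1 if np.any(idx >= 0) else 0
    return AnnulusMap(annulus_index=idx, n_annuli=n_annuli, annulus_width=annulus_width)


def _clipped_moments(values, labels, n_annuli, n_iter=3):
    """Per-annulus mean/sigma with iterative high-side 3-sigma rejection.

    Bragg peaks bias naive ring statistics upwards, so pixels above
    mu + 3 sigma are discarded for ``n_iter`` rounds before the final
    moments are taken over the survivors.
    """
    keep = np.ones(values.shape, dtype=bool)
    mu = np.zeros(n_annuli)
    sigma = np.zeros(n_annuli)
    counts = np.zeros(n_annuli)
    for _ in range(n_iter + 1):
        w = keep.astype(float)
        counts = np.bincount(labels, weights=w, minlength=n_annuli)
        s1 = np.bincount(labels, weights=w * values, minlength=n_annuli)
        s2 = np.bincount(labels, weights=w * values * values, minlength=n_annuli)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = s1 / counts
            var = s2 / counts - mu * mu
        sigma = np.sqrt(np.maximum(var, 0.0))
        keep = keep & (values <= mu[labels] + 3.0 * sigma[labels])
    return mu, sigma, counts.astype(np.int64)


def radial_stats(
    image: np.ndarray, annulus_map: AnnulusMap, options: PeakSearchOptions
) -> RadialStats:
    """Background mean and sigma per annulus.

    Full mode uses every good pixel of each annulus; fast mode uses the
    fixed random sample from :meth:`AnnulusMap.sample_indices`.  Annuli with
    fewer than two usable pixels are flagged unusable.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != annulus_map.annulus_index.shape:
        raise ValueError("image shape does not match annulus map")
    flat_img = image.ravel()
    flat_ann = annulus_map.annulus_index.ravel()
    n = annulus_map.n_annuli
    if n == 0:
        z = np.zeros(0)
        return RadialStats(z, z.copy(), z.astype(np.int64), z.astype(bool))
    if options.fast_mode:
        picks = np.concatenate(
            [s for s in annulus_map.sample_indices(options) if s.size] or [np.zeros(0, int)]
        ).astype(np.intp)
        values = flat_img[picks]
        labels = flat_ann[picks]
    else:
        good = flat_ann >= 0
        values = flat_img[good]
        labels = flat_ann[good]
    mu, sigma, n_used = _clipped_moments(values, labels, n)
    usable = n_used >= 2
    mu[~usable] = np.nan
    sigma[~usable] = np.nan
    return RadialStats(mean=mu, sigma=sigma, n_used=n_used, usable=usable)


def peakfinder8_search(
    image: np.ndarray,
    annulus_map: AnnulusMap,
    stats: RadialStats,
    mask: np.ndarray | None,
    options: PeakSearchOptions,
) -> list[Peak]:
    """Find Bragg peaks by annular-background thresholding.

    Candidate pixels are good pixels whose value exceeds
    ``max(adc_threshold, mu_r + min_snr * sigma_r)``; candidates are grouped
    by 8-connectivity, size-filtered, and summarized by their
    background-subtracted intensity-weighted centroid.  Region SNR is
    ``I / sqrt(sum sigma_r^2)`` over member pixels (``I / (sigma sqrt(n))``
    for a single-annulus region).  Returned sorted by descending intensity.
    """
    image = np.asarray(image, dtype=float)
    ann = annulus_map.annulus_index
    if image.shape != ann.shape:
        raise ValueError("image shape does not match annulus map")
    good = ann >= 0
    if mask is not None:
        good = good & ~np.asarray(mask, dtype=bool)
    safe_ann = np.maximum(ann, 0)
    usable = stats.usable[safe_ann] & good
    mu = stats.mean[safe_ann]
    sigma = stats.sigma[safe_ann]
    with np.errstate(invalid="ignore"):
        threshold = np.maximum(options.adc_threshold, mu + options.min_snr * sigma)
        candidates = usable & (image > threshold)

    labels, n_regions = ndimage.label(candidates, structure=_EIGHT_CONNECTED)
    if n_regions == 0:
        return []
    flat_lab = labels.ravel()
    inside = flat_lab > 0
    lab = flat_lab[inside]
    excess = (image - mu).ravel()[inside]
    var = (sigma * sigma).ravel()[inside]
    slow_idx, fast_idx = np.indices(image.shape)
    fa = fast_idx.ravel()[inside].astype(float)
    sl = slow_idx.ravel()[inside].astype(float)

    n_px = np.bincount(lab, minlength=n_regions + 1)
    intensity = np.bincount(lab, weights=excess, minlength=n_regions + 1)
    noise = np.sqrt(np.bincount(lab, weights=var, minlength=n_regions + 1))
    cf = np.bincount(lab, weights=excess * fa, minlength=n_regions + 1)
    cs = np.bincount(lab, weights=excess * sl, minlength=n_regions + 1)

    out: list[Peak] = []
    for r in range(1, n_regions + 1):
        if not options.min_pix <= n_px[r] <= options.max_pix:
            continue
        if intensity[r] <= 0 or noise[r] <= 0:
            continue
        snr = intensity[r] / noise[r]
        if snr < options.min_snr:
            continue
        out.append(
            Peak(
                fast=float(cf[r] / intensity[r]),
                slow=float(cs[r] / intensity[r]),
                intensity=float(intensity[r]),
                snr=float(snr),
                n_pixels=int(n_px[r]),
            )
        )
    out.sort(key=lambda p: (-p.intensity, p.fast, p.slow))
    return out


# ---------------------------------------------------------------------------
# TSV peak lists

_COLUMNS = ["fast", "slow", "intensity", "snr", "n_pixels"]


def write_peaks(path, peaks: list[Peak]) -> None:
    df = pd.DataFrame(
        [(p.fast, p.slow, p.intensity, p.snr, p.n_pixels) for p in peaks], columns=_COLUMNS
    )
    # default float formatting is the shortest round-trip repr
    df.to_csv(path, sep="\t", index=False)


def read_peaks(path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        Peak(
            fast=float(r.fast),
            slow=float(r.slow),
            intensity=float(r.intensity),
            snr=float(r.snr),
            n_pixels=int(r.n_pixels),
        )
        for r in df.itertuples()
    ]
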