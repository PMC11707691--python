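"""FFT-based autoindexing of still diffraction patterns.

The algorithm reconstructs the direct-space lattice basis from the
reciprocal-space positions of the Bragg peaks, in the spirit of the DirAx
one-dimensional periodicity search but with the periodicity detected by a
fast Fourier transform:

1. map peaks to reciprocal space via the Ewald construction;
2. form triplets of reciprocal points — the normal of the plane through any
   three lattice points is parallel to a direct-space lattice vector;
3. for each triplet, project *all* points onto the normal, histogram the
   signed distances into 1024 bins, Fourier-transform the histogram and take
   the strongest in-band frequency as a candidate repeat; refine the repeat
   by closed-form least squares over the points close to integer multiples,
   and accept the candidate direct-space vector if more than six points fit;
4. merge duplicate candidates and pick the three shortest independent
   vectors whose cell volume matches the reference cell (when given);
5. return the oriented cell for prediction and integration.

Per-operation functions implement one triplet at a time; ``asdf_index`` runs
the identical arithmetic batched over all triplets for speed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import DetectorGeometry, ReciprocalPeak, map_peaks_to_reciprocal
from .lattice import UnitCell, check_cell

__all__ = [
    "AsdfOptions",
    "Triplet",
    "CandidateVector",
    "IndexingResult",
    "generate_triplets",
    "project_distances",
    "periodicity_histogram",
    "fft_candidate_length",
    "refine_repeat",
    "merge_candidates",
    "find_basis",
    "asdf_index",
]


@dataclass
class AsdfOptions:
    """Tuning knobs for the periodicity search.

    ``max_triplets``/``max_points`` default to the full-search limits; the
    fast variant (:meth:`fast`) lowers them to 10000 triplets over the 120
    strongest reflections.  ``direct_length_max`` defaults to 1.2x the
    longest reference axis when a reference cell is supplied, else 250 A.
    """

    max_triplets: int = 20000
    max_points: int = 2000
    n_bins: int = 1024
    fit_tolerance: float = 0.15
    min_fit_points: int = 7
    volume_tolerance: float = 0.10
    direct_length_min: float = 2.0
    direct_length_max: float | None = None
    rng_seed: int = 0
    combination_budget: int = 100
    #: before basis assembly, drop candidates whose fit count is below this
    #: fraction of the best candidate's (chance fits pass the >6 rule easily)
    candidate_fit_fraction: float = 0.75
    #: refine the assembled basis by least squares over all indexed points
    refine_basis: bool = True

    def __post_init__(self) -> None:
        if self.max_points < 3:
            raise ValueError("max_points must be at least 3")
        if self.n_bins & (self.n_bins - 1):
            raise ValueError("n_bins must be a power of two")
        if not 0.0 < self.fit_tolerance < 0.5:
            raise ValueError("fit_tolerance must lie in (0, 0.5)")

    @classmethod
    def fast(cls, **kwargs) -> "AsdfOptions":
        """Reduced-limit options: 10000 triplets over 120 reflections."""
        kwargs.setdefault("max_triplets", 10000)
        kwargs.setdefault("max_points", 120)
        return cls(**kwargs)

    def resolved_length_max(self, reference: UnitCell | None) -> float:
        if self.direct_length_max is not None:
            return self.direct_length_max
        if reference is not None:
            return 1.2 * max(np.linalg.norm(reference.basis[:, i]) for i in range(3))
        return 250.0


@dataclass
class Triplet:
    indices: tuple[int, int, int]
    n_hat: np.ndarray


@dataclass
class CandidateVector:
    """A direct-space lattice-vector hypothesis ``t = n_hat / p_refined``."""

    t: np.ndarray
    length: float
    n_fit: int
    source_count: int = 1


@dataclass
class IndexingResult:
    success: bool
    cell: UnitCell | None = None
    n_candidates: int = 0
    failure_reason: str | None = None


def _as_q_array(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        q = np.asarray(points, dtype=float)
    else:
        q = np.array([np.asarray(p.q, dtype=float) for p in points])
    if q.ndim != 2 or q.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of reciprocal points")
    return q


def _order_and_truncate(points: Sequence[ReciprocalPeak], max_points: int):
    order = sorted(range(len(points)), key=lambda i: (-points[i].intensity, i))
    order = order[:max_points]
    return [points[i] for i in order]


def _triplet_normals(q: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit plane normals for index triples; flags collinear triples."""
    v1 = q[idx[:, 1]] - q[idx[:, 0]]
    v2 = q[idx[:, 2]] - q[idx[:, 0]]
    n = np.cross(v1, v2)
    norms = np.linalg.norm(n, axis=1)
    scale = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    ok = norms > 1e-9 * np.maximum(scale, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_hat = n / norms[:, None]
    return n_hat, ok


def _sample_index_triples(n: int, count: int, rng: np.random.Generator) -> np.ndarray:
    """``count`` distinct sorted index triples drawn uniformly at random."""
    seen: set[tuple[int, int, int]] = set()
    out = []
    while len(out) < count:
        draw = rng.integers(0, n, size=(max(4 * (count - len(out)), 64), 3))
        for row in draw:
            a, b, c = sorted(int(x) for x in row)
            if a == b or b == c:
                continue
            key = (a, b, c)
            if key in seen:
                continue
            seen.add(key)
            out.append(key)
            if len(out) == count:
                break
    return np.array(out, dtype=np.intp)


def generate_triplets(points: Sequence[ReciprocalPeak], options: AsdfOptions) -> list[Triplet]:
    """Plane-normal triplets over the strongest ``max_points`` reflections.

    All combinations when there are at most ``max_triplets`` of them, else a
    seeded random sample of distinct index triples; collinear triples are
    dropped (and resampled, in the random branch, so the requested count is
    met whenever enough non-collinear triples exist).
    """
    if len(points) < 3:
        raise ValueError("need at least three reciprocal points")
    pts = _order_and_truncate(points, options.max_points)
    q = _as_q_array(pts)
    n = len(pts)
    n_comb = math.comb(n, 3)
    if n_comb <= options.max_triplets:
        idx = np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)
        n_hat, ok = _triplet_normals(q, idx)
        return [Triplet(tuple(map(int, idx[i])), n_hat[i]) for i in np.nonzero(ok)[0]]

    rng = np.random.default_rng(options.rng_seed)
    seen: set[tuple[int, int, int]] = set()
    triplets: list[Triplet] = []
    while len(triplets) < options.max_triplets and len(seen) < n_comb:
        need = options.max_triplets - len(triplets)
        idx = _sample_index_triples(n, need, rng)
        fresh = [tuple(map(int, row)) for row in idx if tuple(map(int, row)) not in seen]
        seen.update(fresh)
        if not fresh:
            continue
        idx = np.array(fresh, dtype=np.intp)
        n_hat, ok = _triplet_normals(q, idx)
        triplets.extend(Triplet(tuple(map(int, idx[i])), n_hat[i]) for i in np.nonzero(ok)[0])
    return triplets


def project_distances(points, n_hat: np.ndarray) -> np.ndarray:
    """Signed distances of all points from the origin along ``n_hat`` (1/A)."""
    n_hat = np.asarray(n_hat, dtype=float)
    if abs(np.linalg.norm(n_hat) - 1.0) > 1e-6:
        raise ValueError("n_hat must be a unit vector")
    return _as_q_array(points) @ n_hat


def periodicity_histogram(distances, n_bins: int = 1024) -> tuple[np.ndarray, float]:
    """Histogram the projected distances into ``n_bins`` linear bins.

    Bin 0 corresponds to the most negative distance and the last bin to the
    most positive (half-open bins, last bin closed).  Returns the histogram
    and the distance range ``R``.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two distances")
    lo, hi = float(d.min()), float(d.max())
    span = hi - lo
    if span <= 0:
        raise ValueError("all distances identical; no periodicity to find")
    idx = np.floor((d - lo) / span * n_bins).astype(np.intp)
    idx[idx == n_bins] = n_bins - 1
    hist = np.bincount(idx, minlength=n_bins).astype(float)
    return hist, span


def fft_candidate_length(
    histogram: np.ndarray, R: float, options: AsdfOptions, length_max: float | None = None
) -> float | None:
    """Strongest in-band Fourier component, as a direct-space length.

    Transform index ``k`` corresponds to ``k`` cycles over the projected
    range ``R``, i.e. a reciprocal repeat ``R/k`` and a direct length
    ``L_k = k/R``.  The DC term is excluded and ``k`` is restricted to the
    direct-length band; returns ``None`` when the band is empty.
    """
    lmax = length_max if length_max is not None else options.resolved_length_max(None)
    mag = np.abs(np.fft.rfft(np.asarray(histogram, dtype=float)))
    k = np.arange(mag.size)
    band = (k >= 1) & (k >= options.direct_length_min * R) & (k <= lmax * R)
    if not np.any(band):
        return None
    k_best = int(k[band][np.argmax(mag[band])])
    return k_best / R


def refine_repeat(
    distances, L0: float, options: AsdfOptions
) -> tuple[float, int] | None:
    """Least-squares refinement of a candidate repeat length.

    With ``p0 = 1/L0`` and multiplicities ``m_i = round(d_i/p0)``, points
    with ``|d_i - m_i p0| <= fit_tolerance * p0`` and ``m_i != 0`` enter the
    closed-form fit ``p = sum(m_i d_i) / sum(m_i^2)``.  The fit count is then
    re-evaluated at the refined repeat, and the candidate is accepted only if
    more than six points remain close to integer multiples.
    Returns ``(refined_length, n_fit)`` or ``None`` on rejection.
    """
    if L0 <= 0:
        raise ValueError("candidate length must be positive")
    d = np.asarray(distances, dtype=float)
    p0 = 1.0 / L0
    m = np.rint(d / p0)
    fit = (np.abs(d - m * p0) <= options.fit_tolerance * p0) & (m != 0)
    s2 = float(np.sum(m[fit] ** 2))
    if s2 == 0.0:
        return None
    p_hat = float(np.sum(m[fit] * d[fit])) / s2
    if p_hat <= 0:
        return None
    m2 = np.rint(d / p_hat)
    n_fit = int(np.sum((np.abs(d - m2 * p_hat) <= options.fit_tolerance * p_hat) & (m2 != 0)))
    if n_fit < options.min_fit_points:
        return None
    return 1.0 / p_hat, n_fit


def merge_candidates(candidates: list[CandidateVector]) -> list[CandidateVector]:
    """Merge candidates equal up to sign (lengths within 1%, directions
    within 3 degrees); the representative keeps the larger fit count and the
    source counts add.  Output sorted by ascending length."""
    cos_tol = math.cos(math.radians(3.0))
    order = sorted(
        range(len(candidates)), key=lambda i: (-candidates[i].n_fit, candidates[i].length, i)
    )
    reps: list[CandidateVector] = []
    rep_units = np.empty((0, 3))
    rep_lengths = np.empty(0)
    for i in order:
        c = candidates[i]
        u = c.t / c.length
        if reps:
            close = (
                np.abs(c.length - rep_lengths) / np.minimum(c.length, rep_lengths) <= 0.01
            ) & (np.abs(rep_units @ u) >= cos_tol)
            hits = np.nonzero(close)[0]
        else:
            hits = ()
        if len(hits):
            reps[int(hits[0])].source_count += c.source_count
        else:
            reps.append(replace(c, t=c.t.copy()))
            rep_units = np.vstack([rep_units, u[None, :]])
            rep_lengths = np.append(rep_lengths, c.length)
    reps.sort(key=lambda c: c.length)
    return reps


def find_basis(
    candidates: list[CandidateVector],
    reference: UnitCell | None,
    options: AsdfOptions,
) -> IndexingResult:
    """Assemble a right-handed cell from the shortest independent candidates.

    Three-combinations are tried in order of increasing total length (up to
    ``combination_budget``); a combination qualifies if the scalar triple
    product of its unit vectors exceeds 0.05 in magnitude and, when a
    reference cell is given, its volume matches the reference volume within
    ``volume_tolerance`` (relative).
    """
    n = len(candidates)
    if n < 3:
        return IndexingResult(False, None, n, "too few candidate vectors")
    cands = sorted(candidates, key=lambda c: c.length)
    # the budgeted shortest-total-length combinations live among the shortest
    # few candidates; a 4x-budget pool keeps the enumeration bounded
    pool = 3
    while math.comb(pool, 3) < 4 * options.combination_budget and pool < len(cands):
        pool += 1
    cands = cands[:pool]
    combos = sorted(
        itertools.combinations(range(len(cands)), 3),
        key=lambda ijk: sum(cands[i].length for i in ijk),
    )[: options.combination_budget]
    saw_independent = False
    for ijk in combos:
        trio = [cands[i] for i in ijk]
        units = np.stack([c.t / c.length for c in trio], axis=1)
        if abs(np.linalg.det(units)) <= 0.05:
            continue
        saw_independent = True
        basis = np.stack([c.t for c in trio], axis=1)
        vol = float(np.linalg.det(basis))
        if vol < 0:
            basis[:, 2] = -basis[:, 2]
            vol = -vol
        if reference is not None:
            if abs(vol - reference.volume) / reference.volume > options.volume_tolerance:
                continue
        return IndexingResult(True, UnitCell(basis), n, None)
    reason = "volume constraint not met" if saw_independent else "no independent basis"
    return IndexingResult(False, None, n, reason)


# ---------------------------------------------------------------------------
# batched periodicity search (identical arithmetic to the per-op functions)


def _batched_candidates(
    q: np.ndarray, idx: np.ndarray, options: AsdfOptions, length_max: float, chunk: int = 4096
) -> list[CandidateVector]:
    n_bins = options.n_bins
    out: list[CandidateVector] = []
    k_axis = np.arange(n_bins // 2 + 1)
    for start in range(0, idx.shape[0], chunk):
        sub = idx[start : start + chunk]
        n_hat, ok = _triplet_normals(q, sub)
        n_hat = n_hat[ok]
        if n_hat.size == 0:
            continue
        D = n_hat @ q.T  # (rows, n_points)
        lo = D.min(axis=1)
        span = D.max(axis=1) - lo
        valid = span > 0
        n_hat, D, lo, span = n_hat[valid], D[valid], lo[valid], span[valid]
        rows = D.shape[0]
        if rows == 0:
            continue
        bins = np.floor((D - lo[:, None]) / span[:, None] * n_bins).astype(np.intp)
        np.minimum(bins, n_bins - 1, out=bins)
        flat = bins + (np.arange(rows)[:, None] * n_bins)
        hist = np.bincount(flat.ravel(), minlength=rows * n_bins).reshape(rows, n_bins)
        mag = np.abs(np.fft.rfft(hist.astype(float), axis=1))
        band = (
            (k_axis[None, :] >= 1)
            & (k_axis[None, :] >= options.direct_length_min * span[:, None])
            & (k_axis[None, :] <= length_max * span[:, None])
        )
        mag = np.where(band, mag, -1.0)
        k_best = np.argmax(mag, axis=1)
        has_band = mag[np.arange(rows), k_best] >= 0
        n_hat, D, span, k_best = n_hat[has_band], D[has_band], span[has_band], k_best[has_band]
        if k_best.size == 0:
            continue
        p0 = span / k_best  # reciprocal repeat from L0 = k/R
        m = np.rint(D / p0[:, None])
        fit = (np.abs(D - m * p0[:, None]) <= options.fit_tolerance * p0[:, None]) & (m != 0)
        s2 = np.sum(np.where(fit, m * m, 0.0), axis=1)
        s1 = np.sum(np.where(fit, m * D, 0.0), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hat = s1 / s2
        good = (s2 > 0) & (p_hat > 0)
        if not np.any(good):
            continue
        n_hat, D, p_hat = n_hat[good], D[good], p_hat[good]
        m2 = np.rint(D / p_hat[:, None])
        fit2 = (np.abs(D - m2 * p_hat[:, None]) <= options.fit_tolerance * p_hat[:, None]) & (
            m2 != 0
        )
        n_fit = fit2.sum(axis=1)
        L = 1.0 / p_hat
        accept = (
            (n_fit >= options.min_fit_points)
            & (L >= options.direct_length_min)
            & (L <= length_max)
        )
        rows_ok = np.nonzero(accept)[0]
        if rows_ok.size == 0:
            continue
        # polish each candidate in 3D: t = argmin sum_fit (q_i . t - m_i)^2.
        # The 1D repeat fit cannot correct the triplet normal's direction
        # noise; the joint fit recovers the lattice vector itself.
        t0 = n_hat[rows_ok] * L[rows_ok, None]
        W = fit2[rows_ok].astype(float)
        A = np.einsum("rn,ni,nj->rij", W, q, q)
        bvec = np.einsum("rn,ni->ri", W * m2[rows_ok], q)
        tr = np.einsum("rii->r", A)
        solvable = np.abs(np.linalg.det(A)) > 1e-12 * np.maximum(tr, 1e-30) ** 3
        t_ref = t0.copy()
        if np.any(solvable):
            t_ref[solvable] = np.linalg.solve(A[solvable], bvec[solvable][..., None])[..., 0]
        H = t_ref @ q.T
        M3 = np.rint(H)
        fit3 = (np.abs(H - M3) <= options.fit_tolerance) & (M3 != 0)
        n_fit3 = fit3.sum(axis=1)
        L3 = np.linalg.norm(t_ref, axis=1)
        keep = (
            (n_fit3 >= options.min_fit_points)
            & (L3 >= options.direct_length_min)
            & (L3 <= length_max)
        )
        for i in np.nonzero(keep)[0]:
            out.append(
                CandidateVector(t=t_ref[i], length=float(L3[i]), n_fit=int(n_fit3[i]))
            )
    return out


def _refine_basis(
    basis: np.ndarray, q: np.ndarray, options: AsdfOptions, n_iter: int = 3
) -> np.ndarray | None:
    """Least-squares refinement of the whole basis against the peak list.

    Points are assigned integer indices ``m = round(q @ B)``; rows whose
    residual (in index units) stays within ``fit_tolerance`` on every
    component enter the linear fit ``q B = m``, refined jointly for
    direction and length.  Returns ``None`` when the fit is unstable.
    """
    B = basis.copy()
    for _ in range(n_iter):
        H = q @ B
        M = np.rint(H)
        good = np.all(np.abs(H - M) <= options.fit_tolerance, axis=1) & np.any(M != 0, axis=1)
        if good.sum() < options.min_fit_points:
            return None
        Q = q[good]
        if np.linalg.matrix_rank(Q) < 3:
            return None
        B_new, *_ = np.linalg.lstsq(Q, M[good], rcond=None)
        if abs(np.linalg.det(B_new)) < 1e-9:
            return None
        B = B_new
    return B


def asdf_index(
    peaks: Sequence,
    geometry: DetectorGeometry,
    reference: UnitCell | None = None,
    options: AsdfOptions | None = None,
) -> IndexingResult:
    """Run the full autoindexing pipeline on a detector peak list.

    Deterministic for a given ``options.rng_seed``.  Indexing failure is a
    result (with a reason label), not an exception.
    """
    if options is None:
        options = AsdfOptions()
    if not isinstance(geometry, DetectorGeometry):
        raise TypeError("geometry must be a DetectorGeometry")
    if len(peaks) < 7:
        return IndexingResult(False, None, 0, "too few peaks")
    rpeaks = map_peaks_to_reciprocal(peaks, geometry)
    pts = _order_and_truncate(rpeaks, options.max_points)
    q = _as_q_array(pts)
    n = len(pts)
    length_max = options.resolved_length_max(reference)

    n_comb = math.comb(n, 3)
    if n_comb <= options.max_triplets:
        idx = np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)
    else:
        rng = np.random.default_rng(options.rng_seed)
        idx = _sample_index_triples(n, options.max_triplets, rng)

    candidates = _batched_candidates(q, idx, options, length_max)
    if not candidates:
        return IndexingResult(False, None, 0, "no candidate vectors")
    best_fit = max(c.n_fit for c in candidates)
    cutoff = max(options.min_fit_points, options.candidate_fit_fraction * best_fit)
    strong = [c for c in candidates if c.n_fit >= cutoff]
    merged = merge_candidates(strong)
    result = find_basis(merged, reference, options)
    if result.success and options.refine_basis:
        refined = _refine_basis(result.cell.basis, q, options)
        if refined is not None:
            if np.linalg.det(refined) < 0:
                refined[:, 2] = -refined[:, 2]
            cell = UnitCell(refined)
            vol_ok = reference is None or (
                abs(cell.volume - reference.volume) / reference.volume
                <= options.volume_tolerance
            )
            if vol_ok:
                result = IndexingResult(True, cell, result.n_candidates, None)
    if result.success and reference is not None:
        if not check_cell(result.cell, reference).matched:
            return IndexingResult(False, None, result.n_candidates, "reference cell mismatch")
    return result
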