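"""Unit cells, scattering vectors, Niggli reduction and cell comparison.

The :class:`UnitCell` stores direct-space basis vectors and caches the
reciprocal matrix, so that per-reflection scattering vectors are a single
matrix product with no trigonometric calls and no repeated matrix inversion.
Cells are immutable by convention: all operations return new cells, which is
what makes the cached inverse safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "UnitCell",
    "LatticeMatch",
    "cell_from_parameters",
    "scattering_vector",
    "niggli_reduce",
    "g6_vector",
    "check_cell",
    "count_unique_reflections",
    "read_cell",
    "write_cell",
]


class UnitCell:
    """Direct-space lattice basis.

    Parameters
    ----------
    basis:
        3x3 matrix whose *columns* are the direct-space basis vectors
        ``a``, ``b``, ``c`` in Angstrom.  Must be right-handed
        (positive determinant).
    """

    def __init__(self, basis: np.ndarray):
        basis = np.asarray(basis, dtype=float)
        if basis.shape != (3, 3):
            raise ValueError("basis must be a 3x3 matrix of column vectors")
        det = float(np.linalg.det(basis))
        if not np.isfinite(det) or det <= 0:
            raise ValueError("basis must be right-handed with positive volume")
        self._basis = basis.copy()
        self._basis.setflags(write=False)

    @property
    def basis(self) -> np.ndarray:
        return self._basis

    @property
    def a_vec(self) -> np.ndarray:
        return self._basis[:, 0]

    @property
    def b_vec(self) -> np.ndarray:
        return self._basis[:, 1]

    @property
    def c_vec(self) -> np.ndarray:
        return self._basis[:, 2]

    @cached_property
    def volume(self) -> float:
        """Cell volume in A^3."""
        return float(np.linalg.det(self._basis))

    @cached_property
    def reciprocal_matrix(self) -> np.ndarray:
        """Matrix with columns a*, b*, c* (1/A); q(hkl) = M* @ (h,k,l).

        Computed once per cell: ``B^T M* = I``.
        """
        m = np.linalg.inv(self._basis.T)
        m.setflags(write=False)
        return m

    @cached_property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        """Scalar cell parameters (a, b, c in A; alpha, beta, gamma in deg)."""
        a, b, c = (np.linalg.norm(self._basis[:, i]) for i in range(3))
        av, bv, cv = self._basis[:, 0], self._basis[:, 1], self._basis[:, 2]

        def ang(u, v):
            cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

        return (float(a), float(b), float(c), ang(bv, cv), ang(av, cv), ang(av, bv))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        a, b, c, al, be, ga = self.parameters
        return (
            f"UnitCell(a={a:.4f}, b={b:.4f}, c={c:.4f}, "
            f"alpha={al:.3f}, beta={be:.3f}, gamma={ga:.3f})"
        )


@dataclass
class LatticeMatch:
    """Result of comparing two lattices via their Niggli-reduced cells."""

    matched: bool
    g6_candidate: np.ndarray
    g6_reference: np.ndarray
    length_reldev: float
    angle_dev: float


def cell_from_parameters(a, b, c, alpha, beta, gamma) -> UnitCell:
    """Build a cell in the canonical orientation (a along x, b in xy)."""
    for v in (a, b, c):
        if not v > 0:
            raise ValueError("cell lengths must be positive")
    for v in (alpha, beta, gamma):
        if not 0.0 < v < 180.0:
            raise ValueError("cell angles must lie in (0, 180) degrees")
    al, be, ga = (math.radians(x) for x in (alpha, beta, gamma))
    av = np.array([a, 0.0, 0.0])
    bv = np.array([b * math.cos(ga), b * math.sin(ga), 0.0])
    cx = c * math.cos(be)
    cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz2 = c * c - cx * cx - cy * cy
    if cz2 <= 0:
        raise ValueError("cell parameters are not triangle-feasible")
    cv = np.array([cx, cy, math.sqrt(cz2)])
    return UnitCell(np.stack([av, bv, cv], axis=1))


def scattering_vector(cell: UnitCell, h, k, l) -> np.ndarray:
    """Scattering vector(s) ``h a* + k b* + l c*`` (1/A) via the cached matrix.

    Scalars give a 3-vector; equal-shaped arrays give ``(..., 3)``.
    """
    hkl = np.stack(np.broadcast_arrays(np.asarray(h, float), np.asarray(k, float), np.asarray(l, float)), axis=-1)
    return hkl @ cell.reciprocal_matrix.T


def g6_vector(cell: UnitCell) -> np.ndarray:
    """G6 representation (a^2, b^2, c^2, 2bc cos(alpha), 2ca cos(beta), 2ab cos(gamma))."""
    a, b, c = cell.a_vec, cell.b_vec, cell.c_vec
    return np.array(
        [
            float(a @ a),
            float(b @ b),
            float(c @ c),
            2.0 * float(b @ c),
            2.0 * float(a @ c),
            2.0 * float(a @ b),
        ]
    )


# ---------------------------------------------------------------------------
# Niggli reduction (Krivy & Gruber conditional steps on the basis vectors)

# proper sign-flip transforms: diag(i, j, k) with det = +1
_FLIPS = [np.diag(d).astype(float) for d in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]


def niggli_reduce(cell: UnitCell, eps_rel: float = 1e-5, max_iter: int = 1000) -> UnitCell:
    """Return the Niggli-reduced cell of the same lattice.

    Each conditional step is applied directly to the basis vectors through a
    det=+1 integer transform, so the reduced cell is related to the input by
    a unimodular change of basis and keeps the lattice orientation.
    Comparisons use the relative tolerance ``eps_rel``.  Idempotent.
    """
    B = np.array(cell.basis, dtype=float)
    if abs(np.linalg.det(B)) < 1e-12 * float(np.mean(np.abs(B)) or 1.0) ** 3:
        raise ValueError("degenerate (coplanar) basis cannot be reduced")

    def metric(Bm):
        a, b, c = Bm[:, 0], Bm[:, 1], Bm[:, 2]
        return (
            float(a @ a),
            float(b @ b),
            float(c @ c),
            2.0 * float(b @ c),
            2.0 * float(a @ c),
            2.0 * float(a @ b),
        )

    for _ in range(max_iter):
        A, Bq, C, xi, eta, zeta = metric(B)
        eps = eps_rel * (A + Bq + C) / 3.0

        # step 1: order a, b
        if A > Bq + eps or (abs(A - Bq) <= eps and abs(xi) > abs(eta) + eps):
            B = B @ np.array([[0.0, -1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, -1.0]])
            A, Bq, C, xi, eta, zeta = metric(B)
        # step 2: order b, c
        if Bq > C + eps or (abs(Bq - C) <= eps and abs(eta) > abs(zeta) + eps):
            B = B @ np.array([[-1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, -1.0, 0.0]])
            continue

        # steps 3/4: normalize the signs of (xi, eta, zeta) using proper
        # pair flips; the product sign is a lattice invariant
        def signf(x):
            return 1 if x > eps else (-1 if x < -eps else 0)

        sx, se, sz = signf(xi), signf(eta), signf(zeta)
        want_positive = sx * se * sz > 0
        best = None
        for F in _FLIPS:
            Bf = B @ F
            _, _, _, xf, ef, zf = metric(Bf)
            if want_positive:
                ok = xf > -eps and ef > -eps and zf > -eps
            else:
                ok = xf < eps and ef < eps and zf < eps
            if ok:
                best = Bf
                break
        if best is not None:
            B = best
            A, Bq, C, xi, eta, zeta = metric(B)

        # steps 5-8: shear reductions
        if abs(xi) > Bq + eps or (abs(xi - Bq) <= eps and 2 * eta < zeta - eps) or (
            abs(xi + Bq) <= eps and zeta < -eps
        ):
            s = 1.0 if xi > 0 else -1.0
            B = B @ np.array([[1.0, 0.0, 0.0], [0.0, 1.0, -s], [0.0, 0.0, 1.0]])
            continue
        if abs(eta) > A + eps or (abs(eta - A) <= eps and 2 * xi < zeta - eps) or (
            abs(eta + A) <= eps and zeta < -eps
        ):
            s = 1.0 if eta > 0 else -1.0
            B = B @ np.array([[1.0, 0.0, -s], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
            continue
        if abs(zeta) > A + eps or (abs(zeta - A) <= eps and 2 * xi < eta - eps) or (
            abs(zeta + A) <= eps and eta < -eps
        ):
            s = 1.0 if zeta > 0 else -1.0
            B = B @ np.array([[1.0, -s, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
            continue
        total = xi + eta + zeta + A + Bq
        if total < -eps or (abs(total) <= eps and 2 * (A + eta) + zeta > eps):
            B = B @ np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0], [0.0, 0.0, 1.0]])
            continue
        break
    else:
        raise RuntimeError("Niggli reduction did not converge")

    if np.linalg.det(B) < 0:  # transforms are proper, so this cannot trigger
        B[:, 2] = -B[:, 2]
    return UnitCell(B)


def check_cell(
    candidate: UnitCell,
    reference: UnitCell,
    tol_length: float = 0.05,
    tol_angle: float = 1.5,
) -> LatticeMatch:
    """Compare two lattices after Niggli reduction.

    Matched iff every reduced axis length agrees within ``tol_length``
    (relative, symmetric: |x-y| / mean) and every reduced angle within
    ``tol_angle`` degrees.  Symmetric in its arguments.
    """
    rc = niggli_reduce(candidate)
    rr = niggli_reduce(reference)
    pc, pr = rc.parameters, rr.parameters
    length_reldev = max(
        abs(pc[i] - pr[i]) / ((pc[i] + pr[i]) / 2.0) for i in range(3)
    )
    angle_dev = max(abs(pc[i] - pr[i]) for i in range(3, 6))
    return LatticeMatch(
        matched=(length_reldev <= tol_length and angle_dev <= tol_angle),
        g6_candidate=g6_vector(rc),
        g6_reference=g6_vector(rr),
        length_reldev=float(length_reldev),
        angle_dev=float(angle_dev),
    )


# ---------------------------------------------------------------------------
# unique-reflection counting

#: Laue-group operations acting on Miller indices (rows of 3x3 integer
#: matrices applied as op @ hkl).  Friedel mates are merged in both groups.
def _laue_ops(label: str) -> np.ndarray:
    if label == "-1":
        rots = [np.eye(3, dtype=int)]
    elif label == "4/mmm":
        # point group 422 with the 4-fold along c (in index space)
        rots = [
            np.array(m, dtype=int)
            for m in (
                [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
                [[0, -1, 0], [1, 0, 0], [0, 0, 1]],
                [[-1, 0, 0], [0, -1, 0], [0, 0, 1]],
                [[0, 1, 0], [-1, 0, 0], [0, 0, 1]],
                [[1, 0, 0], [0, -1, 0], [0, 0, -1]],
                [[-1, 0, 0], [0, 1, 0], [0, 0, -1]],
                [[0, 1, 0], [1, 0, 0], [0, 0, -1]],
                [[0, -1, 0], [-1, 0, 0], [0, 0, -1]],
            )
        ]
    else:
        raise ValueError(f"unsupported Laue group {label!r}")
    ops = rots + [-r for r in rots]
    return np.stack(ops)


def count_unique_reflections(
    cell: UnitCell, laue_group: str, d_max: float | None, d_min: float
) -> int:
    """Count symmetry-unique reflection classes in a resolution window.

    Classes are Laue-equivalence classes of Miller indices with Friedel
    mates merged; systematically absent reflections are included (merging
    cannot know the space group) and (0,0,0) is excluded.  Both resolution
    bounds are inclusive, with a 1e-9 relative slack so that classes landing
    exactly on a bound are kept; ``d_max=None`` applies no low-resolution
    cutoff.  The 4/mmm group assumes the tetragonal axis is ``c``.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if d_max is not None and d_max <= d_min:
        raise ValueError("d_max must exceed d_min")
    ops = _laue_ops(laue_group)

    # |h| = |q . a_vec| <= |a| / d_min bounds each index
    lens = [float(np.linalg.norm(cell.basis[:, i])) for i in range(3)]
    hmax, kmax, lmax = (int(math.floor(L / d_min)) + 1 for L in lens)
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = hkl @ cell.reciprocal_matrix.T
    d = 1.0 / np.linalg.norm(q, axis=1)
    keep = d >= d_min * (1.0 - 1e-9)
    if d_max is not None:
        keep &= d <= d_max * (1.0 + 1e-9)
    hkl = hkl[keep]
    if hkl.size == 0:
        return 0

    # representative = lexicographically greatest equivalent; encode tuples
    # into single integers so the max / unique steps stay vectorized
    equiv = np.einsum("oij,nj->noi", ops, hkl)  # (n, n_ops, 3)
    span = int(np.abs(equiv).max()) + 1
    base = 2 * span + 1
    enc = (
        (equiv[..., 0] + span) * base * base
        + (equiv[..., 1] + span) * base
        + (equiv[..., 2] + span)
    )
    reps = enc.max(axis=1)
    return int(np.unique(reps).size)


# ---------------------------------------------------------------------------
# plain-text cell files

_CELL_KEYS = {"a": 0, "b": 1, "c": 2, "al": 3, "alpha": 3, "be": 4, "beta": 4, "ga": 5, "gamma": 5}


def read_cell(path) -> UnitCell:
    """Read cell parameters from a ``key = value`` file or a CRYST1 line.

    Lengths in Angstrom, angles in degrees.  An optional ``lattice_type`` /
    ``centering`` entry is accepted and ignored for the primitive maths.
    """
    params = [None] * 6
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("CRYST1"):
                fields = line.split()
                vals = [float(x) for x in fields[1:7]]
                return cell_from_parameters(*vals)
            key, _, val = line.partition("=")
            key = key.strip().lower()
            if key in ("lattice_type", "centering"):
                continue
            if key in _CELL_KEYS and _:
                params[_CELL_KEYS[key]] = float(val.strip())
    if any(p is None for p in params):
        raise ValueError("cell file does not define all six parameters")
    return cell_from_parameters(*params)


def write_cell(path, cell: UnitCell) -> None:
    a, b, c, al, be, ga = cell.parameters
    with open(path, "w") as fh:
        for key, val in zip(("a", "b", "c", "al", "be", "ga"), (a, b, c, al, be, ga)):
            fh.write(f"{key} = {val!r}\n")
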