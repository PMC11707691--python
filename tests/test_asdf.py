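"""The FFT periodicity search and basis assembly, op by op."""

import itertools
import math

import numpy as np
import pytest

from serialindex.asdf import (
    AsdfOptions,
    CandidateVector,
    asdf_index,
    fft_candidate_length,
    find_basis,
    generate_triplets,
    merge_candidates,
    periodicity_histogram,
    project_distances,
    refine_repeat,
)
from serialindex.geometry import ReciprocalPeak
from serialindex.lattice import UnitCell, cell_from_parameters, check_cell
from serialindex.simulate import LYSOZYME_CELL, random_orientation, simulate_peaks


def rpeaks(q_array, intensities=None):
    q_array = np.asarray(q_array, dtype=float)
    if intensities is None:
        intensities = np.arange(len(q_array), 0, -1, dtype=float)
    return [ReciprocalPeak(q=q, intensity=float(i)) for q, i in zip(q_array, intensities)]


class TestGenerateTriplets:
    def test_three_points_one_triplet(self, rng):
        pts = rpeaks(rng.normal(size=(3, 3)))
        assert len(generate_triplets(pts, AsdfOptions())) == 1

    def test_five_points_exhaustive(self, rng):
        pts = rpeaks(rng.normal(size=(5, 3)))
        tris = generate_triplets(pts, AsdfOptions())
        assert len(tris) == math.comb(5, 3)
        assert len({t.indices for t in tris}) == len(tris)

    def test_large_input_samples_exact_count(self, rng):
        """2000 points trigger sampling of exactly 20000 distinct triplets."""
        pts = rpeaks(rng.normal(size=(2000, 3)), intensities=rng.exponential(1.0, 2000))
        tris = generate_triplets(pts, AsdfOptions(rng_seed=3))
        assert len(tris) == 20000
        assert len({t.indices for t in tris}) == 20000

    def test_truncates_to_strongest(self, rng):
        q = rng.normal(size=(30, 3))
        inten = np.arange(30, dtype=float)  # strongest are the last ones
        pts = rpeaks(q, inten)
        opts = AsdfOptions(max_points=5)
        tris = generate_triplets(pts, opts)
        assert len(tris) == math.comb(5, 3)

    def test_collinear_dropped(self):
        q = np.array([[0.0, 0, 0.1], [0, 0, 0.2], [0, 0, 0.3], [0.1, 0, 0.1]])
        tris = generate_triplets(rpeaks(q), AsdfOptions())
        assert len(tris) == math.comb(4, 3) - 1

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_triplets(rpeaks(rng.normal(size=(2, 3))), AsdfOptions())

    def test_unit_normals(self, rng):
        pts = rpeaks(rng.normal(size=(8, 3)))
        for t in generate_triplets(pts, AsdfOptions()):
            assert np.linalg.norm(t.n_hat) == pytest.approx(1.0)


class TestProjectDistances:
    def test_dot_product(self):
        d = project_distances(rpeaks([[0.3, 0.1, 0.05]]), np.array([0.0, 0.0, 1.0]))
        assert d[0] == pytest.approx(0.05)

    def test_antisymmetry(self, rng):
        q = rng.normal(size=(12, 3))
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        assert np.allclose(
            project_distances(rpeaks(q), -n), -project_distances(rpeaks(q), n)
        )

    def test_rotation_invariance(self, rng):
        q = rng.normal(size=(15, 3))
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        R = random_orientation(9)
        d1 = project_distances(rpeaks(q), n)
        d2 = project_distances(rpeaks(q @ R.T), R @ n)
        assert np.allclose(d1, d2, atol=1e-12)

    def test_non_unit_normal_rejected(self, rng):
        with pytest.raises(ValueError):
            project_distances(rpeaks(rng.normal(size=(4, 3))), np.array([1.0, 1.0, 0.0]))


class TestPeriodicityHistogram:
    def test_two_distances_occupy_endpoints(self):
        hist, R = periodicity_histogram([0.1, -0.4])
        assert R == pytest.approx(0.5)
        assert hist[0] == 1 and hist[-1] == 1 and hist.sum() == 2

    def test_counts_conserved(self, rng):
        d = rng.normal(size=500)
        hist, _ = periodicity_histogram(d)
        assert hist.sum() == 500

    def test_uniform_grid_pigeonhole(self):
        d = np.linspace(-1.0, 1.0, 1025)
        hist, _ = periodicity_histogram(d, n_bins=1024)
        assert (hist > 0).all()

    def test_identical_distances_rejected(self):
        with pytest.raises(ValueError):
            periodicity_histogram([0.2, 0.2, 0.2])


def brute_force_period_scan(distances, options, length_max):
    """Oracle: scan direct lengths, maximizing the fitting-point count."""
    best_L, best_n = None, -1
    for L in np.linspace(options.direct_length_min, length_max, 20000):
        p = 1.0 / L
        m = np.rint(np.asarray(distances) / p)
        n = int(np.sum((np.abs(distances - m * p) <= 0.02 * p) & (m != 0)))
        if n > best_n:
            best_n, best_L = n, L
    return best_L


class TestFftCandidateLength:
    def test_exact_grid_recovers_length(self):
        d = np.arange(0, 11) * 0.0125  # repeat 0.0125 1/A -> 80 A
        opts = AsdfOptions()
        hist, R = periodicity_histogram(d)
        L = fft_candidate_length(hist, R, opts, length_max=95.0)
        oracle = brute_force_period_scan(d, opts, 95.0)
        assert L == pytest.approx(80.0, abs=80.0 / (R * 1024) * 1024 / 10)
        assert abs(L - oracle) < 8.0  # both identify the 80 A family
        ref = refine_repeat(d, L, opts)
        assert ref is not None
        assert ref[0] == pytest.approx(80.0, rel=1e-9)

    def test_scaling(self, rng):
        d = np.sort(rng.normal(size=200)) * 0.01
        opts = AsdfOptions()
        h1, R1 = periodicity_histogram(d)
        h2, R2 = periodicity_histogram(2 * d)
        L1 = fft_candidate_length(h1, R1, opts, length_max=250.0)
        L2 = fft_candidate_length(h2, R2, opts, length_max=250.0)
        assert L2 == pytest.approx(L1 / 2)

    def test_empty_band_returns_none(self):
        hist, R = periodicity_histogram([0.0, 1.0])
        opts = AsdfOptions(direct_length_min=2.0)
        assert fft_candidate_length(hist, R, opts, length_max=0.5) is None

    def test_noise_rarely_survives_refinement(self, rng):
        """Pure-noise projections must fail the >6-fit acceptance."""
        opts = AsdfOptions()
        survived = 0
        for trial in range(100):
            d = np.random.default_rng(trial).uniform(-0.3, 0.3, size=30)
            hist, R = periodicity_histogram(d)
            L = fft_candidate_length(hist, R, opts, length_max=95.0)
            if L is None:
                continue
            ref = refine_repeat(d, L, AsdfOptions(fit_tolerance=0.02))
            if ref is not None:
                survived += 1
        assert survived <= 1


class TestRefineRepeat:
    def test_exact_multiples(self):
        p = 0.0125
        d = np.arange(-5, 6) * p
        res = refine_repeat(d, 1 / p, AsdfOptions())
        assert res is not None
        L, n_fit = res
        assert L == pytest.approx(1 / p, rel=1e-12)
        assert n_fit == 10  # m = 0 carries no information

    @pytest.mark.parametrize("n_points,accepted", [(6, False), (7, True)])
    def test_acceptance_boundary(self, n_points, accepted):
        p = 0.02
        d = np.arange(1, n_points + 1) * p
        res = refine_repeat(d, 1 / p, AsdfOptions())
        assert (res is not None) == accepted

    def test_closed_form_oracle(self, rng):
        p = 0.017
        m = np.array([-4, -2, -1, 1, 2, 3, 5, 7, 9])
        d = m * p + rng.normal(0, 0.0005, size=m.size)
        opts = AsdfOptions()
        res = refine_repeat(d, 1 / p, opts)
        assert res is not None
        m0 = np.rint(d / p)
        fit = (np.abs(d - m0 * p) <= opts.fit_tolerance * p) & (m0 != 0)
        p_expected = float(np.sum(m0[fit] * d[fit]) / np.sum(m0[fit] ** 2))
        assert res[0] == pytest.approx(1 / p_expected, rel=1e-12)

    def test_all_zero_multiplicities_rejected(self):
        d = np.array([0.001, -0.001, 0.002, 0.0, 0.0015, -0.002, 0.0005])
        assert refine_repeat(d, 1.0, AsdfOptions()) is None


class TestMergeCandidates:
    def c(self, t, n_fit=10):
        t = np.asarray(t, dtype=float)
        return CandidateVector(t=t, length=float(np.linalg.norm(t)), n_fit=n_fit)

    def test_sign_insensitive(self):
        merged = merge_candidates([self.c([10, 0, 0], 12), self.c([-10, 0, 0], 9)])
        assert len(merged) == 1
        assert merged[0].n_fit == 12 and merged[0].source_count == 2

    def test_orthogonal_kept(self):
        merged = merge_candidates([self.c([10, 0, 0]), self.c([0, 10, 0])])
        assert len(merged) == 2

    def test_matches_exhaustive_clustering(self, rng):
        cands = []
        for _ in range(40):
            base = rng.choice([10.0, 20.0, 35.0])
            axis = rng.integers(0, 3)
            t = np.zeros(3)
            t[axis] = base * (1 + rng.uniform(-0.002, 0.002)) * rng.choice([-1, 1])
            cands.append(self.c(t, int(rng.integers(7, 40))))
        merged = merge_candidates(cands)
        # oracle: connected components under the same pair metric
        def same(a, b):
            ua, ub = a.t / a.length, b.t / b.length
            return (
                abs(a.length - b.length) / min(a.length, b.length) <= 0.01
                and abs(float(ua @ ub)) >= math.cos(math.radians(3))
            )

        n = len(cands)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(n), 2):
            if same(cands[i], cands[j]):
                parent[find(i)] = find(j)
        assert len(merged) == len({find(i) for i in range(n)})

    def test_sorted_by_length(self, rng):
        cands = [self.c(rng.normal(size=3) * 20) for _ in range(15)]
        merged = merge_candidates(cands)
        lengths = [c.length for c in merged]
        assert lengths == sorted(lengths)


class TestFindBasis:
    def cv(self, t, n_fit=30):
        t = np.asarray(t, float)
        return CandidateVector(t=t, length=float(np.linalg.norm(t)), n_fit=n_fit)

    def test_orthogonal_candidates(self, lysozyme_cell):
        cands = [
            self.cv([79.2, 0, 0]),
            self.cv([0, 79.2, 0]),
            self.cv([0, 0, 38.0]),
            self.cv([79.2, 79.2, 0]),
        ]
        res = find_basis(cands, lysozyme_cell, AsdfOptions())
        assert res.success
        assert res.cell.volume == pytest.approx(79.2 * 79.2 * 38.0, rel=1e-3)

    def test_right_handed_output(self):
        cands = [self.cv([0, 0, 38.0]), self.cv([0, 79.2, 0]), self.cv([79.2, 0, 0])]
        res = find_basis(cands, None, AsdfOptions())
        assert res.success and res.cell.volume > 0

    def test_coplanar_failure(self):
        cands = [self.cv([10, 0, 0]), self.cv([0, 10, 0]), self.cv([7, 7, 0])]
        res = find_basis(cands, None, AsdfOptions())
        assert not res.success and res.failure_reason == "no independent basis"

    def test_volume_constraint_active(self):
        ref = cell_from_parameters(30, 30, 30, 90, 90, 90)
        cands = [self.cv([10, 0, 0]), self.cv([0, 10, 0]), self.cv([0, 0, 10])]
        res = find_basis(cands, ref, AsdfOptions())
        assert not res.success and res.failure_reason == "volume constraint not met"

    def test_too_few_candidates_is_result_not_error(self):
        res = find_basis([self.cv([1, 0, 0])], None, AsdfOptions())
        assert not res.success


class TestAsdfIndex:
    def test_recovers_simulated_cell(self, sim_geometry, lysozyme_cell):
        pat = simulate_peaks(seed=3)
        res = asdf_index(pat.peaks, sim_geometry, lysozyme_cell, AsdfOptions(rng_seed=1))
        assert res.success
        m = check_cell(res.cell, pat.true_cell, tol_length=0.01, tol_angle=0.5)
        assert m.matched

    def test_empty_peak_list_fails_gracefully(self, sim_geometry, lysozyme_cell):
        res = asdf_index([], sim_geometry, lysozyme_cell, AsdfOptions())
        assert not res.success and res.failure_reason == "too few peaks"

    def test_deterministic(self, sim_geometry, lysozyme_cell):
        pat = simulate_peaks(seed=8)
        r1 = asdf_index(pat.peaks, sim_geometry, lysozyme_cell, AsdfOptions(rng_seed=4))
        r2 = asdf_index(pat.peaks, sim_geometry, lysozyme_cell, AsdfOptions(rng_seed=4))
        assert r1.success == r2.success
        assert np.array_equal(r1.cell.basis, r2.cell.basis)

    def test_rotation_equivariance(self, sim_geometry, lysozyme_cell):
        """Rotating the pattern rotates the basis; reduced cell unchanged."""
        pat1 = simulate_peaks(seed=3, orientation=random_orientation(0))
        pat2 = simulate_peaks(seed=3, orientation=random_orientation(1))
        r1 = asdf_index(pat1.peaks, sim_geometry, lysozyme_cell, AsdfOptions(rng_seed=1))
        r2 = asdf_index(pat2.peaks, sim_geometry, lysozyme_cell, AsdfOptions(rng_seed=1))
        assert r1.success and r2.success
        from serialindex.lattice import niggli_reduce

        assert np.allclose(
            niggli_reduce(r1.cell).parameters, niggli_reduce(r2.cell).parameters, atol=0.3
        )

    def test_fast_options_limits(self):
        opts = AsdfOptions.fast()
        assert opts.max_triplets == 10000 and opts.max_points == 120

    def test_null_patterns_rarely_index(self, sim_geometry, lysozyme_cell):
        """Uniform random reciprocal points (no lattice) pass the volume
        constraint against the reference in at most 5% of 100 trials."""
        from serialindex.peaks import Peak

        rng = np.random.default_rng(7)
        false_positives = 0
        for trial in range(100):
            n = int(rng.integers(25, 61))
            peaks = [
                Peak(
                    fast=float(rng.uniform(0, sim_geometry.n_fast - 1)),
                    slow=float(rng.uniform(0, sim_geometry.n_slow - 1)),
                    intensity=float(rng.exponential(1000.0)),
                    snr=0.0,
                    n_pixels=1,
                )
                for _ in range(n)
            ]
            res = asdf_index(peaks, sim_geometry, lysozyme_cell, AsdfOptions(rng_seed=trial))
            false_positives += res.success
        assert false_positives <= 5
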