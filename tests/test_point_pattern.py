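import numpy as np
import pytest

from geoprev import (
    InvalidArgumentError,
    PlanarPointPattern,
    RGrid,
    StudyWindow,
    cross_k,
    cross_l,
    dclf_test,
    difference_k,
    envelope,
    khat,
)

from .conftest import make_marked_pattern


# ---------------------------------------------------------------------------
# independent O(n^2) double-loop oracles
# ---------------------------------------------------------------------------


def brute_k(points, area, r_values):
    n = len(points)
    out = np.zeros(len(r_values))
    for k, r in enumerate(r_values):
        c = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.hypot(*(points[i] - points[j])) <= r:
                    c += 1
        out[k] = area / (n * (n - 1)) * c
    return out


def brute_cross_k(a, b, area, r_values):
    out = np.zeros(len(r_values))
    for k, r in enumerate(r_values):
        c = 0
        for p in a:
            for q in b:
                if np.hypot(*(p - q)) <= r:
                    c += 1
        out[k] = area / (len(a) * len(b)) * c
    return out


class TestKhat:
    def test_two_points_step_function(self):
        win = StudyWindow.square(20_000.0)
        pts = np.array([[1000.0, 1000.0], [1000.0, 6000.0]])  # distance 5000
        pat = PlanarPointPattern(pts, win)
        grid = RGrid(10_000.0, 1000.0)
        k = khat(pat, grid)
        r = grid.values
        assert np.all(k[r < 5000] == 0.0)
        assert np.all(k[r >= 5000] == win.area)

    def test_non_decreasing(self, km100_window):
        pat = make_marked_pattern(40, km100_window, seed=2)
        k = khat(pat, RGrid(50_000.0, 500.0))
        assert np.all(np.diff(k) >= 0)

    def test_matches_brute_force(self, km100_window):
        pat = make_marked_pattern(30, km100_window, seed=7)
        grid = RGrid(60_000.0, 6000.0)
        expected = brute_k(pat.points, km100_window.area, grid.values)
        assert np.allclose(khat(pat, grid), expected, atol=1e-12, rtol=0)

    def test_requires_two_points(self, km100_window):
        pat = PlanarPointPattern(np.array([[1.0, 1.0]]), km100_window)
        with pytest.raises(InvalidArgumentError):
            khat(pat, RGrid(1000.0, 100.0))

    def test_csr_mean_matches_expectation_oracle(self):
        # CSR oracle: E[K_hat(r)] = P(d <= r) for two uniform points in the
        # unit square, which has the closed form pi r^2 - 8/3 r^3 + r^4 / 2.
        # The uncorrected estimator is biased *below* pi r^2 (truncated
        # neighborhoods at the boundary), by ~10% at r = L/8, so the honest
        # comparison is against the exact expectation; agreement with
        # pi r^2 itself within 5% only holds at smaller r (here L/20).
        win = StudyWindow.square(1.0)
        grid = RGrid(0.125, 0.125 / 5)
        rng = np.random.default_rng(42)
        ks = []
        for _ in range(200):
            pts = rng.uniform(0, 1, size=(100, 2))
            ks.append(khat(PlanarPointPattern(pts, win), grid))
        mean_k = np.mean(ks, axis=0)
        r8 = 0.125
        exact = np.pi * r8**2 - 8.0 / 3.0 * r8**3 + r8**4 / 2.0
        assert mean_k[-1] == pytest.approx(exact, rel=0.02)
        r20 = grid.values[2]  # = 0.05 = L/20
        assert mean_k[2] == pytest.approx(np.pi * r20**2, rel=0.05)


class TestCrossK:
    def test_symmetry(self, km100_window):
        pat = make_marked_pattern(40, km100_window, seed=3)
        grid = RGrid(50_000.0, 5000.0)
        assert np.allclose(
            cross_k(pat, "M", "F", grid), cross_k(pat, "F", "M", grid), atol=0
        )

    def test_l_transform_identity(self):
        k = np.pi * np.linspace(0, 10, 11) ** 2
        assert np.allclose(np.sqrt(k / np.pi), np.linspace(0, 10, 11))

    def test_matches_brute_force(self, km100_window):
        pat = make_marked_pattern(50, km100_window, seed=9)
        grid = RGrid(70_000.0, 7000.0)
        expected = brute_cross_k(
            pat.subset("M"), pat.subset("F"), km100_window.area, grid.values
        )
        assert np.allclose(cross_k(pat, "M", "F", grid), expected, atol=1e-12, rtol=0)

    def test_empty_class_errors(self, km100_window):
        pat = make_marked_pattern(10, km100_window, seed=1, male_frac=0.0)
        with pytest.raises(InvalidArgumentError):
            cross_k(pat, "M", "F", RGrid(1000.0, 100.0))


class TestDifferenceK:
    def test_identical_coordinate_sets_give_zero(self, km100_window):
        rng = np.random.default_rng(5)
        locs = rng.uniform(0, 100_000, size=(15, 2))
        pts = np.vstack([locs, locs])
        marks = np.array(["M"] * 15 + ["F"] * 15, dtype=object)
        pat = PlanarPointPattern(pts, km100_window, marks)
        d = difference_k(pat, RGrid(50_000.0, 5000.0))
        assert np.allclose(d, 0.0, atol=1e-9)

    def test_label_swap_negates(self, km100_window):
        pat = make_marked_pattern(30, km100_window, seed=6)
        grid = RGrid(50_000.0, 5000.0)
        d1 = difference_k(pat, grid, "M", "F")
        d2 = difference_k(pat, grid, "F", "M")
        assert np.allclose(d1, -d2, atol=0)

    def test_five_point_brute_force(self):
        win = StudyWindow.square(10.0)
        pts = np.array([[1, 1], [2, 1], [5, 5], [8, 8], [8, 1]], dtype=float)
        marks = np.array(["M", "M", "F", "F", "M"], dtype=object)
        pat = PlanarPointPattern(pts, win, marks)
        grid = RGrid(10.0, 0.5)
        m, f = pts[[0, 1, 4]], pts[[2, 3]]
        expected = brute_k(m, win.area, grid.values) - brute_k(f, win.area, grid.values)
        assert np.allclose(difference_k(pat, grid), expected, atol=1e-12, rtol=0)


class TestEnvelope:
    def test_envelope_bounds_are_min_max(self, km100_window):
        pat = make_marked_pattern(40, km100_window, seed=8)
        res = envelope(pat, "cross_l", "random_labeling", n_sim=19, seed=1,
                       rgrid=RGrid(50_000.0, 5000.0))
        assert np.array_equal(res.envelope_lo, res.simulations.min(axis=0))
        assert np.array_equal(res.envelope_hi, res.simulations.max(axis=0))
        assert np.all(res.envelope_lo <= res.envelope_hi)

    def test_degenerate_single_class_collapses(self, km100_window):
        # all-male labels: every permutation is the identity labeling
        pat = make_marked_pattern(20, km100_window, seed=1, male_frac=1.0)
        res = envelope(pat, "k", "random_labeling", n_sim=19, seed=0,
                       rgrid=RGrid(50_000.0, 5000.0))
        assert np.allclose(res.simulations, res.observed[None, :], atol=0)
        assert np.allclose(res.envelope_lo, res.observed, atol=0)

    def test_class_sizes_preserved_and_seed_reproducible(self, km100_window):
        pat = make_marked_pattern(40, km100_window, seed=4, male_frac=0.4)
        grid = RGrid(40_000.0, 4000.0)
        r1 = envelope(pat, "difference_k", "random_labeling", 25, seed=9, rgrid=grid)
        r2 = envelope(pat, "difference_k", "random_labeling", 25, seed=9, rgrid=grid)
        assert np.array_equal(r1.simulations, r2.simulations)
        u1, p1 = dclf_test(r1, alternative="two_sided")
        u2, p2 = dclf_test(r2, alternative="two_sided")
        assert (u1, p1) == (u2, p2)

    def test_observed_equals_direct_estimators(self, km100_window):
        # envelope's internal digitized counting must agree with the
        # straightforward estimator implementations
        pat = make_marked_pattern(45, km100_window, seed=12)
        grid = RGrid(60_000.0, 3000.0)
        res_l = envelope(pat, "cross_l", "random_labeling", 19, 0, grid)
        assert np.allclose(res_l.observed, cross_l(pat, "M", "F", grid), atol=1e-10)
        res_d = envelope(pat, "difference_k", "random_labeling", 19, 0, grid)
        assert np.allclose(res_d.observed, difference_k(pat, grid), atol=1e-8)

    def test_nsim_floor(self, km100_window):
        pat = make_marked_pattern(10, km100_window, seed=0)
        with pytest.raises(InvalidArgumentError):
            envelope(pat, "cross_l", n_sim=5, rgrid=RGrid(1000.0, 100.0))

    def test_rmax_capped_by_window(self, km100_window):
        pat = make_marked_pattern(10, km100_window, seed=0)
        with pytest.raises(InvalidArgumentError):
            envelope(pat, "cross_l", n_sim=19, rgrid=RGrid(1e7, 1e5))


class TestDCLF:
    def test_observed_equals_reference_gives_u0_p1(self, km100_window):
        pat = make_marked_pattern(20, km100_window, seed=1, male_frac=1.0)
        res = envelope(pat, "k", "random_labeling", n_sim=19, seed=0,
                       rgrid=RGrid(50_000.0, 5000.0))
        u, p = dclf_test(res, alternative="two_sided")
        assert u == 0.0
        assert p == 1.0

    def test_null_calibration(self):
        # under random labeling the pseudo-p is uniform; rejection rate at
        # alpha=0.05 should land in the binomial 99% band [0.02, 0.09]
        win = StudyWindow.square(1000.0)
        rng = np.random.default_rng(2024)
        grid = RGrid(250.0, 25.0)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            pat = make_marked_pattern(40, win, seed=int(rng.integers(2**31)))
            res = envelope(pat, "cross_l", "random_labeling", 199,
                           seed=int(rng.integers(2**31)), rgrid=grid)
            _, p = dclf_test(res, alternative="greater")
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_attraction_power(self):
        # coincident male/female clusters: Cross-L attraction must be
        # detected at p <= 0.005 in >= 90% of replicates
        win = StudyWindow.square(100_000.0)
        grid = RGrid(30_000.0, 1500.0)
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            # male/female cases planted in coincident micro-clusters: each
            # male location has a female partner a few hundred meters away
            centers = rng.uniform(20_000, 80_000, size=(60, 2))
            males = centers + rng.normal(0, 200.0, (60, 2))
            females = centers + rng.normal(0, 200.0, (60, 2))
            pts = np.clip(np.vstack([males, females]), 0, 100_000)
            marks = np.array(["M"] * 60 + ["F"] * 60, dtype=object)
            pat = PlanarPointPattern(pts, win, marks)
            res = envelope(pat, "cross_l", "random_labeling", 199, seed=rep, rgrid=grid)
            _, p = dclf_test(res, alternative="greater")
            hits += p <= 0.005
        assert hits / n_rep >= 0.90

    def test_no_simulations_errors(self, km100_window):
        from geoprev.point_pattern import SummaryFunctionResult

        grid = RGrid(1000.0, 100.0)
        res = SummaryFunctionResult(
            rgrid=grid, observed=np.zeros(len(grid)),
            simulations=np.empty((0, len(grid))),
            envelope_lo=np.zeros(len(grid)), envelope_hi=np.zeros(len(grid)),
            statistic="k", null="csr", seed=0,
        )
        with pytest.raises(InvalidArgumentError):
            dclf_test(res)
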