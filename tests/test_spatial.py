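"""G/F/K estimators against brute-force oracles, CSR closed forms, envelopes."""

import numpy as np
import pytest

from mvbkit.geometry import Box3D
from mvbkit.spatial import (
    InsufficientPointsError,
    PointPattern3D,
    Verdict,
    envelope_test,
    f_function,
    g_function,
    k_function,
    lattice_test_points,
)
from mvbkit.synthetic import ProcessSpec, generate_point_pattern


# ------------------------------------------------------- brute-force oracles

def brute_g(points, window, r_grid):
    n = len(points)
    nnd = np.array([
        min(np.linalg.norm(points[i] - points[j]) for j in range(n) if j != i)
        for i in range(n)
    ])
    b = np.array([
        min(min(p - np.asarray(window.lo)), min(np.asarray(window.hi) - p))
        for p in points
    ])
    out = []
    for r in r_grid:
        keep = b >= r
        out.append(np.nan if not keep.any() else np.mean(nnd[keep] <= r))
    return np.array(out)


def brute_f(points, window, sites, r_grid):
    d = np.array([min(np.linalg.norm(s - p) for p in points) for s in sites])
    b = np.array([
        min(min(s - np.asarray(window.lo)), min(np.asarray(window.hi) - s))
        for s in sites
    ])
    out = []
    for r in r_grid:
        keep = b >= r
        out.append(np.nan if not keep.any() else np.mean(d[keep] <= r))
    return np.array(out)


def brute_k(points, window, r_grid):
    n = len(points)
    V = window.volume
    sides = np.asarray(window.hi) - np.asarray(window.lo)
    out = np.zeros(len(r_grid))
    for ridx, r in enumerate(r_grid):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                delta = points[i] - points[j]
                if np.linalg.norm(delta) <= r:
                    total += V / np.prod(sides - np.abs(delta))
        out[ridx] = V / (n * (n - 1)) * total
    return out


@pytest.fixture(scope="module")
def small_pattern():
    window = Box3D((0, 0, 0), (4, 4, 4))
    rng = np.random.default_rng(31)
    pts = rng.uniform(0, 4, (40, 3))
    return PointPattern3D(pts, window)


class TestAgainstBruteForce:
    def test_g_matches_brute_force(self, small_pattern):
        r = np.linspace(0, 1.0, 21)
        est = g_function(small_pattern, r)
        oracle = brute_g(small_pattern.points, small_pattern.window, r)
        np.testing.assert_allclose(est.values, oracle, atol=1e-12)

    def test_f_matches_brute_force(self, small_pattern):
        r = np.linspace(0, 1.0, 21)
        sites = lattice_test_points(small_pattern.window, per_axis=6)
        est = f_function(small_pattern, r, test_points=sites)
        oracle = brute_f(small_pattern.points, small_pattern.window, sites, r)
        np.testing.assert_allclose(est.values, oracle, atol=1e-12)

    def test_k_matches_brute_force(self, small_pattern):
        r = np.linspace(0, 1.0, 11)
        est = k_function(small_pattern, r)
        oracle = brute_k(small_pattern.points, small_pattern.window, r)
        np.testing.assert_allclose(est.values, oracle, rtol=1e-10)


class TestSmallCases:
    def test_g_two_points_jump_at_distance(self):
        window = Box3D((0, 0, 0), (10, 10, 10))
        pts = np.array([[2.0, 5.0, 5.0], [5.0, 5.0, 5.0]])  # distance 3
        r = np.linspace(0, 5, 51)
        est = g_function(PointPattern3D(pts, window), r, correction="none")
        assert (est.values[r < 3] == 0).all()
        assert (est.values[r >= 3] == 1).all()

    def test_border_correction_noop_for_interior_points(self):
        window = Box3D((0, 0, 0), (10, 10, 10))
        rng = np.random.default_rng(2)
        pts = rng.uniform(4, 6, (30, 3))  # ≥ 4 from every face
        r = np.linspace(0, 3.0, 31)
        pat = PointPattern3D(pts, window)
        np.testing.assert_allclose(
            g_function(pat, r).values, g_function(pat, r, correction="none").values
        )

    def test_f_single_central_point(self):
        window = Box3D((0, 0, 0), (2, 2, 2))
        pat = PointPattern3D(np.array([[1.0, 1.0, 1.0]]), window)
        r = np.linspace(0, 1.5, 16)
        sites = lattice_test_points(window, per_axis=8)
        est = f_function(pat, r, correction="none", test_points=sites)
        d = np.linalg.norm(sites - np.array([1.0, 1.0, 1.0]), axis=1)
        expected = (d[:, None] <= r[None, :]).mean(axis=0)
        np.testing.assert_allclose(est.values, expected)
        assert est.values[0] == 0.0  # F(0) = 0

    def test_insufficient_points_errors(self):
        window = Box3D((0, 0, 0), (1, 1, 1))
        one = PointPattern3D(np.array([[0.5, 0.5, 0.5]]), window)
        with pytest.raises(InsufficientPointsError):
            g_function(one)
        with pytest.raises(InsufficientPointsError):
            k_function(one)
        none = PointPattern3D(np.empty((0, 3)), window)
        with pytest.raises(InsufficientPointsError):
            f_function(none)


class TestInvariances:
    def test_monotone_and_bounded(self, small_pattern):
        # raw empirical CDFs are monotone; the reduced-sample correction can
        # dip locally (its denominator shrinks with r) but stays in [0, 1]
        r = np.linspace(0, 1.0, 30)
        for fn in (g_function, f_function):
            raw = fn(small_pattern, r, correction="none").values
            assert (np.diff(raw) >= -1e-12).all()
            corrected = fn(small_pattern, r).values
            vv = corrected[~np.isnan(corrected)]
            assert ((vv >= 0) & (vv <= 1)).all()
        k = k_function(small_pattern, r).values
        assert (np.diff(k) >= -1e-12).all()
        assert (k >= 0).all()

    def test_k_translation_invariant(self, small_pattern):
        r = np.linspace(0, 1.0, 15)
        shifted = small_pattern.translate((5.0, -2.0, 1.5))
        np.testing.assert_allclose(
            k_function(small_pattern, r).values, k_function(shifted, r).values
        )

    def test_k_axis_permutation_invariant(self, small_pattern):
        r = np.linspace(0, 1.0, 15)
        perm = small_pattern.permute_axes((2, 0, 1))
        np.testing.assert_allclose(
            k_function(small_pattern, r).values, k_function(perm, r).values
        )


class TestCSRTheory:
    def test_g_f_match_closed_form_and_each_other(self, frame_window):
        # mean Ĝ, F̂ over simulations vs 1 − exp(−λ(4/3)πr³)
        lam = 0.21
        r = np.linspace(0, 1.4, 30)
        gs, fs = [], []
        for s in range(150):
            pat = generate_point_pattern(ProcessSpec.csr(lam), frame_window, seed=s)
            gs.append(g_function(pat, r).values)
            fs.append(f_function(pat, r, test_points=16).values)
        g_mean = np.nanmean(gs, axis=0)
        f_mean = np.nanmean(fs, axis=0)
        theo = 1 - np.exp(-lam * (4 / 3) * np.pi * r**3)
        assert np.nanmax(np.abs(g_mean - theo)) < 0.03
        assert np.nanmax(np.abs(f_mean - theo)) < 0.03
        assert np.nanmax(np.abs(g_mean - f_mean)) < 0.04

    def test_k_matches_csr_closed_form(self, frame_window):
        r = np.linspace(0, 1.4, 15)
        ks = [
            k_function(
                generate_point_pattern(ProcessSpec.csr(0.21), frame_window, seed=s), r
            ).values
            for s in range(150)
        ]
        theo = (4 / 3) * np.pi * r**3
        rel = np.abs(np.mean(ks, axis=0)[1:] - theo[1:]) / theo[1:]
        assert rel[-5:].max() < 0.10  # where enough pairs accumulate

    def test_thomas_k_exceeds_csr_at_small_r(self, frame_window):
        spec = ProcessSpec.thomas(0.021, 10, cluster_sd=0.25)
        r = np.array([0.0, 0.3, 0.5])
        theo = (4 / 3) * np.pi * r**3
        wins = 0
        n_rep = 60
        for s in range(n_rep):
            pat = generate_point_pattern(spec, frame_window, seed=s)
            if pat.n < 2:
                continue
            k = k_function(pat, r).values
            wins += k[1] > theo[1] and k[2] > theo[2]
        assert wins >= 0.95 * n_rep


class TestEnvelope:
    def test_min_points_floor(self, frame_window):
        pat = generate_point_pattern(ProcessSpec.csr(0.21), frame_window, seed=0, n_points=10)
        with pytest.raises(InsufficientPointsError):
            envelope_test(pat, min_points=25)

    def test_csr_pattern_is_random(self, frame_window):
        pat = generate_point_pattern(ProcessSpec.csr(0.21), frame_window, seed=7)
        res = envelope_test(pat, nsim=100, seed=3)
        assert res.verdict is Verdict.RANDOM

    def test_tight_thomas_is_clustered(self, frame_window):
        spec = ProcessSpec.thomas(0.021, 10, cluster_sd=0.25)
        pat = generate_point_pattern(spec, frame_window, seed=5)
        res = envelope_test(pat, nsim=100, seed=3)
        assert res.verdict is Verdict.CLUSTERED

    def test_envelopes_bracket_simulations(self, frame_window):
        # by construction the band must contain at least (nsim-1)/(nsim+1)
        # of the simulated curves pointwise; re-simulate to check coverage
        pat = generate_point_pattern(ProcessSpec.csr(0.21), frame_window, seed=11)
        res = envelope_test(pat, nsim=50, seed=4)
        assert all(
            np.all((res.lower[f] <= res.upper[f]) | np.isnan(res.lower[f]))
            for f in res.observed
        )
        # observed curve of a fresh CSR sim falls inside the global band
        inside = 0
        for s in range(20):
            sim = generate_point_pattern(
                ProcessSpec.csr(0.21), frame_window, seed=100 + s, n_points=pat.n
            )
            g = g_function(sim, res.r).values
            ok = ~np.isnan(g) & ~np.isnan(res.lower["G"])
            inside += np.all((g[ok] >= res.lower["G"][ok]) & (g[ok] <= res.upper["G"][ok]))
        assert inside >= 17

    def test_pointwise_envelope_available(self, frame_window):
        pat = generate_point_pattern(ProcessSpec.csr(0.21), frame_window, seed=7)
        res = envelope_test(pat, nsim=20, seed=3, envelope_type="pointwise")
        assert res.verdict in set(Verdict)
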