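import itertools

import numpy as np
import pytest

from tomodenoise import metrics as ME
from tomodenoise.io import ParticleList, Volume3D


def _grid_regions(n, size=16, shape=(48, 160, 160)):
    boxes = []
    for z0 in range(0, shape[0], size):
        for y0 in range(0, shape[1], size):
            for x0 in range(0, shape[2], size):
                boxes.append(((z0, y0, x0), size))
    return boxes[: 2 * n]


class TestSNR:
    def _paired_volume(self, offset, n=100, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(0.0, 1.0, size=(48, 160, 160))
        boxes = _grid_regions(n)
        sig, bg = boxes[:n], boxes[n:]
        for (z, y, x), s in sig:
            data[z:z + s, y:y + s, x:x + s] += offset
        return Volume3D(data), ME.RegionSet(sig, "signal"), ME.RegionSet(bg, "background")

    def test_offset_ten_gives_20db(self):
        vol, sig, bg = self._paired_volume(10.0)
        assert ME.estimate_snr(vol, sig, bg) == pytest.approx(20.0, abs=0.5)

    def test_scale_invariance(self):
        # c = 4 is exact in float32, so the ratio-of-powers must be exact too
        vol, sig, bg = self._paired_volume(10.0)
        ref = ME.estimate_snr(vol, sig, bg)
        assert ME.estimate_snr(Volume3D(4.0 * vol.data), sig, bg) == \
            pytest.approx(ref, abs=1e-9)
        assert ME.estimate_snr(Volume3D(4.2 * vol.data.astype(np.float64)), sig, bg) == \
            pytest.approx(ref, abs=1e-5)

    def test_null_offset_strongly_negative(self):
        vol, sig, bg = self._paired_volume(0.0)
        assert ME.estimate_snr(vol, sig, bg) < -15.0

    def test_estimator_converges_with_region_count(self):
        errs = []
        for n in (10, 150):
            vals = [abs(ME.estimate_snr(*self._paired_volume(10.0, n=n, seed=s)) - 20.0)
                    for s in range(6)]
            errs.append(np.mean(vals))
        assert errs[1] < errs[0]

    def test_flat_background_rejected(self):
        vol = Volume3D(np.zeros((32, 32, 32)))
        boxes = [((0, 0, 0), 8)], [((0, 8, 0), 8)]
        with pytest.raises(ValueError):
            ME.estimate_snr(vol, ME.RegionSet(boxes[0]), ME.RegionSet(boxes[1]))


def _brute_force_greedy(found: ParticleList, truth: ParticleList, tol):
    """Independent re-statement of the greedy rule with explicit loops."""
    order = sorted(range(len(found)),
                   key=lambda i: (-found.scores[i], tuple(found.positions[i])))
    taken = set()
    tps = []
    for fi in order:
        best, best_d = None, None
        for ti in range(len(truth)):
            if ti in taken:
                continue
            d = float(np.linalg.norm(found.positions[fi] - truth.positions[ti]))
            if d <= tol and (best_d is None or d < best_d):
                best, best_d = ti, d
        if best is not None:
            taken.add(best)
            tps.append((fi, best, best_d))
    return len(tps), len(found) - len(tps), len(truth) - len(tps)


class TestMatching:
    def test_identical_lists_all_match(self, rng):
        pos = rng.uniform(0, 50, size=(7, 3))
        truth = ParticleList(pos, np.ones(7))
        found = ParticleList(pos, rng.uniform(size=7))
        m = ME.match_particles(found, truth, 1.0)
        assert (m.n_tp, m.n_fp, m.n_fn) == (7, 0, 0)

    def test_empty_found(self):
        truth = ParticleList(np.zeros((4, 3)) + np.arange(4)[:, None] * 10, np.ones(4))
        m = ME.match_particles(ParticleList(np.empty((0, 3)), np.empty(0)), truth, 2.0)
        assert (m.n_tp, m.n_fn) == (0, 4)

    def test_ambiguous_layout_matches_brute_force(self):
        # 5 found / 4 truth with one contested truth position
        truth = ParticleList(np.array([[0., 0, 0], [4, 0, 0], [20, 0, 0], [40, 0, 0]]),
                             np.ones(4))
        found = ParticleList(
            np.array([[2., 0, 0], [3, 0, 0], [20, 0, 1], [40, 0, 1], [60, 0, 0]]),
            np.array([0.9, 0.8, 0.7, 0.6, 0.5]))
        m = ME.match_particles(found, truth, 3.0)
        assert (m.n_tp, m.n_fp, m.n_fn) == _brute_force_greedy(found, truth, 3.0)

    def test_invariants_hold(self, rng):
        truth = ParticleList(rng.uniform(0, 40, size=(10, 3)), np.ones(10))
        found = ParticleList(rng.uniform(0, 40, size=(14, 3)), rng.uniform(size=14))
        m = ME.match_particles(found, truth, 5.0)
        assert m.n_tp + m.n_fp == 14
        assert m.n_tp + m.n_fn == 10
        assert all(d <= 5.0 for _, _, d in m.true_positives)
        assert len({t for _, t, _ in m.true_positives}) == m.n_tp  # one-to-one

    @pytest.mark.parametrize("tols", [(1.0, 2.0), (2.0, 5.0), (5.0, 20.0)])
    def test_tolerance_monotonicity(self, rng, tols):
        truth = ParticleList(rng.uniform(0, 40, size=(10, 3)), np.ones(10))
        found = ParticleList(rng.uniform(0, 40, size=(14, 3)), rng.uniform(size=14))
        lo, hi = tols
        assert (ME.match_particles(found, truth, hi).n_tp
                >= ME.match_particles(found, truth, lo).n_tp)


class TestPrecisionRecallF1:
    def test_perfect(self):
        m = ME.MatchResult([(0, 0, 0.0), (1, 1, 0.0)], [], [])
        assert ME.precision_recall_f1(m) == (1.0, 1.0, 1.0)

    def test_hand_arithmetic(self):
        m = ME.MatchResult([(0, 0, 0.0)] * 3, [9], [7, 8])
        p, r, f1 = ME.precision_recall_f1(m)
        assert (p, r) == (0.75, 0.6)
        assert f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_no_found_convention(self):
        m = ME.MatchResult([], [], [0, 1, 2])
        assert ME.precision_recall_f1(m) == (1.0, 0.0, 0.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            ME.precision_recall_f1(ME.MatchResult([], [0], []))


def _brute_force_pr_auc(found, truth, tol):
    """Exhaustive threshold sweep + trapezoid with best-precision envelope."""
    points = []
    for thr in sorted(set(found.scores), reverse=True):
        keep = found.scores >= thr
        sub = ParticleList(found.positions[keep], found.scores[keep])
        tp, fp, fn = _brute_force_greedy(sub, truth, tol)
        p = 1.0 if tp + fp == 0 else tp / (tp + fp)
        r = tp / (tp + fn)
        points.append((r, p))
    points = [(0.0, points[0][1])] + points
    best = {}
    for r, p in points:
        best[r] = max(best.get(r, 0.0), p)
    xs, ys = zip(*sorted(best.items()))
    return float(np.trapezoid(ys, xs))


class TestPRCurve:
    def _contrived(self):
        truth = ParticleList(np.array([[0., 0, 0], [10, 0, 0], [20, 0, 0]]), np.ones(3))
        found = ParticleList(
            np.array([[0., 0, 1], [10, 0, 1], [50, 0, 0], [20, 0, 1], [60, 0, 0],
                      [70, 0, 0]]),
            np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4]))
        return found, truth

    def test_perfect_ranking_auc_one(self):
        truth = ParticleList(np.array([[0., 0, 0], [10, 0, 0]]), np.ones(2))
        found = ParticleList(np.array([[0., 0, 0], [10, 0, 0], [50, 0, 0]]),
                             np.array([0.9, 0.8, 0.1]))
        _, auc = ME.pr_curve(found, truth, 2.0)
        assert auc == 1.0

    def test_nothing_within_tolerance_auc_zero(self):
        truth = ParticleList(np.array([[0., 0, 0]]), np.ones(1))
        found = ParticleList(np.array([[30., 0, 0], [40., 0, 0]]), np.array([1.0, 0.5]))
        _, auc = ME.pr_curve(found, truth, 2.0)
        assert auc == 0.0

    def test_six_particle_sweep_matches_brute_force(self):
        found, truth = self._contrived()
        _, auc = ME.pr_curve(found, truth, 2.0)
        assert auc == pytest.approx(_brute_force_pr_auc(found, truth, 2.0), abs=1e-12)

    def test_monotone_score_transform_invariance(self):
        found, truth = self._contrived()
        _, auc = ME.pr_curve(found, truth, 2.0)
        warped = ParticleList(found.positions, np.exp(3 * found.scores))
        _, auc2 = ME.pr_curve(warped, truth, 2.0)
        assert auc2 == pytest.approx(auc, abs=1e-12)

    def test_empty_truth_rejected(self):
        found, _ = self._contrived()
        with pytest.raises(ValueError):
            ME.pr_curve(found, ParticleList(np.empty((0, 3)), np.empty(0)), 2.0)


class TestF1VsZscore:
    def test_affine_invariance(self):
        truth = ParticleList(np.array([[0., 0, 0], [10, 0, 0]]), np.ones(2))
        found = ParticleList(np.array([[0., 0, 0], [10, 0, 0], [50, 0, 0]]),
                             np.array([0.9, 0.8, 0.1]))
        pop = np.linspace(0, 1, 200)
        c1 = ME.f1_vs_zscore(found, truth, 2.0, pop)
        warped = ParticleList(found.positions, 5.0 * found.scores + 3.0)
        c2 = ME.f1_vs_zscore(warped, truth, 2.0, 5.0 * pop + 3.0)
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_single_point_equals_full_list_f1(self):
        truth = ParticleList(np.array([[0., 0, 0], [10, 0, 0]]), np.ones(2))
        found = ParticleList(np.array([[0., 0, 0], [10, 0, 0], [50, 0, 0]]),
                             np.array([0.9, 0.8, 0.1]))
        pop = np.linspace(0, 1, 200)
        curve = ME.f1_vs_zscore(found, truth, 2.0, pop, n_points=1)
        m = ME.match_particles(found, truth, 2.0)
        _, _, f1_full = ME.precision_recall_f1(m)
        assert curve[0, 1] == pytest.approx(f1_full)

    def test_zero_variance_population_rejected(self):
        found = ParticleList(np.array([[0., 0, 0]]), np.array([1.0]))
        with pytest.raises(ValueError):
            ME.f1_vs_zscore(found, found, 2.0, np.ones(10))


class TestMeanMatchDistance:
    def test_exact_matches_zero(self):
        m = ME.MatchResult([(0, 0, 0.0), (1, 1, 0.0)], [], [])
        assert ME.mean_match_distance(m) == (0.0, 0.0)

    def test_hand_values_population_std(self):
        m = ME.MatchResult([(0, 0, 1.0), (1, 1, 3.0)], [], [])
        mean, std = ME.mean_match_distance(m)
        assert (mean, std) == (2.0, 1.0)

    def test_uniform_ball_offsets_monte_carlo(self):
        rng = np.random.default_rng(5)
        r = 2.0
        # draw offsets uniformly in a ball of radius 2 by rejection
        offsets = []
        while len(offsets) < 50:
            c = rng.uniform(-r, r, size=3)
            if np.linalg.norm(c) <= r:
                offsets.append(c)
        offsets = np.asarray(offsets)
        truth_pos = rng.uniform(20, 80, size=(50, 3)) + \
            np.arange(50)[:, None] * 0.0
        truth_pos = np.arange(50)[:, None] * np.array([10.0, 0, 0]) + 20
        truth = ParticleList(truth_pos, np.ones(50))
        found = ParticleList(truth_pos + offsets, np.ones(50))
        m = ME.match_particles(found, truth, 4.0)
        mean, _ = ME.mean_match_distance(m)
        oracle = float(np.linalg.norm(offsets, axis=1).mean())
        assert mean == pytest.approx(oracle, rel=1e-9)
        assert mean == pytest.approx(0.75 * r, rel=0.10)  # E|X| = 3/4 r

    def test_no_tp_rejected(self):
        with pytest.raises(ValueError):
            ME.mean_match_distance(ME.MatchResult([], [0], [0]))
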