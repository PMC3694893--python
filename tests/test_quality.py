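import numpy as np
import pytest

from flowmax.fcyton import PARAM_NAMES, FcytonParams
from flowmax.fitting import SolutionCandidate
from flowmax.quality import (SolutionCluster, cluster_solutions,
                             filter_candidates, final_filter, sample_cluster,
                             sensitivity)


def make_candidate(npae=1.0, sens=None, **param_kw):
    base = dict(N=1e4, F0=0.85, Dmu=3.5, Dsigma=1.0,
                Ediv0=40.0, SDdiv0=10.0, Ediv1=10.0, SDdiv1=4.0,
                Edie0=60.0, SDdie0=20.0, Edie1=80.0, SDdie1=30.0)
    base.update(param_kw)
    cand = SolutionCandidate(params=FcytonParams(**base), score=npae, npae=npae)
    cand.sensitivity = sens
    return cand


def box_ranges(cand, half_width=0.1):
    """Symmetric fractional ranges around a candidate's parameter values."""
    x = cand.params.to_array()
    return {name: (x[i] * (1 - half_width), x[i] * (1 + half_width))
            for i, name in enumerate(PARAM_NAMES)}


class TestFilterCandidates:
    def test_keeps_within_window_of_top(self):
        cands = [make_candidate(npae=v) for v in (3.0, 3.05, 3.2)]
        kept = filter_candidates(cands)
        assert [c.npae for c in kept] == [3.0, 3.05]

    def test_all_equal_all_kept(self):
        cands = [make_candidate(npae=2.0) for _ in range(5)]
        assert len(filter_candidates(cands)) == 5

    def test_matches_brute_force(self, rng):
        npaes = rng.random(100) * 10
        cands = [make_candidate(npae=float(v)) for v in npaes]
        kept = filter_candidates(cands)
        expected = {id(c) for c in cands if c.npae <= npaes.min() + 0.1}
        assert {id(c) for c in kept} == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            filter_candidates([])


class TestSensitivity:
    def test_quadratic_profile_closed_form(self):
        """NPAE = base + c (p - p0)^2 must give endpoints p0 +/- sqrt(tol/c)."""
        cand = make_candidate(npae=2.0)
        x0 = cand.params.to_array()
        c = 0.002

        def npae_fn(x):
            return 2.0 + c * float(((x - x0) ** 2).sum())

        ranges = sensitivity(cand, npae_fn, tol=1.0, rtol=1e-4)
        half = np.sqrt(1.0 / c)  # ~22.4
        i = PARAM_NAMES.index("Ediv0")
        lo, hi = ranges["Ediv0"]
        assert lo == pytest.approx(max(5.0, x0[i] - half), rel=1e-2)
        assert hi == pytest.approx(min(150.0, x0[i] + half), rel=1e-2)

    def test_flat_profile_reaches_global_bounds(self):
        cand = make_candidate(npae=2.0)

        def npae_fn(x):
            return 2.0

        ranges = sensitivity(cand, npae_fn, tol=1.0)
        assert ranges["F0"] == (0.0, 1.0)
        assert ranges["N"] == (1e3, 1e5)

    def test_zero_tolerance_degenerate_point(self):
        cand = make_candidate(npae=2.0)
        ranges = sensitivity(cand, lambda x: 2.0, tol=0.0)
        x0 = cand.params.to_array()
        for i, name in enumerate(PARAM_NAMES):
            assert ranges[name] == (x0[i], x0[i])

    def test_range_brackets_point_estimate(self):
        cand = make_candidate(npae=0.5)
        x0 = cand.params.to_array()

        def npae_fn(x):
            return 0.5 + 50.0 * float(np.abs((x - x0) / (np.abs(x0) + 1)).sum())

        ranges = sensitivity(cand, npae_fn, tol=1.0)
        for i, name in enumerate(PARAM_NAMES):
            lo, hi = ranges[name]
            assert lo <= x0[i] <= hi


class TestClustering:
    def test_two_identical_candidates_merge_once(self):
        a = make_candidate(npae=1.0)
        b = make_candidate(npae=1.0)
        a.sensitivity = box_ranges(a)
        b.sensitivity = box_ranges(b)
        clusters = cluster_solutions([a, b])
        assert len(clusters) == 1
        assert clusters[0].ranges == box_ranges(a)
        assert len(clusters[0].members) == 2

    def test_disjoint_f0_ranges_stay_separate(self):
        a = make_candidate(npae=1.0, F0=0.2)
        b = make_candidate(npae=1.1, F0=0.9)
        a.sensitivity = {**box_ranges(a), "F0": (0.1, 0.3)}
        b.sensitivity = {**box_ranges(b), "F0": (0.8, 1.0)}
        clusters = cluster_solutions([a, b])
        assert len(clusters) == 2

    def test_planted_two_group_partition(self, rng):
        """Two planted solution families with disjoint F0 must give 2 clusters."""
        cands = []
        for k in range(10):
            low_group = k < 5
            f0 = 0.2 + 0.02 * rng.random() if low_group else 0.8 + 0.02 * rng.random()
            c = make_candidate(npae=1.0 + 0.01 * k, F0=f0)
            sens = box_ranges(c, half_width=0.05)
            sens["F0"] = (f0 - 0.05, f0 + 0.05)
            c.sensitivity = sens
            cands.append(c)
        clusters = cluster_solutions(cands)
        assert len(clusters) == 2
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [5, 5]

    def test_merged_ranges_subset_of_members(self, rng):
        cands = []
        for k in range(6):
            c = make_candidate(npae=1.0, Ediv0=40 + rng.random())
            c.sensitivity = box_ranges(c, half_width=0.2)
            cands.append(c)
        clusters = cluster_solutions(cands)
        for cl in clusters:
            for m in cl.members:
                for name in PARAM_NAMES:
                    assert cl.ranges[name][0] >= m.sensitivity[name][0] - 1e-12
                    assert cl.ranges[name][1] <= m.sensitivity[name][1] + 1e-12

    def test_average_stays_inside_ranges(self):
        a = make_candidate(npae=1.0, Ediv0=38.0)
        b = make_candidate(npae=1.0, Ediv0=42.0)
        a.sensitivity = box_ranges(a, 0.15)
        b.sensitivity = box_ranges(b, 0.15)
        (cl,) = cluster_solutions([a, b])
        for i, name in enumerate(PARAM_NAMES):
            lo, hi = cl.ranges[name]
            assert lo - 1e-12 <= cl.average[i] <= hi + 1e-12

    def test_missing_sensitivity_errors(self):
        with pytest.raises(ValueError, match="sensitivity"):
            cluster_solutions([make_candidate()])

    def test_deterministic_given_input_order(self, rng):
        cands = []
        for k in range(8):
            c = make_candidate(npae=1.0 + 0.01 * k, Ediv0=35 + k)
            c.sensitivity = box_ranges(c, 0.3)
            cands.append(c)
        r1 = cluster_solutions(cands)
        r2 = cluster_solutions(cands)
        assert [c.ranges for c in r1] == [c.ranges for c in r2]


class TestFinalFilter:
    @staticmethod
    def distance_npae(centre):
        c = np.asarray(centre)

        def fn(x):
            return float(np.abs((x - c) / (np.abs(c) + 1)).sum())

        return fn

    def _cluster(self, cand, width):
        return SolutionCluster(members=[cand], ranges=box_ranges(cand, width),
                               average=cand.params.to_array())

    def test_single_cluster_always_kept(self):
        cand = make_candidate(npae=1.0)
        cl = self._cluster(cand, 0.05)
        kept = final_filter([cl], self.distance_npae(cand.params.to_array()),
                            n_samples=100, seed=0)
        assert kept == [cl]

    def test_bad_cluster_dropped(self):
        good = make_candidate(npae=1.0)
        bad = make_candidate(npae=1.0, Ediv0=120.0, Edie0=10.0, SDdie0=5.0)
        fn = self.distance_npae(good.params.to_array())
        clusters = [self._cluster(good, 0.02), self._cluster(bad, 0.02)]
        kept = final_filter(clusters, fn, n_samples=200, seed=1)
        assert len(kept) == 1
        assert kept[0].members[0] is good

    def test_same_seed_same_medians(self):
        cand = make_candidate(npae=1.0)
        fn = self.distance_npae(cand.params.to_array() * 1.05)
        m1 = final_filter([self._cluster(cand, 0.1)], fn, n_samples=300, seed=9)[0].median_npae
        m2 = final_filter([self._cluster(cand, 0.1)], fn, n_samples=300, seed=9)[0].median_npae
        assert m1 == m2


class TestSampleCluster:
    def _cluster(self):
        cand = make_candidate()
        return SolutionCluster(members=[cand], ranges=box_ranges(cand, 0.2),
                               average=cand.params.to_array())

    def test_draws_inside_ranges(self):
        cl = self._cluster()
        draws = sample_cluster(cl, 250, seed=4)
        lo = np.array([cl.ranges[n][0] for n in PARAM_NAMES])
        hi = np.array([cl.ranges[n][1] for n in PARAM_NAMES])
        assert np.all(draws >= lo) and np.all(draws <= hi)

    def test_degenerate_point_ranges(self):
        cand = make_candidate()
        x0 = cand.params.to_array()
        cl = SolutionCluster(members=[cand],
                             ranges={n: (x0[i], x0[i]) for i, n in enumerate(PARAM_NAMES)},
                             average=x0)
        draws = sample_cluster(cl, 50, seed=0)
        assert np.allclose(draws, x0)

    def test_uniformity_extremes_approached(self):
        cl = self._cluster()
        draws = sample_cluster(cl, 10_000, seed=2)
        lo = np.array([cl.ranges[n][0] for n in PARAM_NAMES])
        hi = np.array([cl.ranges[n][1] for n in PARAM_NAMES])
        width = hi - lo
        assert np.all(draws.min(axis=0) - lo < 0.01 * width)
        assert np.all(hi - draws.max(axis=0) < 0.01 * width)
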