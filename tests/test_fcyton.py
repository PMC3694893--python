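import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import cumulative_trapezoid, quad

from flowmax.fcyton import (FcytonParams, lognormal_from_moments,
                            progressor_fractions, simulate_cyton,
                            simulate_fcyton)


def make_params(**kw) -> FcytonParams:
    base = dict(N=1e4, F0=0.85, Dmu=3.5, Dsigma=1.0,
                Ediv0=40.0, SDdiv0=10.0, Ediv1=10.0, SDdiv1=4.0,
                Edie0=60.0, SDdie0=20.0, Edie1=80.0, SDdie1=30.0)
    base.update(kw)
    return FcytonParams(**base)


class TestLognormalFromMoments:
    def test_monte_carlo_moments(self, rng):
        dist = lognormal_from_moments(30.0, 10.0)
        draws = dist.rvs(size=10 ** 6, random_state=rng)
        assert draws.mean() == pytest.approx(30.0, rel=5e-3)
        assert draws.std() == pytest.approx(10.0, rel=5e-3)

    def test_small_sd_concentrates_at_mean(self):
        dist = lognormal_from_moments(30.0, 0.3)
        assert dist.cdf(30.9) - dist.cdf(29.1) > 0.95

    def test_pdf_normalized(self):
        dist = lognormal_from_moments(50.0, 25.0)
        integral, _ = quad(dist.pdf, 0, np.inf)
        assert integral == pytest.approx(1.0, abs=1e-6)


class TestProgressorFractions:
    def test_distant_destiny_all_progress(self):
        F = progressor_fractions(100.0, 0.1, 8)
        assert np.allclose(F[1:], 1.0)

    def test_exhausted_destiny_none_progress(self):
        F = progressor_fractions(-50.0, 0.5, 8)
        assert np.allclose(F[1:], 0.0)

    def test_matches_survivor_ratio_oracle(self):
        Dmu, Dsigma, g_max = 3.0, 1.0, 8
        F = progressor_fractions(Dmu, Dsigma, g_max)
        S = stats.norm.sf(np.arange(g_max), loc=Dmu, scale=Dsigma)
        for g in range(1, g_max):
            assert F[g] == pytest.approx(min(1.0, S[g] / S[g - 1]), rel=1e-12)

    def test_generation_zero_slot_unused(self):
        assert np.isnan(progressor_fractions(3.0, 1.0, 8)[0])


class TestSimulateFcyton:
    def test_initial_condition(self):
        p = make_params()
        cm = simulate_fcyton(p, [0.0])
        assert cm.counts[0, 0] == pytest.approx(p.N)
        assert np.all(cm.counts[1:, 0] == 0)

    def test_no_responders_never_divide_and_die_out(self):
        p = make_params(F0=0.0)
        cm = simulate_fcyton(p, [0.0, 50.0, 500.0])
        assert np.all(cm.counts[1:, :] == 0)
        assert cm.counts[0, -1] < 1e-3 * p.N  # all non-responders dead

    def test_full_commitment_doubling_bookkeeping(self):
        """All cells divide to the terminal generation: N * 2^(g_max-1)."""
        p = make_params(F0=1.0, Dmu=100.0, Ediv1=8.0, SDdiv1=2.0)
        cm = simulate_fcyton(p, [500.0], g_max=8)
        assert cm.total[0] == pytest.approx(p.N * 2 ** 7, rel=1e-4)
        assert cm.counts[7, 0] == pytest.approx(p.N * 2 ** 7, rel=1e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_nonnegativity_and_grid_stability(self, seed):
        """Counts stay non-negative and stable under grid refinement."""
        rng = np.random.default_rng(seed)
        E = rng.uniform(5, 150, size=4)
        SD = np.minimum(rng.uniform(1, 150, size=4), E)
        p = make_params(
            N=rng.uniform(1e3, 1e5), F0=rng.uniform(0, 1),
            Dmu=rng.uniform(1, 10), Dsigma=rng.uniform(0.1, 3),
            Ediv0=E[0], SDdiv0=SD[0], Ediv1=E[1], SDdiv1=SD[1],
            Edie0=E[2], SDdie0=SD[2], Edie1=E[3], SDdie1=SD[3],
        )
        times = np.linspace(0, 192, 49)
        cm = simulate_fcyton(p, times, dt=0.5)
        assert cm.counts.min() >= 0
        # reconstruct flows from the count matrix itself:
        # divisions into g arrive as 2 cells; deaths leave silently.
        # conservation: checked via a refined-grid rerun comparison instead
        cm_fine = simulate_fcyton(p, times, dt=0.25)
        denom = max(cm.total.max(), p.N)
        assert np.abs(cm.total - cm_fine.total).max() / denom < 5e-3

    def test_grid_convergence(self, wt_params):
        times = np.linspace(0, 192, 17)
        coarse = simulate_fcyton(wt_params, times, dt=0.5)
        fine = simulate_fcyton(wt_params, times, dt=0.25)
        scale = coarse.counts.max()
        assert np.abs(coarse.counts - fine.counts).max() / scale < 5e-3

    def test_cumulative_dividers_monotone(self, wt_params):
        """Later generations only ever receive cells; arrivals never reverse."""
        times = np.linspace(0, 192, 97)
        cm = simulate_fcyton(wt_params.replace(Edie1=150.0, SDdie1=1.0), times)
        # with death negligible inside the window, terminal counts are the
        # cumulative arrivals and must be non-decreasing
        terminal = cm.counts[-1]
        assert np.all(np.diff(terminal) >= -1e-9 * cm.counts.max())


class TestConservationIdentity:
    def test_explicit_flow_accounting(self, wt_params):
        """N_total + cumulative deaths = N + cumulative divisions."""
        p = wt_params
        dt = 0.25
        times = np.arange(0.0, 192.0 + dt, dt)
        g_max = 8
        # recompute the fluxes exactly as an independent bookkeeping oracle
        from flowmax.fcyton import _grids, _trapz_convolve, progressor_fractions

        t, pdiv0, pdiv1, pdie0, pdie1 = _grids(p, times, dt)
        F = progressor_fractions(p.Dmu, p.Dsigma, g_max)
        ndiv = np.zeros((g_max, t.size))
        ndie = np.zeros((g_max, t.size))
        ndiv[0] = p.N * p.F0 * pdiv0
        ndie[0] = p.N * (1 - p.F0) * pdie0
        for g in range(1, g_max):
            born = 2 * ndiv[g - 1]
            die_in = _trapz_convolve(born, pdie1, dt)
            if g < g_max - 1:
                ndiv[g] = F[g] * _trapz_convolve(born, pdiv1, dt)
                ndie[g] = (1 - F[g]) * die_in
            else:
                ndie[g] = (1 - F[g]) * die_in
        cum_div = cumulative_trapezoid(ndiv.sum(axis=0), dx=dt, initial=0.0)
        cum_die = cumulative_trapezoid(ndie.sum(axis=0), dx=dt, initial=0.0)
        cm = simulate_fcyton(p, t, g_max=g_max, dt=dt)
        lhs = cm.total + cum_die
        rhs = p.N + cum_div
        assert np.abs(lhs - rhs).max() < 1e-6 * max(rhs.max(), 1.0)


class TestSimulateCyton:
    def test_death_far_beyond_division_matches_fcyton(self):
        p = make_params(Edie0=150.0, SDdie0=1.0, Edie1=150.0, SDdie1=1.0,
                        Ediv0=20.0, SDdiv0=5.0, Ediv1=10.0, SDdiv1=3.0)
        times = np.linspace(0, 60, 13)  # window well before any death
        a = simulate_fcyton(p, times)
        b = simulate_cyton(p, times)
        scale = a.counts.max()
        assert np.abs(a.counts - b.counts).max() / scale < 0.01

    def test_division_far_beyond_death_extinction(self):
        p = make_params(Ediv0=150.0, SDdiv0=1.0, Edie0=10.0, SDdie0=3.0, F0=0.9)
        cm = simulate_cyton(p, [400.0])
        assert cm.total[0] < 1e-2 * p.N

    def test_identical_clocks_half_divide(self):
        """Symmetric race: exactly half of generation-0 cells divide."""
        p = make_params(F0=1.0, Ediv0=40.0, SDdiv0=10.0, Edie0=40.0, SDdie0=10.0,
                        Dmu=0.5, Dsigma=0.1,       # destiny stops further division
                        Edie1=150.0, SDdie1=1.0)   # gen-1 deaths far beyond window
        times = np.array([120.0])  # race finished, gen-1 deaths not yet begun
        cm = simulate_cyton(p, times, dt=0.25)
        arrived = cm.counts[1:, 0].sum()  # gen-1 cells: 2 per division
        assert arrived / 2 == pytest.approx(p.N / 2, rel=5e-3)


class TestParamValidation:
    def test_sd_must_not_exceed_mean(self):
        with pytest.raises(ValueError, match="SDdiv0"):
            make_params(SDdiv0=50.0, Ediv0=40.0)

    def test_f0_range(self):
        with pytest.raises(ValueError):
            make_params(F0=1.5)

    def test_vector_round_trip(self, wt_params):
        assert FcytonParams.from_array(wt_params.to_array()) == wt_params
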