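import numpy as np
import pytest

from lipidsites import (
    SurvivalCurve,
    fit_biexponential,
    per_residue_residence_times,
    residence_time,
    simulate_contact_series,
    survival_function,
)
from lipidsites.contacts import ContactEvent, ContactSeries
from lipidsites.kinetics import NoBindingError, default_lag_range
from lipidsites import events_from_series
from oracles import survival_bruteforce


def ev(start, end, lipid=0, res=0, censored=False):
    return ContactEvent(lipid, res, start, end, censored)


class TestSurvivalFunction:
    def test_full_occupancy_gives_flat_curve(self):
        curve = survival_function([ev(0, 100, censored=True)], 100, 50)
        np.testing.assert_allclose(curve.sigma, 1.0)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(0)
        occ = rng.random((6, 500)) < 0.4
        events = events_from_series(
            ContactSeries(
                occupancy=occ[:, None, :],
                lipid_ids=np.arange(6),
                residue_ids=np.array([0]),
                frame_dt=1.0,
                cutoff_lower=5,
                cutoff_upper=7,
            )
        )
        curve = survival_function(events, 500, 120)
        expected = survival_bruteforce(occ, 120)
        np.testing.assert_allclose(curve.sigma, expected, rtol=1e-12)

    def test_exponential_limit(self):
        # Markov channels with k_off = 0.01 per frame: sigma(t) tracks
        # exp(-0.01 t) for lags well below the trajectory length
        series = simulate_contact_series(0.01, 0.01, 20000, 1.0, 20, seed=12)
        events = events_from_series(series)
        curve = survival_function(events, 20000, 300)
        t = curve.lag_times
        np.testing.assert_allclose(curve.sigma, np.exp(-0.01 * t), atol=0.04)

    def test_lipid_relabeling_invariance(self):
        events = [ev(3, 40, lipid=0), ev(100, 160, lipid=1), ev(300, 310, lipid=0)]
        relabeled = [ev(3, 40, lipid=9), ev(100, 160, lipid=4), ev(300, 310, lipid=7)]
        a = survival_function(events, 400, 100)
        b = survival_function(relabeled, 400, 100)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_block_position_invariance(self):
        # sigma depends only on the dwell-length multiset, not event positions
        a = survival_function([ev(0, 50), ev(60, 80)], 1000, 200)
        b = survival_function([ev(500, 550), ev(900, 920)], 1000, 200)
        np.testing.assert_allclose(a.sigma, b.sigma, rtol=1e-12)

    def test_no_events_raises(self):
        with pytest.raises(NoBindingError):
            survival_function([], 100, 10)


class TestBiexponentialFit:
    def test_noiseless_biexponential_recovery(self):
        t = np.arange(0, 60, 0.05)
        y = 0.7 * np.exp(-0.5 * t) + 0.3 * np.exp(-5.0 * t)
        curve = SurvivalCurve(t, y / y[0], n_contacts=100, t_total=1000.0)
        fit = fit_biexponential(curve, time_unit_us=1.0)
        assert fit.converged
        assert fit.amplitude_slow == pytest.approx(0.7, abs=1e-6)
        assert fit.rate_slow == pytest.approx(0.5, abs=1e-6)
        assert fit.amplitude_fast == pytest.approx(0.3, abs=1e-6)
        assert fit.rate_fast == pytest.approx(5.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.residence_time == pytest.approx(2.0, abs=1e-6)

    def test_pure_single_exponential_tolerated(self):
        t = np.arange(0, 40, 0.05)
        curve = SurvivalCurve(t, np.exp(-0.5 * t), n_contacts=100, t_total=1000.0)
        fit = fit_biexponential(curve, time_unit_us=1.0)
        assert fit.converged
        assert fit.residence_time == pytest.approx(2.0, rel=0.01)
        assert fit.rate_slow <= fit.rate_fast

    def test_reporting_convention_tau_is_inverse_koff(self):
        # a slow rate of 0.2632 /us is reported as a 3.8 us residence time
        assert residence_time(0.2632) == pytest.approx(3.8, abs=0.005)

    def test_time_unit_invariance(self):
        t_ns = np.arange(0, 4000.0, 10.0)
        y = 0.8 * np.exp(-t_ns / 1000.0) + 0.2 * np.exp(-t_ns / 50.0)
        y /= y[0]
        fit_ns = fit_biexponential(
            SurvivalCurve(t_ns, y, 50, 40000.0), time_unit_us=1e-3
        )
        fit_us = fit_biexponential(
            SurvivalCurve(t_ns / 1000.0, y, 50, 40.0), time_unit_us=1.0
        )
        assert fit_ns.residence_time == pytest.approx(fit_us.residence_time, rel=1e-6)

    def test_too_few_lag_points_rejected(self):
        t = np.arange(5.0)
        with pytest.raises(ValueError):
            fit_biexponential(SurvivalCurve(t, np.exp(-t), 5, 100.0))


class TestParameterRecovery:
    def test_median_tau_error_below_ten_percent(self):
        # planted exponential kinetics, T = 20 tau, ~550 events per replicate
        errs = []
        for seed in range(20):
            series = simulate_contact_series(0.01, 0.01, 2000, 1.0, 50, seed=seed)
            events = events_from_series(series)
            t_max = default_lag_range(events, 2000)
            curve = survival_function(events, 2000, t_max)
            fit = fit_biexponential(curve, time_unit_us=1.0)
            errs.append(abs(fit.residence_time - 100.0) / 100.0)
        assert np.median(errs) <= 0.10

    def test_doubling_koff_halves_tau(self):
        taus = {}
        for k_off in (0.01, 0.02):
            estimates = []
            for seed in range(8):
                series = simulate_contact_series(
                    k_off, 0.01, 4000, 1.0, 40, seed=100 + seed
                )
                events = events_from_series(series)
                curve = survival_function(events, 4000, default_lag_range(events, 4000))
                estimates.append(
                    fit_biexponential(curve, time_unit_us=1.0).residence_time
                )
            taus[k_off] = np.median(estimates)
        assert taus[0.01] / taus[0.02] == pytest.approx(2.0, rel=0.25)


class TestPerResidueTable:
    def test_identical_residues_and_recovery(self):
        # two residues with the same planted kinetics: over seeded replicates
        # both recover tau (median) and agree with each other within
        # estimator noise
        tau_a_all, tau_b_all = [], []
        for seed in range(5):
            a = simulate_contact_series(0.01, 0.01, 2000, 1.0, 50, seed=20 + seed)
            b = simulate_contact_series(0.01, 0.01, 2000, 1.0, 50, seed=120 + seed)
            occ = np.concatenate([a.occupancy, b.occupancy], axis=1)
            series = ContactSeries(
                occupancy=occ,
                lipid_ids=np.arange(50),
                residue_ids=np.array([0, 1]),
                frame_dt=1.0,
                cutoff_lower=5,
                cutoff_upper=7,
            )
            table = per_residue_residence_times(series)
            assert list(table["residue"]) == [1, 2]  # 1-based reporting
            tau_a, tau_b = table["time_us"] * 1e3  # frame_dt=1 "ns" per frame
            tau_a_all.append(tau_a)
            tau_b_all.append(tau_b)
        assert np.median(tau_a_all) == pytest.approx(100.0, rel=0.25)
        assert np.median(tau_b_all) == pytest.approx(100.0, rel=0.25)
        spread = abs(np.median(tau_a_all) - np.median(tau_b_all))
        assert spread / 100.0 < 0.3

    def test_uncontacted_residue_missing_not_zero(self):
        sim = simulate_contact_series(0.05, 0.05, 500, 1.0, 10, seed=5)
        occ = np.concatenate([sim.occupancy, np.zeros_like(sim.occupancy)], axis=1)
        series = ContactSeries(
            occupancy=occ,
            lipid_ids=np.arange(10),
            residue_ids=np.array([0, 1]),
            frame_dt=1.0,
            cutoff_lower=5,
            cutoff_upper=7,
        )
        table = per_residue_residence_times(series)
        assert list(table["residue"]) == [1]
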