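"""Event frequencies, signed residence times, exponential fits, Ai."""

import numpy as np
import pytest

from conftest import make_staircase_trace, step_model_from_occupancy

from tirftrace.kinetics import (
    ResidenceInterval,
    ResidenceSet,
    affinity_index,
    event_frequencies,
    fit_tau,
    photobleach_correct,
    residence_intervals,
)
from tirftrace.simulate import simulate_binding_trajectory
from tirftrace.stepfind import StepParams, find_steps

PARAMS = StepParams(step_mean=100.0, step_sd=15.0)


def interval_set(taus, sign=1, level=1):
    return ResidenceSet(
        [ResidenceInterval(0, level, sign * t, sign, False) for t in taus]
    )


class TestFrequencies:
    def test_no_steps_gives_zeros(self):
        tr = make_staircase_trace([100.0], [60])
        model = find_steps(tr, PARAMS)
        assert event_frequencies(model, 12.0) == (0.0, 0.0, 0, 0)

    def test_four_up_steps_in_forty_seconds(self):
        levels = [0, 100, 200, 300, 400]
        tr = make_staircase_trace(levels, [40] * 5, dt=0.2,
                                  channel_tag="rhodamine")
        model = find_steps(tr, PARAMS)
        f_on, f_off, n_plus, n_minus = event_frequencies(model, 40.0)
        assert (n_plus, n_minus) == (4, 0)
        assert f_on == pytest.approx(0.1)
        assert f_off == 0.0

    def test_steady_state_flux_balance_pooled(self):
        """Without photobleaching, pooled f_on matches f_off within 3 SE."""
        ups = downs = 0
        for seed in range(60):
            occ = simulate_binding_trajectory(2, 300e-9, 1e6, 0.4, 0.0, 100.0,
                                              seed=seed)
            m = step_model_from_occupancy(occ)
            _, _, n_p, n_m = event_frequencies(m, 100.0)
            ups += n_p
            downs += n_m
        assert abs(ups - downs) <= 3 * np.sqrt(ups + downs)

    def test_up_down_ratio_decreases_with_photobleaching(self):
        def ratio(kpb):
            ups = downs = 0
            for seed in range(40):
                occ = simulate_binding_trajectory(
                    2, 300e-9, 1e6, 0.4, kpb, 100.0, seed=900 + seed
                )
                m = step_model_from_occupancy(occ)
                _, _, n_p, n_m = event_frequencies(m, 100.0)
                ups += n_p
                downs += n_m
            return ups / downs

        r = [ratio(k) for k in (0.0, 0.15, 0.4)]
        assert abs(r[0] - 1.0) < 0.1
        assert r[0] > r[1] > r[2]


class TestResidenceIntervals:
    def test_monomer_cycling_is_all_tau_plus(self):
        # 0 -> 1 -> 0 -> 1 -> 0 cycling monomer: nonzero levels bind-entered
        levels = [0, 100, 0, 100, 0]
        tr = make_staircase_trace(levels, [20] * 5, channel_tag="rhodamine")
        rs = residence_intervals(find_steps(tr, PARAMS))
        assert len(rs.intervals) == 2
        assert all(iv.tau_s > 0 and iv.entry_sign == 1 for iv in rs.intervals)
        assert all(not iv.censored for iv in rs.intervals)

    def test_saturated_dimer_alternates_signs(self):
        # 2 <-> 1 cycling: level-2 intervals bind-entered (tau+),
        # level-1 intervals loss-entered (tau-)
        levels = [200, 100, 200, 100, 200, 100]
        tr = make_staircase_trace(levels, [20] * 6, channel_tag="rhodamine")
        rs = residence_intervals(find_steps(tr, PARAMS))
        inner = [iv for iv in rs.intervals if not iv.censored]
        occs = [iv.occupancy_level for iv in inner]
        for iv in inner:
            assert (iv.tau_s > 0) == (iv.occupancy_level == 2)
        n_plus = sum(1 for iv in inner if iv.tau_s > 0)
        n_minus = len(inner) - n_plus
        assert abs(n_plus - n_minus) <= 1

    def test_zero_occupancy_never_scored(self):
        levels = [0, 100, 0, 100, 100 * 2, 100, 0]
        tr = make_staircase_trace(levels, [15] * 7, channel_tag="rhodamine")
        rs = residence_intervals(find_steps(tr, PARAMS))
        assert all(iv.occupancy_level >= 1 for iv in rs.intervals)

    def test_open_interval_censored_and_excluded(self):
        # single up step; level persists to the record end
        levels = [0, 100]
        tr = make_staircase_trace(levels, [25, 175], channel_tag="rhodamine")
        rs = residence_intervals(find_steps(tr, PARAMS))
        assert len(rs.intervals) == 1
        assert rs.intervals[0].censored
        assert rs.uncensored() == []

    def test_interval_bookkeeping_is_exact(self):
        """#tau+ + #tau- + #censored equals the number of nonzero levels."""
        for seed in range(10):
            occ = simulate_binding_trajectory(3, 1e-6, 1e6, 0.5, 0.1, 60.0,
                                              seed=seed)
            m = step_model_from_occupancy(occ)
            rs = residence_intervals(m)
            from tirftrace.kinetics import _level_occupancies

            n_nonzero_levels = int((_level_occupancies(m) >= 1).sum())
            assert len(rs.intervals) == n_nonzero_levels


class TestTauFits:
    def test_known_exponential_rate_recovered(self, rng):
        taus = rng.exponential(1 / 0.5, size=2000)
        fit = fit_tau(interval_set(taus))
        assert fit.model == "single"
        assert abs(fit.k_tau - 0.5) < 0.05

    def test_biexponential_mixture_detected_and_recovered(self, rng):
        taus = np.concatenate([
            rng.exponential(1 / 3.0, size=2500),
            rng.exponential(1 / 0.3, size=2500),
        ])
        fit = fit_tau(interval_set(taus))
        assert fit.model == "double"
        fast, slow = max(fit.k_tau, fit.k_tau2), min(fit.k_tau, fit.k_tau2)
        assert abs(fast - 3.0) / 3.0 < 0.2
        assert abs(slow - 0.3) / 0.3 < 0.2

    def test_empty_or_small_sets_rejected(self):
        with pytest.raises(ValueError):
            fit_tau(interval_set([]))
        with pytest.raises(ValueError):
            fit_tau(interval_set([1.0] * 10))

    def test_truncation_bias_below_five_percent(self):
        """Fitting only tau <= 30 s barely biases k for k >= 0.2 / s."""
        for k in (0.2, 0.5, 1.0):
            edges = np.arange(0.0, 30.0 + 0.4, 0.4)
            # analytic counts for n = 1e5 intervals, no sampling noise
            counts = 1e5 * (np.exp(-k * edges[:-1]) - np.exp(-k * edges[1:]))
            taus = np.repeat(0.5 * (edges[:-1] + edges[1:]),
                             np.round(counts / 50).astype(int))
            fit = fit_tau(interval_set(taus), tau_max=30.0)
            assert abs(fit.k_tau - k) / k < 0.05

    def test_long_interval_fraction_reported(self, rng):
        taus = rng.exponential(1 / 0.05, size=500)  # mean 20 s, many > 30 s
        fit = fit_tau(interval_set(taus))
        expected = float(np.mean(taus > 30.0))
        assert fit.tau_gt_max_fraction == pytest.approx(expected)


class TestPhotobleachCorrection:
    def test_trivial_identities(self):
        assert photobleach_correct(0.7, 0.0) == 0.7
        assert photobleach_correct(0.5, 0.5) == 0.0

    def test_excess_hazard_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert photobleach_correct(0.2, 0.5) == 0.0

    def test_competing_hazards_recovered_from_simulation(self):
        """koff = 0.3 with kpb = 0.2: fitted k_tau ~ 0.5, corrected ~ 0.3."""
        pooled = ResidenceSet([])
        for seed in range(150):
            occ = simulate_binding_trajectory(1, 100e-9, 1e6, 0.3, 0.2, 100.0,
                                              seed=2000 + seed)
            pooled.extend(residence_intervals(step_model_from_occupancy(occ)))
        fit = fit_tau(pooled, model_selection="single")
        assert abs(fit.k_tau - 0.5) / 0.5 < 0.15
        corr = photobleach_correct(fit.k_tau, 0.2)
        assert abs(corr - 0.3) / 0.3 < 0.30


class TestAffinityIndex:
    def test_equal_rates_return_concentration(self):
        assert affinity_index(300e-9, 0.5, 0.5) == pytest.approx(300e-9)

    def test_monomer_condition_reproduces_micromolar_index(self):
        # 300 nM ligand, k_tau = 0.7 / s, f_on = 0.0512 / s -> 4.1 uM
        ai = affinity_index(300e-9, 0.7, 0.0512)
        assert ai == pytest.approx(4.1e-6, rel=0.01)

    def test_holoenzyme_condition_reproduces_210_nanomolar(self):
        ai = affinity_index(30e-9, 0.315, 0.045)
        assert ai == pytest.approx(210e-9, rel=0.01)

    def test_zero_on_rate_flagged_infinite(self):
        with pytest.warns(UserWarning):
            assert affinity_index(30e-9, 0.5, 0.0) == np.inf


class TestParameterRecoveryGrid:
    @pytest.mark.parametrize("koff,kpb,S", [
        (0.1, 0.0, 1),
        (0.3, 0.1, 1),
        (1.0, 0.3, 1),
        (0.3, 0.1, 2),
        (0.3, 0.0, 14),
    ])
    def test_k_tau_corr_recovers_koff(self, koff, kpb, S):
        """k_tau - k_pb matches the injected off-rate at low occupancy."""
        kon_c = 0.1 * koff / S  # sparse occupancy: level-1 dwells dominate
        pooled = ResidenceSet([])
        seed0 = int(1e4 * koff + 1e3 * kpb + S)
        n_traj, dur = 150, 200.0
        dt = 0.05  # fine sampling: this validates the kinetics chain itself
        for seed in range(n_traj):
            occ = simulate_binding_trajectory(
                S, kon_c / 1e6, 1e6, koff, kpb, dur, seed=seed0 + seed, dt=dt
            )
            pooled.extend(residence_intervals(step_model_from_occupancy(occ, dt=dt)))
        fit = fit_tau(pooled, model_selection="single", frame_interval_s=dt)
        corr = photobleach_correct(fit.k_tau, kpb)
        assert abs(corr - koff) / koff < 0.20
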