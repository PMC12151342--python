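import numpy as np
import pytest
from thermoplaid import simulate as ts
from thermoplaid.bouts import BoutEvent, swim_vigor


class TestPlaidField:
    @pytest.mark.parametrize(
        "x,y,expected",
        [(3.75, 3.75, 2000.0), (11.25, 11.25, 500.0), (0.0, 0.0, 1250.0)],
    )
    def test_reference_points(self, x, y, expected):
        assert ts.PlaidField().power_at(x, y) == pytest.approx(expected)

    def test_grid_extrema_and_mean(self):
        """Power spans 500-2000 mW with spatial mean at the 1250 mW offset."""
        f = ts.PlaidField()
        g = np.linspace(0, 15, 301)[:-1]  # one full period, endpoint excluded
        xx, yy = np.meshgrid(g, g)
        p = f.power_at(xx, yy)
        assert p.max() == pytest.approx(2000.0, abs=0.5)
        assert p.min() == pytest.approx(500.0, abs=0.5)
        assert p.mean() == pytest.approx(1250.0, abs=1e-6)

    def test_periodicity_both_axes(self):
        f = ts.PlaidField()
        rng = np.random.default_rng(0)
        x, y = rng.uniform(0, 100, 50), rng.uniform(0, 100, 50)
        np.testing.assert_allclose(f.power_at(x + 15, y), f.power_at(x, y))
        np.testing.assert_allclose(f.power_at(x, y + 15), f.power_at(x, y))

    def test_diagonal_period(self):
        assert ts.PlaidField().diagonal_period_mm == pytest.approx(15 * np.sqrt(2))


class TestCalibration:
    def test_anchors_and_midpoint(self):
        c = ts.Calibration()
        assert c.power_to_temperature(500) == pytest.approx(25.0)
        assert c.power_to_temperature(2000) == pytest.approx(28.0)
        assert c.power_to_temperature(1250) == pytest.approx(26.5)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ts.Calibration(power_lo_mw=500, power_hi_mw=500)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning):
            ts.Calibration().power_to_temperature(2500)


class TestSimulateFish:
    def test_null_policy_bout_rate(self):
        """Kernel-free Bernoulli(0.04)/bin policy gives ~1 bout/s within 3 SE."""
        exp = ts.simulate_fish(ts.null_policy(1.0), field=ts.PlaidField(),
                               duration_s=600, seed=1)
        n_bins = 600 * 25
        se = np.sqrt(0.04 * 0.96 / n_bins) * 25  # binomial SE on the rate
        assert abs(len(exp.true_bouts) / 600 - 1.0) < 3 * se

    def test_deterministic_under_seed(self, plaid_policy):
        a = ts.simulate_fish(plaid_policy, field=ts.PlaidField(), duration_s=60, seed=7)
        b = ts.simulate_fish(plaid_policy, field=ts.PlaidField(), duration_s=60, seed=7)
        np.testing.assert_array_equal(a.trajectory.x, b.trajectory.x)
        np.testing.assert_array_equal(a.temperature, b.temperature)
        assert [(x.start_frame, x.end_frame) for x in a.true_bouts] == [
            (x.start_frame, x.end_frame) for x in b.true_bouts
        ]

    def test_replay_constant_trace_ignores_motion(self, plaid_policy):
        trace = np.full(60 * 250, 25.0)
        exp = ts.simulate_fish(plaid_policy, replay_temperature=trace,
                               duration_s=60, seed=3)
        assert np.all(exp.temperature == 25.0)
        assert len(exp.true_bouts) > 0  # the fish still swims

    def test_positions_stay_in_arena(self, plaid_policy):
        exp = ts.simulate_fish(plaid_policy, field=ts.PlaidField(), duration_s=120, seed=5)
        r = np.hypot(exp.trajectory.x - 50, exp.trajectory.y - 50)
        assert r.max() <= 50.0

    def test_bad_arguments(self, plaid_policy):
        with pytest.raises(ValueError):
            ts.simulate_fish(plaid_policy, field=ts.PlaidField(), duration_s=0, seed=0)
        with pytest.raises(ValueError):
            ts.simulate_fish(plaid_policy, replay_temperature=np.full(10, 25.0),
                             duration_s=60, seed=0)
        with pytest.raises(ValueError):
            ts.simulate_fish(plaid_policy, duration_s=60, seed=0)


class TestReplayPair:
    def test_trace_identity_and_idempotence(self, plaid_policy):
        plaid = ts.simulate_fish(plaid_policy, field=ts.PlaidField(), duration_s=60, seed=11)
        pair = ts.make_replay_pair(plaid, plaid_policy, seed=12)
        np.testing.assert_array_equal(pair.replay.temperature, plaid.temperature)
        again = ts.make_replay_pair(pair.replay, plaid_policy, seed=13)
        np.testing.assert_array_equal(again.replay.temperature, plaid.temperature)

    def test_position_temperature_coupling_broken(self, plaid_policy):
        """The field predicts temperature from position exactly in plaid,
        and poorly for the yoked twin whose stimulus is decoupled from motion."""
        field, cal = ts.PlaidField(), ts.Calibration()
        plaid = ts.simulate_fish(plaid_policy, field=field, duration_s=300, seed=21)
        pair = ts.make_replay_pair(plaid, plaid_policy, seed=22)

        def coupling(exp):
            predicted = cal.power_to_temperature(
                field.power_at(exp.trajectory.x, exp.trajectory.y)
            )
            return np.corrcoef(predicted, exp.temperature)[0, 1]

        # thermal fluctuation rides on the field signal, so not exactly 1
        assert coupling(plaid) > 0.85
        assert abs(coupling(pair.replay)) < 0.5

    def test_replay_preserves_temperature_marginal(self, plaid_policy):
        plaid = ts.simulate_fish(plaid_policy, field=ts.PlaidField(),
                                 duration_s=60, seed=31)
        pair = ts.make_replay_pair(plaid, plaid_policy, seed=32)
        np.testing.assert_array_equal(
            np.sort(pair.replay.temperature), np.sort(plaid.temperature)
        )


class TestTailTrace:
    def test_silent_trace(self):
        assert np.all(ts.synth_tail_trace([], 100, noise_sd_rad=0.0) == 0.0)

    def test_vigor_exceeds_threshold_inside_bout(self):
        bouts = [BoutEvent(100, 140)]
        tail = ts.synth_tail_trace(bouts, 400, noise_sd_rad=0.0)
        vig = swim_vigor(tail)
        assert vig[110:140].max() > 0.1
        assert vig[:100].max() == 0.0

    def test_noise_only_stays_subthreshold(self):
        # max over many windows of the SD of N(0, 0.01) noise stays << 0.1
        tail = ts.synth_tail_trace([], 250 * 120, noise_sd_rad=0.01, seed=0)
        assert swim_vigor(tail).max() < 0.1

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            ts.synth_tail_trace([BoutEvent(0, 50), BoutEvent(25, 80)], 200)


class TestNeurons:
    def test_silent_input_silent_output(self):
        m = ts.NeuronModel(w_sensory=1, w_motor=1, w_coincidence=1, noise_sd=0.0)
        act = ts.simulate_neurons([m], np.full(100, 26.0), np.zeros(100), seed=0)
        np.testing.assert_allclose(act, 0.0)

    def test_coincidence_gating(self):
        """A coincidence neuron needs temperature change AND a bout to fire."""
        m = ts.NeuronModel(w_coincidence=2.0, noise_sd=0.0)
        bouts = np.zeros(100)
        bouts[50] = 1.0
        flat = ts.simulate_neurons([m], np.full(100, 26.0), bouts, seed=0)
        ramp = ts.simulate_neurons([m], np.linspace(25, 28, 100), bouts, seed=0)
        assert np.allclose(flat, 0.0)
        assert ramp[50:, 0].max() > 0.0

    def test_calcium_kernel_decay(self):
        m = ts.NeuronModel(w_motor=1.0, tau_s=2.0, noise_sd=0.0)
        bouts = np.zeros(100)
        bouts[10] = 1.0
        act = ts.simulate_neurons([m], np.full(100, 26.0), bouts, seed=0)[:, 0]
        assert act[10] == pytest.approx(1.0)
        assert act[10 + 10] == pytest.approx(np.exp(-1.0))  # 2 s = 10 bins at 5 Hz

    def test_errors(self):
        with pytest.raises(ValueError):
            ts.simulate_neurons([], np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            ts.simulate_neurons([ts.NeuronModel(tau_s=0.0)], np.zeros(10), np.zeros(10))

    def test_population_mix(self):
        pop = ts.sample_neuron_population(200, seed=0)
        mixed = [m for m in pop if m.mixed_selectivity]
        assert 0 < len(mixed) < len(pop)
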