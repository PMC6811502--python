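"""Tests of the event-driven simulator and its exact time-averaging.

The central correctness oracle is the linear identity of time averages,
mu_bar = R x_bar + F p, which must hold to accumulation round-off on every
trial because both sides are exact integrals of the same piecewise-constant
trajectory.
"""

import numpy as np
import pytest
import scipy.sparse as sp

from balnet import (
    Network,
    NetworkParams,
    generate_connectivity,
    generate_input_ensemble,
    gain_curve,
    run_ensemble,
    simulate_trial,
)
from balnet.simulate import simulate_trial_prefixes
from balnet.synth import trial_seed


def _unconnected(params):
    N = params.N
    return Network(params=params, R=sp.csc_matrix((N, N)), theta=None or
                   np.concatenate([np.full(params.N_E, params.theta_E),
                                   np.full(params.N_I, params.theta_I)]))


class TestFixedPoints:
    def test_subthreshold_drive_silences_unconnected_network(self):
        params = NetworkParams(N_E=40, N_I=10, K=5)
        net = _unconnected(params)
        p = np.full(50, 0.1)  # f*p well below both thresholds
        s = simulate_trial(net, p, t_obs=500.0, t_burn=200.0, seed=1)
        np.testing.assert_array_equal(s.x_bar, 0.0)
        np.testing.assert_allclose(s.mu_bar, net.f * p, rtol=1e-12)

    def test_suprathreshold_drive_saturates_unconnected_network(self):
        params = NetworkParams(N_E=40, N_I=10, K=5)
        net = _unconnected(params)
        p = np.full(50, 5.0)
        s = simulate_trial(net, p, t_obs=500.0, t_burn=200.0, seed=1)
        np.testing.assert_array_equal(s.x_bar, 1.0)

    def test_runaway_excitation_without_inhibition(self):
        params = NetworkParams(N_E=100, N_I=25, K=10)
        net = generate_connectivity(params, seed=0)
        R = net.R.toarray()
        R[:, 100:] = 0.0  # silence inhibitory synapses
        net = Network(params=params, R=sp.csc_matrix(R), theta=net.theta)
        p = np.full(125, 3.0)
        s = simulate_trial(net, p, t_obs=1000.0, t_burn=300.0, seed=2)
        assert s.x_bar.mean() > 0.95


class TestTimeAverageIdentity:
    def test_identity_on_default_balanced_network(self, default_params):
        net = generate_connectivity(default_params, seed=5)
        ens = generate_input_ensemble(default_params, r=1, seed=5)
        s = simulate_trial(net, ens.P[:, 0], t_obs=2500.0, t_burn=500.0,
                           seed=trial_seed(5, 0))
        rhs = net.R @ s.x_bar + net.f * ens.P[:, 0]
        resid = np.linalg.norm(s.mu_bar - rhs) / np.linalg.norm(s.mu_bar)
        assert resid < 1e-9

    def test_identity_and_ei_split_on_every_small_trial(self, small_network):
        params = small_network.params
        ens = generate_input_ensemble(params, r=5, seed=8)
        for t in range(5):
            s = simulate_trial(small_network, ens.P[:, t], t_obs=800.0,
                               t_burn=300.0, seed=trial_seed(8, t))
            rhs = small_network.R @ s.x_bar + small_network.f * ens.P[:, t]
            assert np.linalg.norm(s.mu_bar - rhs) <= 1e-9 * np.linalg.norm(s.mu_bar)
            np.testing.assert_allclose(s.mu_bar, s.e_bar + s.i_bar, rtol=1e-9)
            assert np.all((s.x_bar >= 0) & (s.x_bar <= 1))
            assert np.all(s.i_bar <= 1e-15)

    def test_prefix_windows_match_single_windows(self, small_network):
        """The last prefix checkpoint equals a plain run of the same duration."""
        params = small_network.params
        ens = generate_input_ensemble(params, r=1, seed=9)
        xs, mus = simulate_trial_prefixes(
            small_network, ens.P[:, 0], [250.0, 1000.0], t_burn=300.0, seed=77
        )
        s = simulate_trial(small_network, ens.P[:, 0], t_obs=1000.0,
                           t_burn=300.0, seed=77)
        np.testing.assert_allclose(xs[1], s.x_bar, atol=1e-12)
        np.testing.assert_allclose(mus[1], s.mu_bar, rtol=1e-9)


class TestStatistics:
    def test_update_count_matches_poisson_rates(self, small_network):
        params = small_network.params
        s = simulate_trial(small_network, np.full(params.N, 1.0),
                           t_obs=2000.0, t_burn=500.0, seed=3)
        total_t = 2500.0
        rate = params.N_E / params.tau_E + params.N_I / params.tau_I
        expected = rate * total_t
        assert abs(s.n_updates - expected) < 3 * np.sqrt(expected)

    def test_determinism_same_seed(self, small_network):
        p = np.full(small_network.N, 2.0)
        a = simulate_trial(small_network, p, 500.0, 100.0, seed=12)
        b = simulate_trial(small_network, p, 500.0, 100.0, seed=12)
        np.testing.assert_array_equal(a.x_bar, b.x_bar)
        np.testing.assert_array_equal(a.mu_bar, b.mu_bar)
        assert a.n_updates == b.n_updates

    def test_weak_row_correlations_in_balanced_state(self, small_response):
        _, response = small_response
        active = response.X.std(axis=1) > 1e-6
        corr = np.corrcoef(response.X[active])
        off = np.abs(corr[~np.eye(corr.shape[0], dtype=bool)])
        assert np.nanmean(off) < 0.2


class TestEnsemble:
    def test_single_trial_ensemble_reduces_to_simulate_trial(self, small_network):
        params = small_network.params
        ens = generate_input_ensemble(params, r=1, seed=21)
        resp = run_ensemble(small_network, ens, 500.0, 200.0, seed=21)
        s = simulate_trial(small_network, ens.P[:, 0], 500.0, 200.0,
                           seed=trial_seed(21, 0))
        np.testing.assert_array_equal(resp.X[:, 0], s.x_bar)
        np.testing.assert_array_equal(resp.U[:, 0], s.mu_bar)

    def test_trials_independent_of_execution_order(self, small_network):
        """Each column depends only on its own (p, seed) pair."""
        params = small_network.params
        ens = generate_input_ensemble(params, r=4, seed=22)
        resp = run_ensemble(small_network, ens, 400.0, 150.0, seed=22)
        s2 = simulate_trial(small_network, ens.P[:, 2], 400.0, 150.0,
                            seed=trial_seed(22, 2))
        np.testing.assert_array_equal(resp.X[:, 2], s2.x_bar)


class TestGainCurve:
    def test_zero_drive_is_quiescent_and_means_grow(self, small_network):
        p = generate_input_ensemble(small_network.params, r=1, seed=30).P[:, 0]
        table = gain_curve(small_network, p, [0.0, 0.5, 1.0, 2.0, 3.0],
                           t_obs=800.0, t_burn=300.0, seed=30)
        assert table.x_E.iloc[0] == 0.0 and table.x_I.iloc[0] == 0.0
        assert table.x_E.iloc[-1] > table.x_E.iloc[1]
        assert table.x_I.iloc[-1] > table.x_I.iloc[1]

    def test_linear_gain_at_strong_drive(self, default_params):
        """Population means grow linearly with S for sufficiently large drive.

        Upper half of the S grid on the default-scale network; the R^2
        threshold was frozen from an oracle run of this configuration.
        """
        net = generate_connectivity(default_params, seed=0)
        p = generate_input_ensemble(default_params, r=1, seed=0).P[:, 0]
        S = np.linspace(0.0, 2.0, 11)
        table = gain_curve(net, p, S, t_obs=3000.0, t_burn=500.0, seed=0)
        upper = table.iloc[5:]
        for col in ("x_E", "x_I"):
            y = upper[col].to_numpy()
            slope, icept = np.polyfit(upper.S, y, 1)
            fit = slope * upper.S + icept
            ss_res = np.sum((y - fit) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            assert 1 - ss_res / ss_tot > 0.97
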