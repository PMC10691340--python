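"""Template decoders: time courses, cross-temporal matrices, noise matching."""

import numpy as np
import pytest
from scipy.stats import norm

from infoload.decode import (
    TrialTensor,
    cross_temporal_matrix,
    delay_decoder_timecourse,
    match_performance_noise,
    simulate_loading_trials,
)
from infoload.errors import CalibrationError, ConfigError
from infoload.linear import make_random_network, loading_vectors


def _static_trials(rng, C=4, N=10, B=12, trials_per=10, sigma=0.0):
    """Condition means constant in time, optional observation noise."""
    means = rng.normal(size=(C, N)) * 2.0
    labels = np.repeat(np.arange(C), trials_per)
    rates = means[labels][:, :, None] + np.zeros((1, 1, B))
    rates = rates + sigma * rng.normal(size=rates.shape)
    return TrialTensor(rates, labels, 0.05 * np.arange(B), dt=0.05)


class TestDelayDecoder:
    def test_noiseless_static_code_is_perfect(self):
        trials = _static_trials(np.random.default_rng(0))
        acc, folds = delay_decoder_timecourse(trials, (0.3, 0.55), cv_folds=5,
                                              seed=1)
        assert np.allclose(acc, 1.0)
        assert folds.shape == (5, trials.n_bins)

    def test_permuted_labels_give_chance(self):
        rng = np.random.default_rng(1)
        trials = _static_trials(rng, C=6, trials_per=100, sigma=0.5)
        perm = rng.permutation(trials.n_trials)
        shuffled = TrialTensor(trials.rates, trials.labels[perm], trials.time,
                               dt=trials.dt)
        acc, _ = delay_decoder_timecourse(shuffled, (0.3, 0.55), cv_folds=5,
                                          seed=2)
        assert np.all(np.abs(acc - 1 / 6) < 0.1)

    def test_gaussian_two_class_analytic_accuracy(self):
        """1 neuron, 2 classes at means +/-1, observation sigma=1: accuracy of
        the centroid rule is Phi(1) ~ 0.841."""
        rng = np.random.default_rng(3)
        trials_per = 1000
        labels = np.repeat([0, 1], trials_per)
        mu = np.array([-1.0, 1.0])[labels]
        rates = (mu[:, None] + rng.normal(size=(2 * trials_per, 8)))[:, None, :]
        tt = TrialTensor(rates, labels, 0.1 * np.arange(8), dt=0.1)
        acc, _ = delay_decoder_timecourse(tt, (0.0, 0.75), cv_folds=4, seed=4)
        # train window averages 8 bins -> very clean templates; per-bin test
        assert abs(acc.mean() - norm.cdf(1.0)) < 0.03

    def test_window_outside_data(self):
        trials = _static_trials(np.random.default_rng(5))
        with pytest.raises(ConfigError):
            delay_decoder_timecourse(trials, (10.0, 11.0))

    def test_permutation_and_scaling_invariance(self):
        """Accuracy is invariant to neuron reordering and a global positive
        rescaling of the rates."""
        rng = np.random.default_rng(6)
        trials = _static_trials(rng, sigma=0.8)
        acc0, _ = delay_decoder_timecourse(trials, (0.3, 0.55), seed=7)
        perm = rng.permutation(trials.n_neurons)
        tt_perm = TrialTensor(3.0 * trials.rates[:, perm, :], trials.labels,
                              trials.time, dt=trials.dt)
        acc1, _ = delay_decoder_timecourse(tt_perm, (0.3, 0.55), seed=7)
        assert np.allclose(acc0, acc1)

    def test_logistic_decoder_agrees_qualitatively(self):
        trials = _static_trials(np.random.default_rng(8), sigma=0.5)
        acc_c, _ = delay_decoder_timecourse(trials, (0.3, 0.55), seed=9)
        acc_l, _ = delay_decoder_timecourse(trials, (0.3, 0.55), seed=9,
                                            decoder="logistic")
        assert np.mean(np.abs(acc_c - acc_l)) < 0.1


class TestCrossTemporal:
    def test_static_code_generalizes_everywhere(self):
        trials = _static_trials(np.random.default_rng(10), sigma=0.3,
                                trials_per=20)
        mat = cross_temporal_matrix(trials, cv_folds=4, seed=11)
        diag = np.diag(mat.accuracy)
        assert np.all(np.abs(mat.accuracy - diag.mean()) < 0.15)

    def test_orthogonal_epochs_block_structure(self):
        """Condition patterns orthogonal between two epochs: within-epoch
        decoding high, cross-epoch at chance."""
        rng = np.random.default_rng(12)
        C, N, B, tp = 4, 40, 10, 15
        early = np.zeros((C, N))
        late = np.zeros((C, N))
        early[:, :20] = rng.normal(size=(C, 20)) * 3
        late[:, 20:] = rng.normal(size=(C, 20)) * 3
        labels = np.repeat(np.arange(C), tp)
        rates = np.empty((C * tp, N, B))
        rates[:, :, :5] = early[labels][:, :, None]
        rates[:, :, 5:] = late[labels][:, :, None]
        rates += 0.5 * rng.normal(size=rates.shape)
        tt = TrialTensor(rates, labels, 0.1 * np.arange(B), dt=0.1)
        mat = cross_temporal_matrix(tt, cv_folds=3, seed=13).accuracy
        within = np.concatenate([mat[:5, :5].ravel(), mat[5:, 5:].ravel()])
        across = np.concatenate([mat[:5, 5:].ravel(), mat[5:, :5].ravel()])
        assert within.mean() > 0.9
        assert abs(across.mean() - 0.25) < 0.1

    def test_amplifying_loading_shows_dynamic_coding(self):
        """Amplifying-loaded linear network: early-trained decoders do not
        generalize to the late delay (off-diagonal gap > 0.3) although
        same-time decoding is high early; slow transfer keeps the early code
        distinct from the late one."""
        from infoload.linear import make_feedforward_network

        net = make_feedforward_network(60, ff_gain=1.0, fast_rates=(0.3, 0.6),
                                       seed=3, tau=1.0)
        U = loading_vectors(net, "amplifying", n_conditions=6, seed=4)
        tt = simulate_loading_trials(net, U, T=6.0, dt_bin=0.25,
                                     n_trials_per_cond=30, sigma=0.02, seed=5)
        rng = np.random.default_rng(7)
        tt = TrialTensor(tt.rates + 0.2 * rng.standard_normal(tt.rates.shape),
                         tt.labels, tt.time, dt=tt.dt, events=tt.events,
                         n_conditions=6)
        mat = cross_temporal_matrix(tt, cv_folds=4, seed=6).accuracy
        B = mat.shape[0]
        early = slice(1, 4)  # 0.25-0.75 s, during the amplifying transient
        late = slice(B - 8, B)
        late_block = mat[late, late].mean()
        cross = 0.5 * (mat[early, late].mean() + mat[late, early].mean())
        assert mat[1, 1] > 0.8          # same-time decodable early
        assert cross < late_block - 0.3  # but the code does not generalize


@pytest.fixture(scope="module")
def calibration_net():
    return make_random_network(60, "unconstrained", seed=20)


class TestMatchPerformanceNoise:
    @pytest.fixture()
    def net(self, calibration_net):
        return calibration_net

    def test_noiseless_accuracy_is_one(self, net):
        U = loading_vectors(net, "amplifying", n_conditions=2, seed=21)
        tt = simulate_loading_trials(net, U, T=8.0, dt_bin=0.5,
                                     n_trials_per_cond=30, sigma=0.0, seed=22)
        acc, _ = delay_decoder_timecourse(tt, (7.0, 8.0), cv_folds=2, seed=23)
        assert acc[-1] == 1.0

    def test_accuracy_nonincreasing_in_sigma(self, net):
        U = loading_vectors(net, "amplifying", n_conditions=2, seed=24)
        accs = []
        for sigma in np.linspace(0.0, 1.8, 10):
            tt = simulate_loading_trials(net, U, T=8.0, dt_bin=1.0,
                                         n_trials_per_cond=150, sigma=sigma,
                                         seed=25)
            acc, _ = delay_decoder_timecourse(tt, (7.0, 8.0), cv_folds=2,
                                              seed=26)
            accs.append(acc[-1])
        assert np.all(np.diff(accs) <= 0.02 + 1e-12)

    def test_calibration_hits_target(self, net):
        U = loading_vectors(net, "amplifying", n_conditions=2, seed=27)
        sigma = match_performance_noise(net, U, target_accuracy=0.85, tol=0.03,
                                        seed=28, T=8.0, n_trials=400)
        tt = simulate_loading_trials(net, U, T=8.0, dt_bin=0.5,
                                     n_trials_per_cond=200, sigma=sigma,
                                     seed=999)
        acc, _ = delay_decoder_timecourse(tt, (7.2, 8.0), cv_folds=2, seed=998)
        mask = tt.time >= 7.2
        assert abs(acc[mask].mean() - 0.85) <= 0.03 + 0.03

    def test_unreachable_target(self, net):
        # a zero-information loading cannot reach high accuracy even at sigma=0
        U = np.zeros((2, net.n_neurons))
        U[:, 0] = 1e-9
        with pytest.raises(CalibrationError):
            match_performance_noise(net, U, target_accuracy=0.99, tol=0.01,
                                    seed=29, T=4.0, n_trials=100)

    def test_amplifying_beats_other_loadings_at_fixed_noise(self):
        """End-of-delay decodability ordering across 10 networks."""
        wins = 0
        for seed in range(10):
            net = make_random_network(100, "unconstrained", seed=seed)
            accs = {}
            for strat in ("amplifying", "persistent", "random"):
                U = loading_vectors(net, strat, n_conditions=2, horizon=10.0,
                                    seed=seed)
                tt = simulate_loading_trials(net, U, T=10.0, dt_bin=0.5,
                                             n_trials_per_cond=40, sigma=0.6,
                                             seed=seed + 50)
                acc, _ = delay_decoder_timecourse(tt, (9.0, 10.0), cv_folds=4,
                                                  seed=seed + 60)
                accs[strat] = acc[-3:].mean()
            if (accs["amplifying"] >= accs["persistent"] - 0.02
                    and accs["amplifying"] >= accs["random"] - 0.02):
                wins += 1
        assert wins >= 9
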