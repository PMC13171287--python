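import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from popstate.hmm import (
    CVReport,
    PoissonHMM,
    cv_error,
    em_fit,
    emission_logprob,
    forward_backward,
    label_on_off,
    multi_restart_fit,
    select_num_phases,
    session_counts,
    viterbi,
)
from popstate.synthetic import GeneratorConfig, sample_state_sequence


# ---------------------------------------------------------------- oracles


def path_logprob(path, counts, model):
    lp = np.log(model.pi0[path[0]])
    for t in range(1, len(path)):
        lp += np.log(model.P[path[t - 1], path[t]])
    for t, s in enumerate(path):
        for j in range(counts.shape[0]):
            lp += emission_logprob(counts[j, t], model.lam[s, j])
    return lp


def enumeration_loglik(counts, model):
    T = counts.shape[1]
    lps = [
        path_logprob(path, counts, model)
        for path in itertools.product(range(model.n_phases), repeat=T)
    ]
    return logsumexp(lps)


def enumeration_viterbi(counts, model):
    T = counts.shape[1]
    best, best_lp = None, -np.inf
    for path in itertools.product(range(model.n_phases), repeat=T):
        lp = path_logprob(path, counts, model)
        if lp > best_lp:
            best_lp, best = lp, path
    return np.array(best)


def random_model(rng, n_phases=2, n_channels=2):
    return PoissonHMM(
        lam=rng.uniform(0.1, 3.0, size=(n_phases, n_channels)),
        P=rng.dirichlet(np.ones(n_phases), size=n_phases),
        pi0=rng.dirichlet(np.ones(n_phases)),
    )


def two_state_trials(rng, n_trials=100, n_bins=300, n_channels=16,
                     lam_off=0.2, lam_on=2.0, p_stay=0.98):
    trials, states = [], []
    for _ in range(n_trials):
        st = sample_state_sequence(p_stay, p_stay, (0.5, 0.5), n_bins, rng)
        lam = np.where(st == 1, lam_on, lam_off)
        trials.append(rng.poisson(np.tile(lam, (n_channels, 1))))
        states.append(st)
    return trials, states


# ---------------------------------------------------------------- tests


class TestEmissionLogprob:
    def test_zero_count(self):
        assert emission_logprob(0, 2.0) == pytest.approx(np.log(np.exp(-2.0)))

    def test_degenerate_poisson(self):
        assert emission_logprob(0, 0.0) == 0.0
        assert emission_logprob(3, 0.0) == -np.inf

    def test_closed_form(self):
        lam = 3.0
        expected = np.log(lam**3 * np.exp(-lam) / 6.0)
        assert emission_logprob(3, lam) == pytest.approx(expected, rel=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            emission_logprob(-1, 1.0)


class TestForwardBackward:
    def test_single_phase(self, rng):
        lam = np.array([[0.5, 1.5]])
        model = PoissonHMM(lam=lam, P=np.array([[1.0]]), pi0=np.array([1.0]))
        counts = rng.poisson(1.0, size=(2, 20))
        gamma, ll = forward_backward(counts, model)
        assert np.allclose(gamma, 1.0)
        direct = sum(
            emission_logprob(counts[j, t], lam[0, j])
            for j in range(2)
            for t in range(20)
        )
        assert ll == pytest.approx(direct, abs=1e-9)

    def test_single_bin_posterior(self, rng):
        model = random_model(rng)
        counts = rng.poisson(1.0, size=(2, 1))
        gamma, ll = forward_backward(counts, model)
        b = np.array(
            [
                sum(emission_logprob(counts[j, 0], model.lam[s, j]) for j in range(2))
                for s in range(2)
            ]
        )
        unnorm = model.pi0 * np.exp(b)
        assert np.allclose(gamma[0], unnorm / unnorm.sum(), atol=1e-12)
        assert ll == pytest.approx(np.log(unnorm.sum()), abs=1e-9)

    def test_matches_enumeration(self, rng):
        for _ in range(5):
            model = random_model(rng)
            counts = rng.poisson(1.0, size=(2, 5))
            _, ll = forward_backward(counts, model)
            assert ll == pytest.approx(enumeration_loglik(counts, model), abs=1e-9)

    def test_posteriors_normalized(self, rng):
        model = random_model(rng, n_phases=3, n_channels=4)
        counts = rng.poisson(2.0, size=(4, 30))
        gamma, _ = forward_backward(counts, model)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)


class TestEmFit:
    def test_one_phase_closed_form(self, rng):
        trials = [rng.poisson(1.3, size=(3, 50)) for _ in range(4)]
        model = em_fit(trials, 1)
        stacked = np.hstack(trials)
        assert np.allclose(model.lam[0], stacked.mean(axis=1), atol=1e-12)
        assert model.converged

    def test_all_zero_counts(self):
        trials = [np.zeros((3, 40), dtype=int)]
        model = em_fit(trials, 1)
        assert np.allclose(model.lam, 0.0, atol=1e-12)
        assert model.log_likelihood == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1234)
        trials, _ = two_state_trials(rng, n_trials=60, n_bins=300, n_channels=8)
        model = em_fit(trials, 2)
        on = int(np.argmax(model.lam.mean(axis=1)))
        assert np.abs(model.lam[on] - 2.0).max() / 2.0 < 0.1
        assert np.abs(model.lam[1 - on] - 0.2).max() / 0.2 < 0.1
        assert abs(model.P[on, on] - 0.98) < 0.01
        assert abs(model.P[1 - on, 1 - on] - 0.98) < 0.01

    def test_loglik_monotone(self, rng):
        trials, _ = two_state_trials(rng, n_trials=10, n_bins=100, n_channels=4)
        lls = []
        init = None
        prev_model = None
        # run EM one iteration at a time and track the likelihood
        from popstate.hmm import _loglik, _random_init, _as_trials

        trials = _as_trials(trials)
        model = _random_init(trials, 2, rng)
        for _ in range(15):
            lls.append(_loglik(trials, model))
            model = em_fit(trials, 2, init=model, max_iter=1, loglik_rtol=0.0)
        diffs = np.diff(lls)
        assert np.all(diffs >= -1e-8)

    def test_invariants(self, rng):
        trials, _ = two_state_trials(rng, n_trials=8, n_bins=80, n_channels=4)
        model = em_fit(trials, 2)
        assert np.max(np.abs(model.P.sum(axis=1) - 1.0)) < 1e-12
        assert model.pi0.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(model.lam >= 0)

    def test_bias_shrinks_with_data(self):
        biases = []
        for n_trials in (10, 80):
            rng = np.random.default_rng(5)
            trials, _ = two_state_trials(
                rng, n_trials=n_trials, n_bins=200, n_channels=6
            )
            model = em_fit(trials, 2)
            on = int(np.argmax(model.lam.mean(axis=1)))
            biases.append(abs(model.lam[on].mean() - 2.0))
        assert biases[1] <= biases[0] + 0.01


class TestMultiRestart:
    def test_one_phase_identical(self, rng):
        trials = [rng.poisson(1.0, size=(3, 60))]
        a = multi_restart_fit(trials, 1, np.random.default_rng(0))
        b = em_fit(trials, 1)
        assert np.allclose(a.lam, b.lam)

    def test_deterministic_under_seed(self, rng):
        trials, _ = two_state_trials(rng, n_trials=6, n_bins=80, n_channels=4)
        a = multi_restart_fit(trials, 2, np.random.default_rng(7), n_restarts=3)
        b = multi_restart_fit(trials, 2, np.random.default_rng(7), n_restarts=3)
        assert np.allclose(a.lam, b.lam)
        assert a.log_likelihood == b.log_likelihood

    def test_best_of_restarts(self, rng):
        trials, _ = two_state_trials(rng, n_trials=6, n_bins=80, n_channels=4)
        from popstate.hmm import _as_trials, _random_init

        tlist = _as_trials(trials)
        restart_rng = np.random.default_rng(3)
        lls = [
            em_fit(tlist, 2, init=_random_init(tlist, 2, restart_rng)).log_likelihood
            for _ in range(5)
        ]
        best = multi_restart_fit(trials, 2, np.random.default_rng(3), n_restarts=5)
        assert best.log_likelihood >= max(lls) - 1e-9


class TestViterbi:
    def test_matches_enumeration_small(self):
        model = PoissonHMM(
            lam=np.array([[1.0], [5.0]]),
            P=np.array([[0.9, 0.1], [0.1, 0.9]]),
            pi0=np.array([0.5, 0.5]),
        )
        counts = np.array([[0, 0, 6, 7]])
        path = viterbi(counts, model).phases
        assert np.array_equal(path, enumeration_viterbi(counts, model))

    def test_matches_enumeration_random(self, rng):
        for _ in range(10):
            model = random_model(rng)
            counts = rng.poisson(1.5, size=(2, 8))
            path = viterbi(counts, model).phases
            want = enumeration_viterbi(counts, model)
            assert path_logprob(tuple(path), counts, model) == pytest.approx(
                path_logprob(tuple(want), counts, model), abs=1e-9
            )

    def test_single_phase_constant(self, rng):
        model = PoissonHMM(
            lam=np.array([[1.0, 2.0]]), P=np.array([[1.0]]), pi0=np.array([1.0])
        )
        path = viterbi(rng.poisson(1.0, size=(2, 30)), model).phases
        assert np.all(path == 0)

    def test_accuracy_on_separated_rates(self):
        rng = np.random.default_rng(21)
        trials, states = two_state_trials(
            rng, n_trials=20, n_bins=200, n_channels=8, lam_off=0.3, lam_on=3.0
        )
        model = em_fit(trials, 2)
        mapping = label_on_off(model)
        on = next(k for k, v in mapping.items() if v == "ON")
        hits = total = 0
        for counts, st in zip(trials, states):
            path = viterbi(counts, model).phases
            hits += np.sum((path == on) == (st == 1))
            total += st.size
        assert hits / total >= 0.9

    def test_beats_random_paths(self, rng):
        model = random_model(rng, n_channels=3)
        counts = rng.poisson(1.0, size=(3, 40))
        best = path_logprob(tuple(viterbi(counts, model).phases), counts, model)
        for _ in range(100):
            alt = tuple(rng.integers(0, 2, size=40))
            assert best >= path_logprob(alt, counts, model) - 1e-9


class TestLabelOnOff:
    def test_larger_mean_is_on(self):
        model = PoissonHMM(
            lam=np.array([[0.2, 0.2], [2.0, 2.0]]),
            P=np.full((2, 2), 0.5),
            pi0=np.array([0.5, 0.5]),
        )
        assert label_on_off(model) == {1: "ON", 0: "OFF"}

    def test_swapped_rows_swap_labels(self):
        model = PoissonHMM(
            lam=np.array([[2.0, 2.0], [0.2, 0.2]]),
            P=np.full((2, 2), 0.5),
            pi0=np.array([0.5, 0.5]),
        )
        assert label_on_off(model) == {0: "ON", 1: "OFF"}

    def test_tie_errors(self):
        model = PoissonHMM(
            lam=np.array([[1.0, 1.0], [1.0, 1.0]]),
            P=np.full((2, 2), 0.5),
            pi0=np.array([0.5, 0.5]),
        )
        with pytest.raises(ValueError, match="ambiguous"):
            label_on_off(model)

    def test_wrong_phase_count(self):
        model = PoissonHMM(
            lam=np.array([[1.0]]), P=np.array([[1.0]]), pi0=np.array([1.0])
        )
        with pytest.raises(ValueError):
            label_on_off(model)


class TestCrossValidation:
    def test_one_phase_normalizes_to_unity(self, rng):
        trials, _ = two_state_trials(rng, n_trials=8, n_bins=60, n_channels=4)
        mean_err, per_fold = cv_error(trials, 1, rng=np.random.default_rng(0))
        assert mean_err == pytest.approx(1.0, abs=1e-12)
        assert all(v == pytest.approx(1.0, abs=1e-12) for v in per_fold)

    def test_two_state_data_improves(self):
        rng = np.random.default_rng(8)
        trials, _ = two_state_trials(rng, n_trials=24, n_bins=150, n_channels=8)
        mean_err, _ = cv_error(
            trials, 2, rng=np.random.default_rng(1), n_restarts=3
        )
        assert mean_err <= 0.9

    def test_null_data_no_big_gain(self):
        rng = np.random.default_rng(9)
        trials = [rng.poisson(1.0, size=(8, 150)) for _ in range(24)]
        mean_err, _ = cv_error(
            trials, 2, rng=np.random.default_rng(2), n_restarts=3
        )
        assert 1.0 - mean_err < 0.1

    def test_too_few_trials(self, rng):
        trials, _ = two_state_trials(rng, n_trials=3, n_bins=30, n_channels=2)
        with pytest.raises(ValueError, match="at least 4"):
            cv_error(trials, 2)

    def test_label_permutation_invariance(self, rng):
        trials, _ = two_state_trials(rng, n_trials=8, n_bins=60, n_channels=4)
        model = em_fit(trials, 2)
        permuted = PoissonHMM(
            lam=model.lam[::-1].copy(),
            P=model.P[::-1, ::-1].copy(),
            pi0=model.pi0[::-1].copy(),
        )
        from popstate.hmm import _held_out_error, _loglik

        assert _loglik(trials, permuted) == pytest.approx(
            _loglik(trials, model), abs=1e-8
        )
        assert np.allclose(
            _held_out_error(trials, permuted), _held_out_error(trials, model)
        )


class TestSelectNumPhases:
    def test_two_state_selected(self):
        rng = np.random.default_rng(31)
        trials, _ = two_state_trials(rng, n_trials=24, n_bins=150, n_channels=8)
        report = select_num_phases(
            trials, s_range=[1, 2, 3], rng=np.random.default_rng(0), n_restarts=3
        )
        assert report.selected == 2
        assert report.passed is True

    def test_null_data_fails(self):
        rng = np.random.default_rng(32)
        trials = [rng.poisson(1.0, size=(8, 150)) for _ in range(24)]
        report = select_num_phases(
            trials, s_range=[1, 2], rng=np.random.default_rng(0), n_restarts=3
        )
        assert report.passed is False

    def test_degenerate_range(self, rng):
        trials, _ = two_state_trials(rng, n_trials=8, n_bins=50, n_channels=4)
        report = select_num_phases(trials, s_range=[1], rng=np.random.default_rng(0))
        assert report.selected == 1
        assert report.passed is None


class TestSessionCounts:
    def test_shapes_and_alignment(self):
        config = GeneratorConfig(n_channels=4, n_trials=(5, 5), seed=3)
        from popstate.synthetic import generate_session

        session, truth = generate_session(config)
        counts, trial_ids = session_counts(session, "cue_to_dimming", "attend_RF")
        assert len(counts) == 5
        for mat in counts:
            assert mat.shape[0] == 4

    def test_counts_match_ground_truth_statistics(self):
        config = GeneratorConfig(
            n_channels=2, n_trials=(30, 30), seed=13, p_stay_on=0.9
        )
        from popstate.synthetic import generate_session

        session, truth = generate_session(config)
        counts, _ = session_counts(session, "cue_to_dimming", "attend_away")
        stacked = np.hstack(counts)
        # overall mean should sit between the OFF and ON emission means
        lam_off, lam_on = truth.emission[0, 0], truth.emission[1, 0]
        assert lam_off < stacked.mean() < lam_on
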