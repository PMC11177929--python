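"""Poisson independent decoder, batching, cross-temporal matrices, SVM harness."""

import numpy as np
import pytest
from scipy import stats

from wmv1.decode import (BatchSet, DecodingMatrix, TuningFunction,
                         cross_temporal_matrix, fit_pid, make_batches,
                         make_windows, permutation_null, pid_decode,
                         pid_loglik, svm_cross_task, window_counts)
from wmv1.simulate import SimConfig, simulate_session


class TestWindows:
    def test_standard_grid(self):
        w = make_windows((-200, 1700), 200, 50)
        assert len(w) == 35
        assert w[0] == (-200, 0) and w[-1] == (1500, 1700)

    def test_single_and_tiling(self):
        assert make_windows((0, 500), 500, 50) == [(0, 500)]
        tiles = make_windows((0, 1000), 200, 200)
        assert tiles == [(0, 200), (200, 400), (400, 600), (600, 800), (800, 1000)]

    def test_bad_step(self):
        with pytest.raises(ValueError):
            make_windows((0, 1000), 200, 0)


class TestBatches:
    def test_counts_per_condition(self, default_session):
        _, s = default_session  # 120 trials/condition, 6 incorrect
        w = make_windows((0, 1700), 200, 200)
        b = make_batches(s, w, batch_size=20)
        # 114 correct per condition -> 5 batches each, 19 dropped
        for c in np.unique(b.labels):
            assert (b.labels == c).sum() == 5

    def test_batch_means_equal_bruteforce(self, default_session):
        _, s = default_session
        w = [(700.0, 900.0)]
        b = make_batches(s, w, batch_size=20)
        correct = s.subset_trials(s.correct_mask())
        counts = window_counts(correct, w)[:, 0, :]
        labels = correct.condition_labels()
        c0 = np.unique(labels)[0]
        members = np.flatnonzero(labels == c0)[:20]
        assert np.allclose(b.counts[0, 0, :], counts[members].mean(axis=0))

    def test_insufficient_trials_error(self, default_session):
        _, s = default_session
        with pytest.raises(ValueError, match="batch_size"):
            make_batches(s, [(0.0, 200.0)], batch_size=1000)


def constant_batchset(levels, n_batches=6):
    """One window; condition ci has constant count levels[i]."""
    counts, labels = [], []
    for i, lv in enumerate(levels):
        counts += [[[lv]]] * n_batches
        labels += [f"c{i}"] * n_batches
    return BatchSet(np.array(counts, dtype=float), np.array(labels),
                    [(0.0, 200.0)], batch_size=1)


class TestPid:
    def test_tuning_is_condition_mean_with_floor(self):
        b = constant_batchset([2.0, 4.0])
        t = fit_pid(b, 0)
        assert np.allclose(t.f[:, 0], [2.0, 4.0])
        b0 = constant_batchset([0.0, 4.0])
        assert fit_pid(b0, 0, floor=0.01).f[0, 0] == 0.01

    def test_loglik_hand_example_one_electrode(self):
        t = TuningFunction(np.array([[2.0], [4.0]]), np.array(["t1", "t2"]))
        pred, ll = pid_decode(t, np.array([3.0]))
        assert ll[0] == pytest.approx(3 * np.log(2) - 2, abs=1e-9)
        assert ll[1] == pytest.approx(3 * np.log(4) - 4, abs=1e-9)
        assert pred == "t2"

    def test_loglik_hand_example_two_electrodes(self):
        t = TuningFunction(np.array([[4.0, 2.0], [2.0, 4.0]]),
                           np.array(["t1", "t2"]))
        pred, ll = pid_decode(t, np.array([4.0, 2.0]))
        assert ll[0] == pytest.approx(4 * np.log(4) + 2 * np.log(2) - 6, abs=1e-9)
        assert ll[1] == pytest.approx(4 * np.log(2) + 2 * np.log(4) - 6, abs=1e-9)
        assert pred == "t1"

    def test_tie_predictions_uniform(self):
        t = TuningFunction(np.array([[3.0], [3.0], [3.0], [3.0]]),
                           np.array(["a", "b", "c", "d"]))
        rng = np.random.default_rng(0)
        picks = [pid_decode(t, np.array([2.0]), rng)[0] for _ in range(1000)]
        freq = np.array([picks.count(c) for c in "abcd"]) / 1000
        assert np.all(np.abs(freq - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 1000))

    def test_negative_counts_rejected(self):
        t = TuningFunction(np.array([[2.0], [4.0]]), np.array(["a", "b"]))
        with pytest.raises(ValueError):
            pid_loglik(t, np.array([-1.0]))

    def test_map_equivalence_against_posterior_oracle(self):
        # flat bias: Eq-style argmax == naive-Bayes Poisson MAP (uniform prior)
        rng = np.random.default_rng(1)
        for _ in range(1000):
            c, e = rng.integers(2, 5), rng.integers(1, 4)
            f = rng.uniform(0.5, 8.0, (c, e + 1))
            partial = f[:, :-1].sum(axis=1)
            f[:, -1] = partial.max() + 1.0 - partial
            assert np.allclose(f.sum(axis=1), f.sum(axis=1)[0])
            n = rng.integers(0, 10, e + 1).astype(float)
            t = TuningFunction(f, np.arange(c))
            ll = pid_loglik(t, n)
            post = np.prod(stats.poisson.pmf(n[None, :], f), axis=1)
            if (post == post.max()).sum() > 1 or (ll == ll.max()).sum() > 1:
                continue
            assert np.argmax(ll) == np.argmax(post)

    def test_uninformative_electrode_never_changes_prediction(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            f = rng.uniform(0.5, 8.0, (4, 3))
            n = rng.integers(0, 12, 3).astype(float)
            base = pid_loglik(TuningFunction(f, np.arange(4)), n)
            f2 = np.concatenate([f, np.full((4, 1), 5.0)], axis=1)
            n2 = np.concatenate([n, [7.0]])
            aug = pid_loglik(TuningFunction(f2, np.arange(4)), n2)
            assert np.argmax(base) == np.argmax(aug)


def delay_session(effect, seed, n_electrodes=6, n_trials=80):
    levels = np.array([1.0, 0.4, -0.4, -1.0]) * effect
    delta = np.tile(levels, (n_electrodes, 1))
    cfg = SimConfig(n_electrodes=n_electrodes, n_trials_per_condition=n_trials,
                    seed=seed, stim_gain=np.ones((n_electrodes, 4)),
                    delay_delta=delta, off_response_amp=0.0,
                    incorrect_fraction=0.0)
    return simulate_session(cfg)


class TestCrossTemporal:
    def test_stimulus_only_tuning_structure(self):
        cfg = SimConfig(n_electrodes=6, n_trials_per_condition=110, seed=10,
                        delay_delta=np.zeros((6, 4)), incorrect_fraction=0.0)
        s = simulate_session(cfg)
        w = make_windows((-200, 1700), 200, 200)
        b = make_batches(s, w, batch_size=10)
        m = cross_temporal_matrix(b, train_per_condition=8, repetitions=30, seed=0)
        diag = np.diag(m.accuracy)
        stim_i = [i for i, (a, _) in enumerate(w) if a == 0][0]
        delay_i = [i for i, (a, _) in enumerate(w) if a >= 800]
        assert diag[stim_i] > 0.6
        assert abs(np.mean(diag[delay_i]) - 0.25) < 0.12

    def test_shuffled_labels_at_chance(self):
        s = delay_session(0.0, seed=3)
        w = make_windows((700, 1700), 200, 500)
        b = make_batches(s, w, batch_size=10)
        m = cross_temporal_matrix(b, train_per_condition=6, repetitions=50,
                                  n_perm=60, seed=1)
        p = m.pvalues()
        lo, hi = np.percentile(m.null_distribution, [2.5, 97.5], axis=0)
        inside = (m.accuracy >= lo) & (m.accuracy <= hi)
        assert inside.mean() >= 0.75
        assert (p > 0.05).mean() >= 0.75

    def test_accuracy_monotone_in_delay_effect(self):
        means = []
        for effect in (0.0, 2.0, 5.0):
            accs = []
            for seed in range(10):
                s = delay_session(effect, seed=seed)
                w = [(700.0, 1200.0), (1200.0, 1700.0)]
                b = make_batches(s, w, batch_size=10)
                m = cross_temporal_matrix(b, train_per_condition=6,
                                          repetitions=20, seed=seed)
                accs.append(np.diag(m.accuracy).mean())
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]

    def test_insufficient_batches_names_condition(self, default_session):
        _, s = default_session
        w = [(700.0, 1700.0)]
        b = make_batches(s, w, batch_size=20)  # 5 batches per condition
        with pytest.raises(ValueError, match="c0"):
            cross_temporal_matrix(b, train_per_condition=15, repetitions=2)


class TestPermutation:
    def test_pvalue_definition(self):
        null = np.concatenate([np.linspace(0.1, 0.5, 99)])
        m = DecodingMatrix(np.array([[0.5]]), [(0, 200)], 1, 0.25,
                           null.reshape(-1, 1, 1))
        assert m.pvalues()[0, 0] == pytest.approx(2 / 100)  # ties at the max
        m_low = DecodingMatrix(np.array([[0.0]]), [(0, 200)], 1, 0.25,
                               null.reshape(-1, 1, 1))
        assert m_low.pvalues()[0, 0] == pytest.approx(1.0)

    def test_null_centers_at_chance(self):
        s = delay_session(4.0, seed=5)
        w = [(700.0, 1700.0)]
        b = make_batches(s, w, batch_size=10)
        p, null = permutation_null(b, observed=0.9, window_index=0,
                                   n_perm=120, train_per_condition=6, seed=2)
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean() - 0.25) < 3 * se + 0.01
        assert p < 0.05
        with pytest.raises(ValueError):
            permutation_null(b, 0.9, 0, n_perm=10)


class TestSvmCrossTask:
    def test_shared_tuning_generalizes(self):
        train = delay_session(6.0, seed=0, n_trials=60)
        test = delay_session(6.0, seed=1, n_trials=60)
        cmap = {c: c for c in ("c0", "c1", "c2", "c3")}
        accs = svm_cross_task(train, test, (700.0, 1700.0), cmap,
                              n_per_condition=40, iters=8, seed=0)
        assert accs.mean() > 0.25 + 3 * accs.std(ddof=1) / np.sqrt(len(accs))

    def test_independent_tuning_at_chance(self):
        train = delay_session(6.0, seed=0, n_trials=60)
        cfg = SimConfig(n_electrodes=6, n_trials_per_condition=60, seed=99,
                        stim_gain=np.ones((6, 4)),
                        delay_delta=np.tile([-1.0, 1.0, 6.0, -6.0], (6, 1)) * 0.0,
                        off_response_amp=0.0, incorrect_fraction=0.0)
        test = simulate_session(cfg)
        cmap = {c: c for c in ("c0", "c1", "c2", "c3")}
        accs = svm_cross_task(train, test, (700.0, 1700.0), cmap,
                              n_per_condition=40, iters=8, seed=0)
        assert abs(accs.mean() - 0.25) < 0.1

    def test_unmapped_condition_rejected(self):
        train = delay_session(6.0, seed=0, n_trials=30)
        test = delay_session(6.0, seed=1, n_trials=30)
        with pytest.raises(ValueError, match="unmapped"):
            svm_cross_task(train, test, (700.0, 1700.0), {"c0": "c0"},
                           n_per_condition=10, iters=1, seed=0)
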