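"""KNN decoding: set construction, brute-force oracle equivalence,
invariances, s.f.-split decoders, matching, and fixed-classifier drift."""

import itertools

import numpy as np
import pytest

from driftlab.decoding import (fixed_classifier_drift, knn_decode, make_sets,
                               sf_split_decode, shuffle_labels,
                               subsample_match)
from driftlab.grid import StimulusGrid, default_grid
from driftlab.synthgen import (SessionData, generate_session,
                               random_population)


def _session(grid, responses, ids=None, baseline=None):
    n, s, t = responses.shape
    return SessionData(responses=responses,
                       baseline_samples=np.ones((n, 10))
                       if baseline is None else baseline,
                       locomotion=np.zeros((s, t), bool),
                       blink=np.zeros((s, t), bool),
                       neuron_ids=np.arange(n) if ids is None else ids,
                       grid=grid)


def brute_force_knn(sets, k):
    """Independent oracle: exhaustive set-based CV KNN with the same
    deterministic tie rules, written as plain loops over pairs."""
    n_set, n_stim, n_neurons = sets.shape
    correct = total = 0
    for held in range(n_set):
        train = [(si, st, sets[si, st]) for si in range(n_set)
                 for st in range(n_stim) if si != held]
        for st in range(n_stim):
            x = sets[held, st]
            scored = sorted(
                (float(np.sqrt(np.sum((x - v) ** 2))), si, stj)
                for si, stj, v in train)
            top = scored[:k]
            votes = {}
            for d, si, stj in top:
                votes[stj] = votes.get(stj, 0) + 1
            best = max(votes.values())
            tied = {c for c, v in votes.items() if v == best}
            for d, si, stj in top:
                if stj in tied:
                    pred = stj
                    break
            correct += pred == st
            total += 1
    return correct / total


class TestMakeSets:
    def test_25_trials_by_180_stimuli_gives_25_sets(self, grid):
        truth = random_population(grid, 3, seed=1)
        sess = generate_session(grid, truth, 25, seed=2,
                                locomotion_rate=0.0, blink_rate=0.0)
        sets = make_sets(sess.responses)
        assert sets.shape == (25, 180, 3)

    def test_single_trial_gives_one_set_and_cv_errors(self, small_grid):
        truth = random_population(small_grid, 2, seed=3)
        sess = generate_session(small_grid, truth, 1, seed=4,
                                locomotion_rate=0.0, blink_rate=0.0)
        sets = make_sets(sess.responses)
        assert sets.shape[0] == 1
        with pytest.raises(ValueError, match="2 sets"):
            knn_decode(sets, k=1)

    def test_subsampling_reproducible_from_seed(self, small_grid):
        truth = random_population(small_grid, 4, seed=5)
        sess = generate_session(small_grid, truth, 20, seed=6,
                                locomotion_rate=0.0, blink_rate=0.0)
        a = make_sets(sess.responses, n_sets=8, seed=42)
        b = make_sets(sess.responses, n_sets=8, seed=42)
        c = make_sets(sess.responses, n_sets=8, seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_every_set_holds_one_trial_per_stimulus(self, small_grid):
        rng = np.random.default_rng(7)
        resp = rng.poisson(2.0, (2, small_grid.n_stim, 6)).astype(float)
        sets = make_sets(resp, seed=0)
        # each (set, stimulus) vector must be one of that stimulus' trials
        for si in range(sets.shape[0]):
            for st in range(small_grid.n_stim):
                assert any(np.array_equal(sets[si, st], resp[:, st, t])
                           for t in range(6))


class TestKnnDecode:
    def test_orthogonal_one_hot_population_is_perfect(self):
        grid = StimulusGrid(np.arange(0.0, 180.0, 45.0),
                            np.array([0.1]))  # 4 stimuli
        n_stim = grid.n_stim
        resp = np.zeros((n_stim, n_stim, 5))
        for s in range(n_stim):
            resp[s, s, :] = 10.0
        res = knn_decode(_session(grid, resp), k=4)
        assert res.accuracy == 1.0
        assert np.array_equal(res.confusion, np.diag([5] * n_stim))

    def test_equals_brute_force_enumeration(self):
        """Exact equality with an exhaustive all-pairs oracle on small
        instances (<= 5 stimuli, <= 4 sets), across k."""
        rng = np.random.default_rng(8)
        for n_stim, n_set, n_neur, k in [(3, 3, 2, 1), (5, 4, 3, 2),
                                         (4, 4, 2, 3), (5, 3, 4, 2)]:
            sets = rng.normal(2.0, 1.0, (n_set, n_stim, n_neur))
            res = knn_decode(sets, k=k)
            assert res.accuracy == pytest.approx(brute_force_knn(sets, k))

    def test_hand_worked_three_stimulus_fixture(self):
        """3 stimuli x 2 sets x 2 neurons, k=1: distances small enough to
        enumerate by hand; every test vector's nearest neighbor in the
        other set shares its label, so accuracy is 1."""
        sets = np.array([
            [[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]],
            [[1.0, 0.0], [9.0, 0.0], [0.0, 9.0]],
        ])
        res = knn_decode(sets, k=1)
        assert res.accuracy == 1.0

    def test_chance_level_after_label_shuffle(self, small_grid):
        truth = random_population(small_grid, 8, tuned_fraction=1.0, seed=9)
        sess = generate_session(small_grid, truth, 12, seed=10,
                                locomotion_rate=0.0, blink_rate=0.0)
        shuffled = shuffle_labels(sess.responses, seed=11)
        res = knn_decode(_session(small_grid, shuffled), k=4)
        n_tested = res.confusion.sum()
        chance = 1.0 / small_grid.n_stim
        sd = np.sqrt(chance * (1 - chance) / n_tested)
        assert abs(res.accuracy - chance) < 3 * sd

    def test_relabeling_invariance(self):
        """Applying one permutation to the stimulus axis everywhere leaves
        accuracy unchanged."""
        rng = np.random.default_rng(12)
        sets = rng.normal(0, 1, (4, 6, 3))
        perm = rng.permutation(6)
        res1 = knn_decode(sets, k=3)
        res2 = knn_decode(sets[:, perm, :], k=3)
        assert res2.accuracy == pytest.approx(res1.accuracy)

    def test_constant_neuron_appended_no_effect(self):
        rng = np.random.default_rng(13)
        sets = rng.normal(0, 1, (4, 6, 3))
        pad = np.concatenate([sets, np.full((4, 6, 1), 7.0)], axis=2)
        assert knn_decode(pad, k=3).accuracy == \
            pytest.approx(knn_decode(sets, k=3).accuracy)

    def test_noise_degrades_accuracy(self, small_grid):
        """Accuracy is statistically non-increasing in added iid noise."""
        truth = random_population(small_grid, 10, tuned_fraction=1.0,
                                  seed=14)
        accs = []
        for noise_scale in (0.0, 3.0, 10.0):
            vals = []
            for rep in range(3):
                sess = generate_session(small_grid, truth, 10,
                                        seed=20 + rep, locomotion_rate=0.0,
                                        blink_rate=0.0)
                rng = np.random.default_rng(30 + rep)
                noisy = sess.responses + \
                    rng.gamma(1.0, noise_scale, sess.responses.shape)
                vals.append(knn_decode(_session(small_grid, noisy),
                                       k=4).accuracy)
            accs.append(np.mean(vals))
        assert accs[0] >= accs[1] >= accs[2] - 0.02

    def test_k_exceeding_pool_rejected(self):
        rng = np.random.default_rng(15)
        sets = rng.normal(0, 1, (3, 4, 2))
        with pytest.raises(ValueError, match="k="):
            knn_decode(sets, k=3)

    def test_sf_curve_shape(self, small_grid):
        truth = random_population(small_grid, 6, tuned_fraction=1.0, seed=16)
        sess = generate_session(small_grid, truth, 8, seed=17,
                                locomotion_rate=0.0, blink_rate=0.0)
        res = knn_decode(sess, k=4)
        assert res.sf_curve.shape == (small_grid.n_spatial_freqs,)
        assert res.accuracy == pytest.approx(res.sf_curve.mean(), abs=1e-9)


class TestSfSplit:
    def test_default_grid_splits_60_120(self, grid):
        truth = random_population(grid, 4, seed=18)
        sess = generate_session(grid, truth, 6, seed=19,
                                locomotion_rate=0.0, blink_rate=0.0)
        low, high = sf_split_decode(sess, k=4, seed=20)
        assert low.confusion.shape == (60, 60)
        assert high.confusion.shape == (120, 120)
        assert low.chance == pytest.approx(1 / 60)
        assert high.chance == pytest.approx(1 / 120)

    def test_degenerate_boundary_rejected(self, grid):
        truth = random_population(grid, 2, seed=21)
        sess = generate_session(grid, truth, 6, seed=22,
                                locomotion_rate=0.0, blink_rate=0.0)
        with pytest.raises(ValueError):
            sf_split_decode(sess, boundary=1.0)


class TestSubsampleMatch:
    def test_already_matched_unchanged(self, small_grid):
        truth = random_population(small_grid, 5, seed=23)
        s1 = generate_session(small_grid, truth, 8, seed=24,
                              locomotion_rate=0.0, blink_rate=0.0)
        s2 = generate_session(small_grid, truth, 8, seed=25,
                              locomotion_rate=0.0, blink_rate=0.0)
        out = subsample_match([s1, s2], seed=26)
        assert np.array_equal(out[0].responses, s1.responses)
        assert np.array_equal(out[1].responses, s2.responses)

    def test_trial_counts_matched_to_minimum(self, small_grid):
        truth = random_population(small_grid, 5, seed=27)
        trials = (40, 30, 35)
        sessions = [generate_session(small_grid, truth, t, seed=28 + i,
                                     locomotion_rate=0.0, blink_rate=0.0)
                    for i, t in enumerate(trials)]
        out = subsample_match(sessions, seed=31)
        assert all(s.responses.shape[2] == 30 for s in out)

    def test_no_shared_neurons_rejected(self, small_grid):
        truth = random_population(small_grid, 3, seed=32)
        s1 = generate_session(small_grid, truth, 5, seed=33,
                              locomotion_rate=0.0, blink_rate=0.0)
        s2 = s1.copy()
        s2.neuron_ids = s2.neuron_ids + 100
        with pytest.raises(ValueError, match="shared"):
            subsample_match([s1, s2], seed=34)


class TestFixedClassifierDrift:
    def test_self_test_equals_cv_accuracy_exactly(self, small_grid):
        truth = random_population(small_grid, 8, tuned_fraction=1.0, seed=35)
        sess = generate_session(small_grid, truth, 10, seed=36,
                                locomotion_rate=0.0, blink_rate=0.0)
        res = fixed_classifier_drift(sess, sess, k=4, seed=37)
        assert res.acc_x2 == res.acc_x1
        assert res.drift == 0.0

    def test_null_drift_near_zero(self, small_grid):
        """Statistically identical regenerations of one ground truth give
        drift ~ 0: the mean over seeds is within 3 SE of zero."""
        truth = random_population(small_grid, 12, tuned_fraction=1.0,
                                  seed=38)
        drifts = []
        for rep in range(8):
            s1 = generate_session(small_grid, truth, 12, seed=50 + 2 * rep,
                                  locomotion_rate=0.0, blink_rate=0.0)
            s2 = generate_session(small_grid, truth, 12, seed=51 + 2 * rep,
                                  locomotion_rate=0.0, blink_rate=0.0)
            drifts.append(fixed_classifier_drift(s1, s2, k=4,
                                                 seed=rep).drift)
        drifts = np.array(drifts)
        se = drifts.std(ddof=1) / np.sqrt(drifts.size)
        assert abs(drifts.mean()) < 3 * max(se, 1e-3)

    def test_reliability_drop_gives_negative_drift(self, small_grid):
        """Halving reliability in the test session makes drift clearly
        negative across seeds."""
        truth = random_population(small_grid, 12, tuned_fraction=1.0,
                                  seed=39)
        truth.reliability[:] = 0.9
        degraded = truth.copy()
        degraded.reliability[:] = 0.45
        drifts = []
        for rep in range(6):
            s1 = generate_session(small_grid, truth, 12, seed=70 + 2 * rep,
                                  locomotion_rate=0.0, blink_rate=0.0)
            s2 = generate_session(small_grid, degraded, 12,
                                  seed=71 + 2 * rep,
                                  locomotion_rate=0.0, blink_rate=0.0)
            drifts.append(fixed_classifier_drift(s1, s2, k=4,
                                                 seed=rep).drift)
        drifts = np.array(drifts)
        assert drifts.mean() < 0
        assert np.sum(drifts < 0) >= 5
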