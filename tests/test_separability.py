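"""IDNN separability and WD repeatability: closed forms, oracles, invariances."""

import itertools

import numpy as np
import pytest

from iemg.features import FeatureMatrix
from iemg.separability import (ClassStats, class_stats, combined_term,
                               half_mahalanobis, idnn, idnn_all,
                               leave_one_electrode_out, wd, wd_all)

from conftest import random_feature_matrix


def naive_idnn_all(X, movement):
    """Direct transcription: per-class mean/cov loops, plain inverses,
    pairwise half-Mahalanobis in both directions, nearest-neighbour min."""
    labels = list(dict.fromkeys(movement))
    mus, invs = {}, {}
    for lbl in labels:
        block = X[np.array([m == lbl for m in movement])]
        mus[lbl] = block.mean(axis=0)
        invs[lbl] = np.linalg.inv(np.atleast_2d(np.cov(block, rowvar=False)))
    out = {}
    for i in labels:
        terms = []
        for j in labels:
            if j == i:
                continue
            d = mus[i] - mus[j]
            a = 0.5 * d @ invs[i] @ d
            b = 0.5 * d @ invs[j] @ d
            terms.append(0.0 if a + b == 0 else a * b / (a + b))
        out[i] = min(terms)
    return out


def naive_wd(X, movement, repetition, label):
    reps = sorted({int(r) for m, r in zip(movement, repetition) if m == label})
    mus, invs = {}, {}
    for r in reps:
        block = X[np.array([(m == label and int(q) == r)
                            for m, q in zip(movement, repetition)])]
        mus[r] = block.mean(axis=0)
        invs[r] = np.linalg.inv(np.atleast_2d(np.cov(block, rowvar=False)))
    terms = []
    for k, r in itertools.combinations(reps, 2):
        d = mus[k] - mus[r]
        a = 0.5 * d @ invs[k] @ d
        b = 0.5 * d @ invs[r] @ d
        terms.append(0.0 if a + b == 0 else a * b / (a + b))
    return float(np.mean(terms))


def _stats(label, mu, S, n=10):
    return ClassStats(label=(label,), mu=np.asarray(mu, float),
                      S=np.asarray(S, float), n=n)


class TestClassStats:
    def test_mean_of_two_windows(self):
        fm = FeatureMatrix(X=[[0, 0], [2, 2]], columns=[("E1", "MAV"), ("E1", "WL")],
                           movement=np.array(["a", "a"], dtype=object),
                           repetition=[1, 1])
        (s,) = class_stats(fm)
        np.testing.assert_array_equal(s.mu, [1, 1])

    def test_identical_windows_get_regularized_inverse(self):
        # zero covariance escalates to a ridge; distances stay defined
        s = _stats("a", [0.0, 0.0], np.zeros((2, 2)))
        t = _stats("b", [1.0, 0.0], np.zeros((2, 2)))
        value = idnn([s, t], "a")
        assert np.isfinite(value) and value > 0

    def test_single_window_group_is_error(self):
        fm = FeatureMatrix(X=[[0.0], [1.0], [2.0]], columns=[("E1", "MAV")],
                           movement=np.array(["a", "a", "b"], dtype=object),
                           repetition=[1, 1, 1])
        with pytest.raises(ValueError, match="need >= 2"):
            class_stats(fm)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(11)
        fm = random_feature_matrix(rng, n_classes=3, n_features=4)
        for s in class_stats(fm, "repetition"):
            mask = np.array([(m == s.label[0] and r == s.label[1])
                             for m, r in zip(fm.movement, fm.repetition)])
            block = fm.X[mask]
            mu = sum(block) / len(block)
            S = sum(np.outer(row - mu, row - mu) for row in block) / (len(block) - 1)
            np.testing.assert_allclose(s.mu, mu, rtol=1e-12)
            np.testing.assert_allclose(s.S, S, rtol=1e-10, atol=1e-12)


class TestHalfMahalanobis:
    def test_identity_covariance(self):
        assert half_mahalanobis([2, 0], [0, 0], np.eye(2)) == pytest.approx(2.0)

    def test_coincident_means(self):
        assert half_mahalanobis([1, 1], [1, 1], np.eye(2)) == 0.0

    def test_scaled_covariance(self):
        assert half_mahalanobis([2, 0], [0, 0], 4 * np.eye(2)) == pytest.approx(0.5)

    def test_sqrt_form(self):
        assert half_mahalanobis([2, 0], [0, 0], np.eye(2),
                                sqrt_distance=True) == pytest.approx(1.0)


class TestCombinedTerm:
    def test_bounded_by_min(self):
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(1e-6, 100, (200, 2)):
            assert combined_term(a, b) <= min(a, b) + 1e-12

    def test_zero_when_both_zero(self):
        assert combined_term(0.0, 0.0) == 0.0


class TestIdnn:
    def test_two_class_identity_covariance(self):
        s = [_stats("a", [0, 0], np.eye(2)), _stats("b", [2, 0], np.eye(2))]
        assert idnn(s, "a") == pytest.approx(1.0)

    def test_coincident_classes(self):
        s = [_stats("a", [1, 1], np.eye(2)), _stats("b", [1, 1], np.eye(2))]
        assert idnn(s, "a") == 0.0

    def test_nearest_neighbour_dominates(self):
        s = [_stats("A", [0, 0], np.eye(2)), _stats("B", [2, 0], np.eye(2)),
             _stats("C", [10, 0], np.eye(2))]
        assert idnn(s, "A") == pytest.approx(1.0)

    def test_fewer_than_two_classes_is_error(self):
        with pytest.raises(ValueError):
            idnn([_stats("a", [0], [[1.0]])], "a")

    def test_monotone_in_mean_separation(self):
        # identity covariances: IDNN strictly increases with |delta mu|
        prev = -1.0
        for d in np.linspace(0.5, 5.0, 10):
            s = [_stats("a", [0, 0], np.eye(2)), _stats("b", [d, 0], np.eye(2))]
            value = idnn(s, "a")
            assert value > prev
            prev = value


class TestWd:
    def _rep(self, r, mu, S=None):
        return ClassStats(label=("m", r), mu=np.asarray(mu, float),
                          S=np.eye(len(mu)) if S is None else np.asarray(S, float),
                          n=10)

    def test_identical_repetition_means(self):
        reps = [self._rep(r, [1.0, 2.0]) for r in (1, 2, 3)]
        assert wd(reps) == 0.0

    def test_two_repetitions_identity_covariance(self):
        assert wd([self._rep(1, [0, 0]), self._rep(2, [2, 0])]) == pytest.approx(1.0)

    def test_mean_over_pairs_matches_hand_computation(self):
        # three coincident repetitions plus one shifted by (2, 0):
        # 3 zero pairs + 3 pairs with combined term 1 -> mean 0.5
        reps = [self._rep(r, [0, 0]) for r in (1, 2, 3)] + [self._rep(4, [2, 0])]
        assert wd(reps) == pytest.approx(0.5)

    def test_single_repetition_is_error(self):
        with pytest.raises(ValueError):
            wd([self._rep(1, [0, 0])])


class TestOracleEquivalence:
    def test_idnn_and_wd_match_naive_transcription(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n_classes = int(rng.integers(2, 6))
            n_features = int(rng.integers(2, 7))
            fm = random_feature_matrix(rng, n_classes, n_features, n_reps=3)
            got = idnn_all(class_stats(fm, "movement"))
            want = naive_idnn_all(fm.X, list(fm.movement))
            for lbl in want:
                assert got[lbl] == pytest.approx(want[lbl], rel=1e-8)
            got_wd = wd_all(fm)
            for lbl in got_wd:
                assert got_wd[lbl] == pytest.approx(
                    naive_wd(fm.X, list(fm.movement), list(fm.repetition), lbl),
                    rel=1e-8)


class TestAffineInvariance:
    def test_invariant_under_invertible_affine_maps(self):
        rng = np.random.default_rng(1)
        fm = random_feature_matrix(rng, n_classes=3, n_features=4, n_reps=3)
        base_idnn = idnn_all(class_stats(fm, "movement"))
        base_wd = wd_all(fm)
        for _ in range(5):
            A = rng.normal(0, 1, (4, 4)) + 4 * np.eye(4)
            b = rng.normal(0, 10, 4)
            fm2 = FeatureMatrix(X=fm.X @ A.T + b, columns=fm.columns,
                                movement=fm.movement, repetition=fm.repetition)
            for lbl, v in idnn_all(class_stats(fm2, "movement")).items():
                assert v == pytest.approx(base_idnn[lbl], rel=1e-8)
            for lbl, v in wd_all(fm2).items():
                assert v == pytest.approx(base_wd[lbl], rel=1e-8)


class TestLeaveOneOut:
    def _planted(self, rng, informative="E1", n=40):
        # informative electrode separates the classes; the other is pure noise
        X_info = np.vstack([rng.normal(0, 1, (n, 1)),
                            rng.normal(6, 1, (n, 1))])
        X_noise = rng.normal(0, 1, (2 * n, 1))
        movement = np.array(["a"] * n + ["b"] * n, dtype=object)
        rep = np.array([1] * (n // 2) + [2] * (n - n // 2), dtype=int)
        return FeatureMatrix(
            X=np.hstack([X_info, X_noise]),
            columns=[(informative, "MAV"), ("E2", "MAV")],
            movement=movement, repetition=np.concatenate([rep, rep]))

    def test_excluding_informative_electrode_hurts_more(self):
        rng = np.random.default_rng(9)
        fm = self._planted(rng)
        without_noise = leave_one_electrode_out(fm, "E2", "idnn").idnn
        without_info = leave_one_electrode_out(fm, "E1", "idnn").idnn
        assert min(without_noise.values()) > max(without_info.values())

    def test_exclusion_then_reinclusion_reproduces_full_value(self):
        rng = np.random.default_rng(10)
        fm = random_feature_matrix(rng, n_classes=3, n_features=3)
        full = idnn_all(class_stats(fm, "movement"))
        # dropping E1 changes the value; selecting the full set again restores it
        dropped = idnn_all(class_stats(fm.drop_electrode("E1"), "movement"))
        assert dropped != full
        again = idnn_all(class_stats(fm.select_channels(fm.electrodes), "movement"))
        assert again == full

    def test_identical_electrodes_are_symmetric(self):
        rng = np.random.default_rng(12)
        fm = random_feature_matrix(rng, n_classes=2, n_features=1)
        fm2 = FeatureMatrix(X=np.hstack([fm.X, fm.X, fm.X]),
                            columns=[("E1", "MAV"), ("E2", "MAV"), ("E3", "MAV")],
                            movement=fm.movement, repetition=fm.repetition)
        r1 = leave_one_electrode_out(fm2, "E1", "idnn").idnn
        r2 = leave_one_electrode_out(fm2, "E2", "idnn").idnn
        for lbl in r1:
            assert r1[lbl] == pytest.approx(r2[lbl], rel=1e-9)

    def test_single_electrode_cannot_be_left_out(self):
        rng = np.random.default_rng(13)
        fm = random_feature_matrix(rng, n_classes=2, n_features=1)
        with pytest.raises(ValueError):
            leave_one_electrode_out(fm, "E1")
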