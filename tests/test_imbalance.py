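"""Threshold moving (empirical and closed-form) and the comparison strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imbfall
from imbfall.imbalance import ImbalanceError, ThresholdPolicy, default_grid
from imbfall.preprocess import SplitCorpus, WindowedSample


def _split_with_counts(n_maj, n_min):
    def mk(label, i):
        return WindowedSample(np.zeros((4, 3)), label, f"t{label}{i}", 0)

    train = [mk(0, i) for i in range(n_maj)] + [mk(1, i) for i in range(n_min)]
    return SplitCorpus(train=train, validation=[], test=[])


class TestMinorityFrequency:
    @pytest.mark.parametrize("maj,mino,expected", [(90, 10, 0.1), (50, 50, 0.5)])
    def test_simple_counts(self, maj, mino, expected):
        assert imbfall.minority_frequency(_split_with_counts(maj, mino)) == expected

    def test_reported_corpus_counts(self):
        # 8439 falls among 94786 + 8439 windows
        assert 8439 / 103225 == pytest.approx(0.0818, abs=5e-5)
        assert imbfall.minority_frequency(_split_with_counts(94786 // 50, 8439 // 50)) == (
            pytest.approx(0.0818, abs=2e-3)
        )


def brute_force_threshold(posteriors, f, grid):
    """Exhaustive oracle for the distribution-matching threshold."""
    best_lam, best_err = None, np.inf
    for lam in sorted(grid):
        f_lam = np.mean(np.asarray(posteriors) >= lam)
        err = abs(f - f_lam)
        if err < best_err:
            best_lam, best_err = lam, err
    return best_lam


class TestEmpiricalThreshold:
    def test_worked_example_ties_to_smallest(self):
        p = [0.9, 0.8, 0.3, 0.2, 0.1]
        grid = np.round(np.linspace(0.1, 0.9, 9), 10)  # exact decimal lattice
        policy = imbfall.empirical_threshold(p, f=0.4, grid=grid)
        assert policy.lam == pytest.approx(0.4)
        assert policy.provenance == "empirical"

    def test_full_minority_frequency_gives_smallest_grid_value(self):
        grid = np.round(np.linspace(0.1, 0.9, 9), 10)
        policy = imbfall.empirical_threshold([0.5, 0.6], f=1.0, grid=grid)
        assert policy.lam == pytest.approx(0.1)

    def test_exact_match_attainable(self):
        """When some grid value reproduces f exactly, the error is zero."""
        p = np.array([0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95])
        policy = imbfall.empirical_threshold(p, f=0.3)
        f_lam = np.mean(p >= policy.lam)
        assert f_lam == pytest.approx(0.3)

    def test_argmin_property_exhaustive(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        f = 0.27
        policy = imbfall.empirical_threshold(p, f)
        grid = default_grid(p)
        achieved = abs(f - np.mean(p >= policy.lam))
        for lam in grid:
            assert achieved <= abs(f - np.mean(p >= lam)) + 1e-12

    def test_agrees_with_bruteforce_on_random_batches(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.beta(0.5, 2.0, size=rng.integers(5, 200))
            f = float(rng.uniform(0, 1))
            policy = imbfall.empirical_threshold(p, f)
            assert policy.lam == pytest.approx(brute_force_threshold(p, f, default_grid(p)))

    def test_empty_batch_rejected(self):
        with pytest.raises(ImbalanceError, match="empty"):
            imbfall.empirical_threshold([], f=0.5)


class TestClosedFormThreshold:
    def test_reference_ratio_rounds_to_one_tenth(self):
        policy = imbfall.closed_form_threshold(11.23, 0.5)
        assert policy.lam == pytest.approx(0.1029, abs=5e-4)
        assert round(policy.lam, 1) == 0.1

    def test_balanced_ratio(self):
        assert imbfall.closed_form_threshold(1.0, 0.5).lam == pytest.approx(0.459, abs=5e-4)

    def test_limit_is_tenth_of_default(self):
        assert imbfall.closed_form_threshold(1e9, 0.5).lam == pytest.approx(0.05, abs=1e-9)

    def test_strictly_decreasing_in_rho_increasing_in_k(self):
        rhos = np.linspace(0.0, 50.0, 100)
        ks = np.linspace(0.05, 0.9, 100)
        lam_rho = [imbfall.closed_form_threshold(r, 0.5).lam for r in rhos]
        assert np.all(np.diff(lam_rho) < 0)
        lam_k = [imbfall.closed_form_threshold(5.0, k).lam for k in ks]
        assert np.all(np.diff(lam_k) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ImbalanceError):
            imbfall.closed_form_threshold(-1.0)
        with pytest.raises(ImbalanceError):
            imbfall.closed_form_threshold(5.0, k=1.5)


class TestApplyThreshold:
    def test_boundary_inclusive(self):
        policy = ThresholdPolicy(lam=0.1)
        np.testing.assert_array_equal(
            imbfall.apply_threshold(np.array([0.05, 0.15, 0.95]), policy), [0, 1, 1]
        )
        np.testing.assert_array_equal(
            imbfall.apply_threshold(np.array([0.1]), policy), [1]
        )

    def test_default_threshold_is_argmax_for_binary_softmax(self):
        rng = np.random.default_rng(0)
        p1 = rng.uniform(size=100)
        batch = np.column_stack([1 - p1, p1])
        policy = ThresholdPolicy(lam=0.5)
        np.testing.assert_array_equal(
            imbfall.apply_threshold(batch, policy), batch.argmax(axis=1)
        )

    def test_policy_text_roundtrip(self):
        policy = imbfall.closed_form_threshold(11.23, 0.5)
        back = ThresholdPolicy.from_text(policy.to_text())
        assert back == policy


class TestClassWeights:
    def test_inverse_frequency(self):
        w = imbfall.class_weights(_split_with_counts(90, 10))
        np.testing.assert_allclose(w, [100 / 180, 100 / 20])
        np.testing.assert_allclose(w, [0.556, 5.0], atol=5e-4)
        # frequency-weighted mean is 1
        assert 0.9 * w[0] + 0.1 * w[1] == pytest.approx(1.0)

    def test_balanced_weights_are_unity(self):
        np.testing.assert_allclose(imbfall.class_weights(_split_with_counts(50, 50)), [1.0, 1.0])

    def test_missing_class_rejected(self):
        with pytest.raises(ImbalanceError, match="both classes"):
            imbfall.class_weights(_split_with_counts(10, 0))


class TestFocalLoss:
    def test_direct_evaluation(self):
        # p_t = 0.9, gamma = 2, alpha = 1: 0.01 * (-ln 0.9)
        val = imbfall.focal_loss(0.9, 1, gamma=2.0, alpha=1.0)
        assert val == pytest.approx(0.01 * -np.log(0.9), rel=1e-9)

    @given(st.floats(0.01, 0.99), st.integers(0, 1), st.floats(0.05, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_gamma_zero_is_weighted_cross_entropy(self, p, y, alpha):
        pt = p if y == 1 else 1 - p
        at = alpha if y == 1 else 1 - alpha
        assert imbfall.focal_loss(p, y, gamma=0.0, alpha=alpha) == pytest.approx(
            -at * np.log(pt), rel=1e-9
        )

    def test_vanishes_for_confident_correct_prediction(self):
        assert imbfall.focal_loss(1 - 1e-9, 1, gamma=2.0) < 1e-15

    def test_invalid_posterior_rejected(self):
        with pytest.raises(ImbalanceError):
            imbfall.focal_loss(1.0, 1)


def _minority_windows(n, shape=(10, 3), seed=0):
    rng = np.random.default_rng(seed)
    return [
        WindowedSample(rng.normal(size=shape), 1, f"fall_{i:03d}", 0) for i in range(n)
    ]


class TestSmote:
    def test_identical_parents_give_identical_copy(self):
        base = np.ones((10, 3)) * 2.5
        windows = [WindowedSample(base.copy(), 1, f"t{i}", 0) for i in range(6)]
        synth = imbfall.smote_windows(windows, n_new=4, k_neighbors=3, seed=0)
        assert len(synth) == 4
        for s in synth:
            np.testing.assert_allclose(s.window, base)
            assert s.label == 1

    def test_synthetic_windows_lie_between_parents(self):
        windows = _minority_windows(20)
        synth = imbfall.smote_windows(windows, n_new=30, k_neighbors=5, seed=1)
        parents = np.stack([w.window.ravel() for w in windows])
        for s in synth:
            v = s.window.ravel()
            # componentwise betweenness for some parent pair
            ok = False
            for i in range(len(windows)):
                for j in range(len(windows)):
                    if i == j:
                        continue
                    lo = np.minimum(parents[i], parents[j])
                    hi = np.maximum(parents[i], parents[j])
                    if np.all(v >= lo - 1e-9) and np.all(v <= hi + 1e-9):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_zero_requested_returns_empty(self):
        assert imbfall.smote_windows(_minority_windows(10), 0) == []

    def test_deterministic_given_seed(self):
        windows = _minority_windows(12)
        a = imbfall.smote_windows(windows, 5, 3, seed=9)
        b = imbfall.smote_windows(windows, 5, 3, seed=9)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.window, wb.window)

    def test_too_few_minority_rejected(self):
        with pytest.raises(ImbalanceError, match="minority"):
            imbfall.smote_windows(_minority_windows(4), 2, k_neighbors=5)
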