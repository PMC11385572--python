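import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import alphasel as a
from conftest import make_tfrset


def reference_linear_svm(train_x, train_y, test_x, c=1.0):
    """Independent linear soft-margin SVM: dual QP solved with SLSQP.

    Maximize sum(alpha) - 1/2 alpha' Q alpha  s.t.  0 <= alpha <= C, y'alpha = 0,
    then predict sign(w.x + b).  Used only as a cross-check oracle.
    """
    classes = np.unique(train_y)
    y = np.where(train_y == classes[1], 1.0, -1.0)
    mu, sd = train_x.mean(axis=0), train_x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (train_x - mu) / sd
    q = (y[:, None] * xs) @ (y[:, None] * xs).T
    n = len(y)

    def neg_dual(alpha):
        return 0.5 * alpha @ q @ alpha - alpha.sum()

    def grad(alpha):
        return q @ alpha - np.ones(n)

    res = minimize(
        neg_dual,
        np.full(n, 0.1),
        jac=grad,
        bounds=[(0.0, c)] * n,
        constraints=[{"type": "eq", "fun": lambda al: al @ y, "jac": lambda al: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    alpha = res.x
    w = ((alpha * y)[:, None] * xs).sum(axis=0)
    sv = (alpha > 1e-6) & (alpha < c - 1e-6)
    if sv.any():
        b = np.mean(y[sv] - xs[sv] @ w)
    else:
        on = alpha > 1e-6
        b = np.mean(y[on] - xs[on] @ w)
    scores = ((test_x - mu) / sd) @ w + b
    return np.where(scores >= 0, classes[1], classes[0]), scores


class TestFeatureSelection:
    def test_64_channels_and_6_alpha_frequencies_give_384_features(self, family250):
        times = np.arange(0.0, 40.0, 4.0)
        power = np.random.default_rng(0).random((3, 64, 26, times.size))
        tfr = make_tfrset(power, times, family250.frequencies)
        feats = a.select_alpha_features(tfr)
        assert feats.shape == (3, 384, times.size)

    def test_two_channels_one_inband_frequency_give_two_features(self):
        times = np.arange(0.0, 20.0, 4.0)
        power = np.random.default_rng(0).random((2, 2, 3, times.size))
        tfr = make_tfrset(power, times, [5.0, 10.0, 20.0])
        feats = a.select_alpha_features(tfr, band=(8.0, 13.0))
        assert feats.shape == (2, 2, times.size)
        assert np.allclose(feats, power[:, :, 1, :])

    def test_empty_band_rejected(self):
        times = np.arange(0.0, 20.0, 4.0)
        tfr = make_tfrset(np.ones((1, 2, 1, times.size)), times, [20.0])
        with pytest.raises(ValueError, match="band"):
            a.select_alpha_features(tfr, band=(8.0, 13.0))

    def test_db_input_rejected(self):
        times = np.arange(-20.0, 20.0, 4.0)
        tfr = make_tfrset(np.ones((1, 2, 1, times.size)), times, [10.0])
        db = a.db_baseline(tfr, window=(-20.0, -4.0))
        with pytest.raises(ValueError, match="raw"):
            a.select_alpha_features(db)


class TestBlockAssignment:
    @pytest.mark.parametrize(
        "n_per_class, expected_per_block, removed_per_class",
        [(9, 3, 0), (10, 3, 1), (12, 4, 0)],
    )
    def test_balanced_blocks_with_surplus_removal(
        self, n_per_class, expected_per_block, removed_per_class
    ):
        labels = np.array(["L"] * n_per_class + ["R"] * n_per_class)
        blocks = a.assign_blocks(labels, 3, np.random.default_rng(1))
        for cls in ("L", "R"):
            cls_blocks = blocks[labels == cls]
            assert np.sum(cls_blocks == -1) == removed_per_class
            for b in range(3):
                assert np.sum(cls_blocks == b) == expected_per_block

    def test_too_few_trials_rejected(self):
        labels = np.array(["L", "L", "R", "R"])
        with pytest.raises(ValueError, match="at least 3"):
            a.assign_blocks(labels, 3, np.random.default_rng(0))

    def test_requires_exactly_two_classes(self):
        with pytest.raises(ValueError, match="2 classes"):
            a.assign_blocks(np.array(["a", "b", "c"] * 3), 3, np.random.default_rng(0))


class TestBlockAverage:
    def test_three_blocks_two_classes_give_six_averages(self):
        rng = np.random.default_rng(2)
        feats = rng.random((12, 5, 4))
        labels = np.array(["L", "R"] * 6)
        blocks = a.assign_blocks(labels, 3, rng)
        averages, avg_blocks, avg_labels = a.block_average(feats, blocks, labels)
        assert averages.shape == (6, 5, 4)
        # each training fold (two blocks) holds 4 averages
        assert np.sum(avg_blocks != 0) == 4

    def test_average_of_identical_trials_is_the_trial(self):
        feats = np.ones((6, 3, 2))
        labels = np.array(["L", "R"] * 3)
        blocks = np.array([0, 0, 1, 1, 2, 2])
        averages, _, _ = a.block_average(feats, blocks, labels)
        assert np.allclose(averages, 1.0)

    def test_invariant_to_trial_order(self):
        rng = np.random.default_rng(3)
        feats = rng.random((12, 4, 3))
        labels = np.array(["L"] * 6 + ["R"] * 6)
        blocks = np.array([0, 1, 2] * 4)
        ref, _, ref_labels = a.block_average(feats, blocks, labels)
        perm = rng.permutation(12)
        out, _, out_labels = a.block_average(feats[perm], blocks[perm], labels[perm])
        assert np.allclose(ref, out)
        assert np.array_equal(ref_labels, out_labels)


class TestDecodeTimepoint:
    def test_separable_classes_are_perfectly_classified(self):
        rng = np.random.default_rng(4)
        train = np.vstack([rng.normal(-5, 0.01, (2, 10)), rng.normal(5, 0.01, (2, 10))])
        labels = np.array(["L", "L", "R", "R"])
        test = np.vstack([rng.normal(-5, 0.01, (3, 10)), rng.normal(5, 0.01, (3, 10))])
        pred = a.decode_timepoint(train, labels, test)
        assert np.array_equal(pred, np.array(["L"] * 3 + ["R"] * 3))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            a.decode_timepoint(np.ones((3, 4)), np.array(["L"] * 3), np.ones((1, 4)))

    def test_agreement_with_independent_qp_svm_on_random_problems(self):
        rng = np.random.default_rng(7)
        agree, total = 0, 0
        for _ in range(20):
            n_feat = rng.integers(3, 8)
            sep = rng.uniform(1.0, 2.5)
            mean = rng.normal(0, 1, n_feat)
            delta = rng.normal(0, 1, n_feat)
            delta *= sep / np.linalg.norm(delta)
            train_x = np.vstack(
                [mean - delta + rng.normal(0, 0.5, (4, n_feat)),
                 mean + delta + rng.normal(0, 0.5, (4, n_feat))]
            )
            train_y = np.array(["A"] * 4 + ["B"] * 4)
            test_x = np.vstack(
                [mean - delta + rng.normal(0, 0.5, (5, n_feat)),
                 mean + delta + rng.normal(0, 0.5, (5, n_feat))]
            )
            ours = a.decode_timepoint(train_x, train_y, test_x)
            ref, scores = reference_linear_svm(train_x, train_y, test_x)
            confident = np.abs(scores) > 0.05  # ignore knife-edge points
            agree += np.sum((ours == ref)[confident])
            total += confident.sum()
        assert agree / total >= 0.98


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.full(20, 0.7)
        assert np.allclose(a.smooth_moving_average(x, 5), 0.7)

    def test_interior_impulse_spreads_to_one_fifth(self):
        x = np.zeros(15)
        x[7] = 1.0
        out = a.smooth_moving_average(x, 5)
        assert np.allclose(out[5:10], 0.2)
        assert np.allclose(out[[4, 10]], 0.0)

    def test_even_or_negative_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            a.smooth_moving_average(np.ones(5), 4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=60),
        st.sampled_from([1, 3, 5, 7]),
    )
    def test_matches_bruteforce_windowed_mean(self, values, w):
        x = np.asarray(values)
        out = a.smooth_moving_average(x, w)
        half = w // 2
        expected = np.array(
            [x[max(0, i - half) : min(x.size, i + half + 1)].mean() for i in range(x.size)]
        )
        assert np.allclose(out, expected)


class TestDecodeTimecourse:
    @staticmethod
    def _toy_tfr(rng, n_trials_per_class=12, n_ch=4, n_times=30, signal=0.0):
        """Raw-power TFRSet with one in-band frequency and optional class signal."""
        freqs = np.array([10.0])
        times = np.arange(n_times) * 4.0
        info = pd.DataFrame(
            {
                "participant_id": 0,
                "condition": "selective",
                "cue_axis": "horizontal",
                "lateral_location": ["left", "right"] * n_trials_per_class,
                "vertical_location": ["top", "bottom"] * n_trials_per_class,
            }
        )
        power = rng.random((2 * n_trials_per_class, n_ch, 1, n_times)) + 1.0
        is_right = (info["lateral_location"] == "right").to_numpy()
        power[is_right, : n_ch // 2] += signal
        return make_tfrset(power, times, freqs, trial_info=info)

    def test_strong_signal_decodes_near_perfectly(self):
        rng = np.random.default_rng(11)
        cfg = a.DecodingConfig(
            time_window=(0.0, 116.0),
            subsample=1,
            contrasts=[("lateral_location", ("left", "right"))],
            seed=0,
        )
        tfr = self._toy_tfr(rng, signal=5.0)
        res = a.decode_timecourse(tfr, tfr.trial_info, cfg)
        assert res.accuracy.mean() > 0.95

    def test_label_permutation_gives_chance_accuracy(self):
        rng = np.random.default_rng(12)
        cfg = a.DecodingConfig(
            time_window=(0.0, 116.0),
            subsample=1,
            contrasts=[("lateral_location", ("left", "right"))],
            seed=0,
        )
        tfr = self._toy_tfr(rng, n_trials_per_class=15, signal=0.0)
        res = a.decode_timecourse(tfr, tfr.trial_info, cfg)
        assert abs(res.accuracy.mean() - 0.5) < 0.06

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        tfr = self._toy_tfr(rng, signal=0.5)
        cfg = a.DecodingConfig(
            time_window=(0.0, 60.0),
            subsample=2,
            contrasts=[("lateral_location", ("left", "right"))],
            seed=5,
        )
        r1 = a.decode_timecourse(tfr, tfr.trial_info, cfg)
        r2 = a.decode_timecourse(tfr, tfr.trial_info, cfg)
        assert np.array_equal(r1.accuracy, r2.accuracy)

    def test_channel_permutation_leaves_accuracy_unchanged(self):
        rng = np.random.default_rng(14)
        tfr = self._toy_tfr(rng, signal=0.8)
        cfg = a.DecodingConfig(
            time_window=(0.0, 60.0),
            subsample=2,
            contrasts=[("lateral_location", ("left", "right"))],
            seed=2,
        )
        ref = a.decode_timecourse(tfr, tfr.trial_info, cfg)
        perm = np.random.default_rng(1).permutation(tfr.power.shape[1])
        tfr_perm = make_tfrset(
            tfr.power[:, perm], tfr.times, tfr.frequencies, trial_info=tfr.trial_info
        )
        out = a.decode_timecourse(tfr_perm, tfr_perm.trial_info, cfg)
        assert np.allclose(ref.accuracy, out.accuracy)

    def test_missing_contrast_labels_rejected(self):
        rng = np.random.default_rng(15)
        tfr = self._toy_tfr(rng)
        info = tfr.trial_info.drop(columns=["vertical_location"])
        cfg = a.DecodingConfig(time_window=(0.0, 60.0), subsample=2)
        with pytest.raises(ValueError, match="vertical_location"):
            a.decode_timecourse(tfr, info, cfg)
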