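import hashlib
import pickle

import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from emgadapt.adaptation import (
    AdaptationConfig,
    incremental_adapt,
    n_incremental_batches,
    predict,
    source_beta,
    ti_svm_adapt,
    tradaboost_adapt,
    tradaboost_round,
    tradaboost_run,
    train_base_svm,
)

from conftest import clustered_data


def separable_two_class(rng, n=60, margin=8.0):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 3))
    X[:, 0] += np.where(y == 0, -margin, margin)
    return X, y


def shifted_copy(rng, X, y, shift):
    """Same labels, class means translated by a random direction * shift."""
    X2 = X + rng.normal(size=X.shape) * 0.0
    for cls in np.unique(y):
        direction = rng.normal(size=X.shape[1])
        direction /= np.linalg.norm(direction)
        X2[y == cls] += shift * direction
    return X2, y.copy()


class TestBaseSvm:
    def test_separable_training_accuracy_is_one(self, rng):
        X, y = separable_two_class(rng)
        model = train_base_svm(X, y)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            train_base_svm(rng.normal(size=(10, 2)), np.zeros(10))

    def test_prediction_invariant_to_feature_scaling(self, rng):
        """Standardisation absorbs per-dimension rescaling of inputs."""
        X, y = clustered_data(rng, n_classes=3, n_per_class=30, n_dims=4)
        scale = np.array([1.0, 10.0, 0.1, 100.0])
        m1 = train_base_svm(X, y)
        m2 = train_base_svm(X * scale, y)
        Xt, _ = clustered_data(rng, n_classes=3, n_per_class=5, n_dims=4)
        np.testing.assert_array_equal(
            predict(m1, Xt), predict(m2, Xt * scale)
        )

    def test_eleven_class_problem_beats_chance(self, rng):
        X, y = clustered_data(rng, n_classes=11, n_per_class=30, n_dims=8,
                              separation=2.0)
        idx = rng.permutation(len(y))
        train, test = idx[:220], idx[220:]
        model = train_base_svm(X[train], y[train])
        acc = np.mean(predict(model, X[test]) == y[test])
        assert acc > 3.0 / 11


class TestIncremental:
    def test_standard_calibration_set_makes_22_batches(self):
        assert n_incremental_batches(1056, 48) == 22

    def test_adaptation_history_counts_batches(self, rng):
        X, y = clustered_data(rng, n_classes=3, n_per_class=40, n_dims=4)
        model = train_base_svm(X, y)
        Xc, yc = clustered_data(rng, n_classes=3, n_per_class=32, n_dims=4)
        cfg = AdaptationConfig(batch_size=48)
        adapted = incremental_adapt(model, Xc, yc, cfg)
        assert adapted.history[-1] == "incremental:2"  # ceil(96/48)

    def test_same_distribution_separable_stays_perfect(self, rng):
        X, y = separable_two_class(rng, n=80)
        Xc, yc = separable_two_class(rng, n=40)
        Xt, yt = separable_two_class(rng, n=40)
        model = incremental_adapt(train_base_svm(X, y), Xc, yc,
                                  AdaptationConfig(batch_size=16))
        assert np.mean(predict(model, Xt) == yt) == 1.0

    def test_unknown_label_in_batch_rejected(self, rng):
        X, y = separable_two_class(rng)
        model = train_base_svm(X, y)
        with pytest.raises(ValueError, match="label"):
            incremental_adapt(model, X[:4], np.array([0, 1, 2, 2]))

    def test_adapted_beats_unadapted_under_shift(self, rng):
        """Mean over seeded runs: calibration adaptation recovers accuracy."""
        gains = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X, y = clustered_data(r, n_classes=5, n_per_class=40, n_dims=6,
                                  separation=3.0)
            X2, y2 = shifted_copy(r, X, y, shift=2.0)
            cal = r.permutation(len(y2))[:60]
            test = np.setdiff1d(np.arange(len(y2)), cal)
            base = train_base_svm(X, y)
            adapted = incremental_adapt(base, X2[cal], y2[cal],
                                        AdaptationConfig(batch_size=20))
            acc_base = np.mean(predict(base, X2[test]) == y2[test])
            acc_adapt = np.mean(predict(adapted, X2[test]) == y2[test])
            gains.append(acc_adapt - acc_base)
        assert np.mean(gains) > 0

    def test_close_to_scratch_retrain_on_small_instances(self, rng):
        """Sanity bound: the incremental path lands within 2% of a scratch
        SVM trained on {Day-1 support samples + all calibration}."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            X, y = clustered_data(r, n_classes=4, n_per_class=40, n_dims=5,
                                  separation=2.5)
            Xc, yc = clustered_data(r, n_classes=4, n_per_class=12, n_dims=5,
                                    separation=2.5)
            Xt, yt = clustered_data(r, n_classes=4, n_per_class=25, n_dims=5,
                                    separation=2.5)
            base = train_base_svm(X, y)
            inc = incremental_adapt(base, Xc, yc, AdaptationConfig(batch_size=16))
            Xs = np.vstack([base.support_X, Xc])
            ys = np.concatenate([base.support_y, yc])
            scratch = SVC(kernel="linear", C=1.0).fit(
                base.scaler.transform(Xs), ys
            )
            acc_inc = np.mean(predict(inc, Xt) == yt)
            acc_scr = np.mean(scratch.predict(base.scaler.transform(Xt)) == yt)
            assert abs(acc_inc - acc_scr) <= 0.02


class TestTradaboostMechanics:
    @pytest.fixture()
    def standardized_sets(self, rng):
        X, y = clustered_data(rng, n_classes=3, n_per_class=40, n_dims=4,
                              separation=3.0)
        Xc, yc = clustered_data(rng, n_classes=3, n_per_class=10, n_dims=4,
                                separation=3.0)
        scaler = StandardScaler().fit(X)
        return scaler.transform(X), y, scaler.transform(Xc), yc

    def test_beta_closed_form(self):
        n_src, rounds = 4224, 26
        expected = 1.0 / (1.0 + np.sqrt(2.0 * np.log(4224) / 26))
        assert source_beta(n_src, rounds) == pytest.approx(expected, rel=1e-12)

    def test_zero_misclassification_leaves_weights_uniform(self,
                                                           standardized_sets):
        Xs, ys, Xc, yc = standardized_sets
        n = len(ys) + len(yc)
        w_src = np.full(len(ys), 1.0 / n)
        w_cal = np.full(len(yc), 1.0 / n)
        new_src, new_cal, rec = tradaboost_round(
            Xs, ys, Xc, yc, w_src, w_cal, beta=source_beta(len(ys), 26)
        )
        if rec.eps <= 1e-9:  # separable blobs: no errors anywhere
            np.testing.assert_allclose(new_src, w_src)
            np.testing.assert_allclose(new_cal, w_cal)

    def test_misclassified_weights_move_in_opposite_directions(self, rng):
        # overlapping classes guarantee errors on both sides
        Xs, ys = clustered_data(rng, n_classes=2, n_per_class=50, n_dims=3,
                                separation=0.7)
        Xc, yc = clustered_data(rng, n_classes=2, n_per_class=20, n_dims=3,
                                separation=0.7)
        n = len(ys) + len(yc)
        w_src = np.full(len(ys), 1.0 / n)
        w_cal = np.full(len(yc), 1.0 / n)
        new_src, new_cal, rec = tradaboost_round(
            Xs, ys, Xc, yc, w_src, w_cal, beta=source_beta(len(ys), 26)
        )
        miss_src = rec.svc.predict(Xs) != ys
        miss_cal = rec.svc.predict(Xc) != yc
        assert miss_src.any() and miss_cal.any()
        ratio_src = new_src / w_src
        ratio_cal = new_cal / w_cal
        # relative to correctly classified peers, wrong source samples sank
        # and wrong calibration samples rose
        assert np.all(ratio_src[miss_src] < ratio_src[~miss_src].min())
        assert np.all(ratio_cal[miss_cal] > ratio_cal[~miss_cal].max())

    def test_weights_renormalize_to_one(self, rng):
        Xs, ys = clustered_data(rng, n_classes=2, n_per_class=40, n_dims=3,
                                separation=0.8)
        Xc, yc = clustered_data(rng, n_classes=2, n_per_class=16, n_dims=3,
                                separation=0.8)
        cfg = AdaptationConfig(rounds=6)
        n = len(ys) + len(yc)
        w_src = np.full(len(ys), 1.0 / n)
        w_cal = np.full(len(yc), 1.0 / n)
        beta = source_beta(len(ys), cfg.rounds)
        for _ in range(cfg.rounds):
            w_src, w_cal, _ = tradaboost_round(
                Xs, ys, Xc, yc, w_src, w_cal, beta, cfg
            )
            assert w_src.sum() + w_cal.sum() == pytest.approx(1.0, abs=1e-12)


class TestTradaboostAdapt:
    def test_selected_round_comes_from_last_half(self, rng):
        Xs, ys = clustered_data(rng, n_classes=3, n_per_class=30, n_dims=4,
                                separation=1.5)
        Xc, yc = clustered_data(rng, n_classes=3, n_per_class=10, n_dims=4,
                                separation=1.5)
        scaler = StandardScaler().fit(Xs)
        cfg = AdaptationConfig(rounds=26)
        records, best = tradaboost_run(
            scaler.transform(Xs), ys, scaler.transform(Xc), yc, cfg
        )
        assert len(records) == 26
        assert best >= 13  # rounds 14..26, 0-based

    def test_same_distribution_separable_stays_perfect(self, rng):
        Xs, ys = separable_two_class(rng, n=80)
        Xc, yc = separable_two_class(rng, n=30)
        Xt, yt = separable_two_class(rng, n=50)
        model = tradaboost_adapt(Xs, ys, Xc, yc, AdaptationConfig(rounds=8))
        assert np.mean(predict(model, Xt) == yt) == 1.0

    def test_discarded_source_concentrates_in_shifted_class(self, rng):
        """Moving one source class away from its target-day position makes
        its samples the ones the boosting discards."""
        Xs, ys = clustered_data(rng, n_classes=3, n_per_class=40, n_dims=4,
                                separation=4.0)
        Xc, yc = Xs.copy(), ys.copy()
        moved = 1
        # source class 1 drifts onto class 2's territory: those samples now
        # conflict with both the target-day class 1 and the class-2 cluster
        Xs[ys == moved] = Xs[ys == 2] + rng.normal(
            scale=0.3, size=(np.sum(ys == moved), Xs.shape[1])
        )
        keep_cal_idx = rng.permutation(len(yc))[:30]
        scaler = StandardScaler().fit(Xs)
        cfg = AdaptationConfig(rounds=10)
        records, best = tradaboost_run(
            scaler.transform(Xs), ys,
            scaler.transform(Xc[keep_cal_idx]), yc[keep_cal_idx], cfg,
        )
        discarded = ~records[best].source_kept
        frac_moved = discarded[ys == moved].mean()
        frac_other = discarded[ys != moved].mean()
        assert frac_moved > frac_other

    def test_eps_clipping_keeps_update_finite(self, rng):
        # perfectly separable: raw eps would be 0
        Xs, ys = separable_two_class(rng, n=40)
        Xc, yc = separable_two_class(rng, n=20)
        scaler = StandardScaler().fit(Xs)
        records, _ = tradaboost_run(
            scaler.transform(Xs), ys, scaler.transform(Xc), yc,
            AdaptationConfig(rounds=4),
        )
        assert all(np.isfinite(r.eps) and r.eps >= 1e-10 for r in records)


class TestTiSvm:
    def test_no_shift_separable_is_perfect(self, rng):
        Xs, ys = separable_two_class(rng, n=80)
        Xc, yc = separable_two_class(rng, n=30)
        Xt, yt = separable_two_class(rng, n=50)
        model = ti_svm_adapt(Xs, ys, Xc, yc,
                             AdaptationConfig(rounds=6, batch_size=16))
        assert np.mean(predict(model, Xt) == yt) == 1.0

    def test_deterministic_given_inputs(self, rng):
        Xs, ys = clustered_data(rng, n_classes=3, n_per_class=30, n_dims=4)
        Xc, yc = clustered_data(rng, n_classes=3, n_per_class=10, n_dims=4)
        Xt, _ = clustered_data(rng, n_classes=3, n_per_class=10, n_dims=4)
        cfg = AdaptationConfig(rounds=6, batch_size=8)
        p1 = predict(ti_svm_adapt(Xs, ys, Xc, yc, cfg), Xt)
        p2 = predict(ti_svm_adapt(Xs, ys, Xc, yc, cfg), Xt)
        np.testing.assert_array_equal(p1, p2)

    def test_history_records_both_stages(self, rng):
        Xs, ys = clustered_data(rng, n_classes=3, n_per_class=30, n_dims=4)
        Xc, yc = clustered_data(rng, n_classes=3, n_per_class=10, n_dims=4)
        model = ti_svm_adapt(Xs, ys, Xc, yc,
                             AdaptationConfig(rounds=6, batch_size=10))
        assert any(h.startswith("tradaboost") for h in model.history)
        assert model.history[-1] == "incremental:3"  # ceil(30/10)


class TestPredict:
    def test_training_set_of_separable_fit_is_perfect(self, rng):
        X, y = separable_two_class(rng)
        model = train_base_svm(X, y)
        np.testing.assert_array_equal(predict(model, X), y)

    def test_output_length_and_permutation_equivariance(self, rng):
        X, y = clustered_data(rng, n_classes=3, n_per_class=20, n_dims=4)
        model = train_base_svm(X, y)
        Xt, _ = clustered_data(rng, n_classes=3, n_per_class=10, n_dims=4)
        perm = rng.permutation(len(Xt))
        labels = predict(model, Xt)
        assert len(labels) == len(Xt)
        np.testing.assert_array_equal(predict(model, Xt[perm]), labels[perm])

    def test_dimension_mismatch_names_expected_dims(self, rng):
        X, y = separable_two_class(rng)
        model = train_base_svm(X, y)
        with pytest.raises(ValueError, match="expected feature dimension 3"):
            predict(model, np.zeros((4, 5)))

    def test_response_time_reported(self, rng):
        X, y = separable_two_class(rng)
        model = train_base_svm(X, y)
        labels, elapsed = predict(model, X, return_time=True)
        assert elapsed >= 0.0 and len(labels) == len(X)
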