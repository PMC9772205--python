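"""Classifier components: feature layout, PCA+SVM submodels, consensus heads."""

import itertools

import numpy as np
import pytest

import casvision as cv
from casvision.models import FEATURE_LENGTH, PcaLinearSvm
from casvision.signs import IMAGE_SIGNS, SignKind
from tests.conftest import TINY_C_GRID, TINY_NC_GRID


class TestExtractFeatures:
    def test_zero_crop(self):
        assert not cv.extract_features(np.zeros((64, 64, 3))).any()

    def test_single_pixel_index_arithmetic(self):
        crop = np.zeros((64, 64, 3))
        row, col, ch = 10, 33, 2
        crop[row, col, ch] = 1.0
        vec = cv.extract_features(crop)
        nz = np.flatnonzero(vec)
        assert list(nz) == [row * 64 * 3 + col * 3 + ch]

    def test_layout_round_trip(self):
        rng = np.random.default_rng(0)
        crop = rng.random((64, 64, 3))
        assert np.array_equal(cv.extract_features(crop).reshape(64, 64, 3), crop)

    def test_wrong_shape(self):
        with pytest.raises(ValueError, match="shape"):
            cv.extract_features(np.zeros((32, 32, 3)))


class TestPcaLinearSvm:
    def test_separable_gaussians_high_accuracy(self, gaussian_pair):
        """Held-out accuracy >= 0.95 when Bayes error is < 0.002."""
        X, y = gaussian_pair
        train, test = slice(0, 150), slice(150, None)
        m = PcaLinearSvm(C_grid=TINY_C_GRID, n_components_grid=TINY_NC_GRID, random_state=0)
        m.fit(X[train], y[train])
        acc = (m.predict(X[test]) == y[test]).mean()
        assert acc >= 0.95

    def test_score_ranking_auc(self, gaussian_pair):
        X, y = gaussian_pair
        m = PcaLinearSvm(C_grid=TINY_C_GRID, n_components_grid=TINY_NC_GRID, random_state=0)
        m.fit(X[:150], y[:150])
        scores = m.decision_function(X[150:])
        _, _, auc = cv.binary_metrics(y[150:], scores > 0, scores)
        assert auc >= 0.99

    def test_degenerate_labels(self, gaussian_pair):
        X, _ = gaussian_pair
        m = PcaLinearSvm()
        with pytest.raises(ValueError, match="degenerate labels"):
            m.fit(X[:50], np.ones(50, dtype=bool))

    def test_deterministic_refit(self, gaussian_pair):
        X, y = gaussian_pair
        fits = [
            PcaLinearSvm(C_grid=(0.1, 1.0), n_components_grid=(4, 8), random_state=7).fit(
                X[:120], y[:120]
            )
            for _ in range(2)
        ]
        assert fits[0].n_components_ == fits[1].n_components_
        assert fits[0].C_ == fits[1].C_
        assert np.array_equal(fits[0].coef_, fits[1].coef_)
        assert np.array_equal(fits[0].components_, fits[1].components_)

    def test_grid_clipped_for_small_samples(self, gaussian_pair):
        X, y = gaussian_pair
        m = PcaLinearSvm(C_grid=(1.0,), n_components_grid=(512,), random_state=0)
        m.fit(X[:30], y[:30])  # grid auto-clipped, no failure
        assert m.n_components_ <= 30

    def test_boundary_score_is_negative_label(self):
        """An exact-zero decision value classifies as negative (strict >)."""
        m = PcaLinearSvm()
        m.mean_ = np.zeros(4)
        m.components_ = np.eye(2, 4)
        m.coef_ = np.array([1.0, 0.0])
        m.intercept_ = 0.0
        m.n_features_in_ = 4
        m.classes_ = np.array([False, True])
        x = np.zeros((1, 4))  # lies exactly on the hyperplane
        assert m.decision_function(x)[0] == 0.0
        assert not m.predict(x)[0]

    def test_score_sign_matches_label(self, gaussian_pair):
        X, y = gaussian_pair
        m = PcaLinearSvm(C_grid=(1.0,), n_components_grid=(8,), random_state=1)
        m.fit(X[:100], y[:100])
        s = m.decision_function(X[100:])
        p = m.predict(X[100:])
        nz = s != 0
        assert np.array_equal(p[nz], s[nz] > 0)


class TestVotingConsensus:
    def test_majority_equals_brute_force_oracle(self):
        """Voting output equals count-of-true >= 2 on all 8 label patterns."""
        model = cv.SignConsensusClassifier(consensus="voting")
        # install stub submodels with controllable outputs
        for pattern in itertools.product([False, True], repeat=3):
            class Stub:
                def __init__(self, value):
                    self.value = value

                def decision_function(self, X):
                    return np.full(len(np.atleast_2d(X)), 1.0 if self.value else -1.0)

            model.submodels_ = [Stub(v) for v in pattern]
            model.n_features_in_ = 4
            pred = model.predict(np.zeros((1, 4)))[0]
            assert pred == (sum(pattern) >= 2), pattern

    def test_all_negative_score_is_mean(self):
        model = cv.SignConsensusClassifier(consensus="voting")

        class Stub:
            def __init__(self, s):
                self.s = s

            def decision_function(self, X):
                return np.full(len(np.atleast_2d(X)), self.s)

        model.submodels_ = [Stub(-1.0), Stub(-2.0), Stub(-3.0)]
        model.n_features_in_ = 4
        assert not model.predict(np.zeros((1, 4)))[0]
        assert model.decision_function(np.zeros((1, 4)))[0] == pytest.approx(-2.0)


class TestAggregatingHead:
    def test_head_leans_on_rater_inputs_when_image_is_noise(self):
        """Raters equal to consensus + pure-noise pixels: accuracy >= 0.95."""
        rng = np.random.default_rng(3)
        n = 160
        X = rng.random((n, 300))
        y = rng.random(n) < 0.5
        R = np.column_stack([y, y, y])
        model = cv.SignConsensusClassifier(
            consensus="aggregating",
            C_grid=TINY_C_GRID,
            n_components_grid=(4, 8),
            random_state=0,
        )
        # submodels can't learn noise; head must exploit the +/-1 inputs
        model.fit(X[:120], y[:120], rater_labels=R[:120])
        head_X = np.hstack([X[120:], np.where(R[120:], 1.0, -1.0)])
        head_acc = ((model.head_.decision_function(head_X) > 0) == y[120:]).mean()
        assert head_acc >= 0.95

    def test_single_class_consensus_errors(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 50))
        R = rng.random((40, 3)) < 0.5
        with pytest.raises(ValueError, match="degenerate labels"):
            cv.SignConsensusClassifier(
                consensus="aggregating", C_grid=(1.0,), n_components_grid=(4,)
            ).fit(X, np.ones(40, dtype=bool), rater_labels=R)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.random((60, 40))
        y = rng.random(60) < 0.5
        R = np.column_stack([y, y ^ (rng.random(60) < 0.2), y])
        fit = lambda: cv.SignConsensusClassifier(
            consensus="aggregating", C_grid=(1.0,), n_components_grid=(4,), random_state=9
        ).fit(X, y, rater_labels=R)
        a, b = fit(), fit()
        assert np.array_equal(a.decision_function(X), b.decision_function(X))


class TestAggregatingDegradation:
    def test_head_survives_coin_flip_submodels(self, high_signal_cohort, high_signal_features):
        """With submodel outputs replaced by coin flips at inference, the
        head's accuracy stays within 0.1 of an image-only submodel's."""
        sign = cv.SignKind.EYELID_REDNESS
        roi = cv.roi_for_sign(sign)
        X, R, y = [], [], []
        for p in high_signal_cohort.patients:
            for eye in ("left", "right"):
                X.append(high_signal_features[(p.patient_id, eye)][roi])
                R.append([p.rater_labels[r][eye][sign] for r in range(3)])
                y.append(p.consensus[eye][sign])
        X, R, y = np.asarray(X), np.asarray(R), np.asarray(y)
        n_train = 90
        model = cv.SignConsensusClassifier(
            sign=sign, consensus="aggregating",
            C_grid=TINY_C_GRID, n_components_grid=TINY_NC_GRID, random_state=3,
        )
        model.fit(X[:n_train], y[:n_train], rater_labels=R[:n_train])
        X_test, y_test = X[n_train:], y[n_train:]
        image_only_acc = (model.submodels_[0].predict(X_test) == y_test).mean()
        rng = np.random.default_rng(0)
        coin = np.where(rng.random((len(X_test), 3)) < 0.5, 1.0, -1.0)
        head_scores = model.head_.decision_function(np.hstack([X_test, coin]))
        degraded_acc = ((head_scores > 0) == y_test).mean()
        assert degraded_acc >= image_only_acc - 0.1


class TestDefaultAssignment:
    def test_published_architecture_choices(self):
        a = cv.default_consensus_assignment()
        assert a[SignKind.EYELID_REDNESS] == "aggregating"
        assert a[SignKind.CARUNCLE_INFLAMMATION] == "aggregating"
        assert a[SignKind.EYELID_SWELLING] == "voting"
        assert a[SignKind.CONJUNCTIVAL_REDNESS] == "voting"
        assert a[SignKind.CONJUNCTIVAL_EDEMA] == "voting"
        assert set(a) == set(IMAGE_SIGNS)


class TestSerialization:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(8)
        n = 80
        X = rng.random((n, FEATURE_LENGTH))
        y = rng.random(n) < 0.5
        X[y, :10] += 0.5
        R = np.column_stack([y, y, y ^ (rng.random(n) < 0.1)])
        m = cv.SignConsensusClassifier(
            sign=SignKind.EYELID_REDNESS,
            consensus="aggregating",
            C_grid=TINY_C_GRID,
            n_components_grid=(4, 8),
            random_state=2,
        )
        return m.fit(X, y, rater_labels=R), X

    def test_save_load_round_trip(self, fitted, tmp_path):
        model, X = fitted
        cv.save_sign_model(model, tmp_path / "bundle")
        loaded = cv.load_sign_model(tmp_path / "bundle")
        assert np.array_equal(loaded.predict(X), model.predict(X))
        assert np.allclose(loaded.decision_function(X), model.decision_function(X))

    def test_round_trip_preserves_hyperparameters(self, fitted, tmp_path):
        model, _ = fitted
        cv.save_sign_model(model, tmp_path / "bundle")
        loaded = cv.load_sign_model(tmp_path / "bundle")
        for a, b in zip(model.submodels_, loaded.submodels_):
            assert (a.C_, a.n_components_) == (b.C_, b.n_components_)
        assert (model.head_.C_, model.head_.n_components_) == (
            loaded.head_.C_, loaded.head_.n_components_
        )

    def test_corrupt_bundle_raises(self, fitted, tmp_path):
        model, _ = fitted
        cv.save_sign_model(model, tmp_path / "bundle")
        (tmp_path / "bundle" / "meta.json").write_text("{not json")
        with pytest.raises(ValueError, match="corrupt"):
            cv.load_sign_model(tmp_path / "bundle")

    def test_version_mismatch_raises(self, fitted, tmp_path):
        import json

        model, _ = fitted
        cv.save_sign_model(model, tmp_path / "bundle")
        meta = json.loads((tmp_path / "bundle" / "meta.json").read_text())
        meta["format_version"] = 99
        (tmp_path / "bundle" / "meta.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="version"):
            cv.load_sign_model(tmp_path / "bundle")
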