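"""Splits, metrics, confusion pooling and the end-to-end experiment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import casvision as cv
from casvision.evaluation import _allocate
from casvision.signs import IMAGE_SIGNS
from tests.conftest import TINY_C_GRID, TINY_NC_GRID


class TestSplitEntire:
    def _ids(self, n):
        return [f"p{i:03d}" for i in range(n)]

    def _activity(self, ids, frac_active=0.4, frac_none=0.1):
        out = {}
        for i, pid in enumerate(ids):
            if i < frac_none * len(ids):
                out[pid] = None
            else:
                out[pid] = i % 10 < frac_active * 10
        return out

    def test_sizes(self):
        ids = self._ids(10)
        train, test = cv.split_entire(ids, self._activity(ids), 0, seed=1)
        assert len(test) == 2 and len(train) == 8
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_deterministic(self):
        ids = self._ids(50)
        act = self._activity(ids)
        assert cv.split_entire(ids, act, 3, seed=9) == cv.split_entire(ids, act, 3, seed=9)
        assert cv.split_entire(ids, act, 3, seed=9) != cv.split_entire(ids, act, 4, seed=9)

    def test_each_patient_tested_at_expected_rate(self):
        """Over 1,000 repeats, each patient appears in test ~20% of the time."""
        ids = self._ids(100)
        act = self._activity(ids)
        counts = {pid: 0 for pid in ids}
        n_rep = 1000
        for rep in range(n_rep):
            _, test = cv.split_entire(ids, act, rep, seed=0)
            for pid in test:
                counts[pid] += 1
        freqs = np.array(list(counts.values())) / n_rep
        assert np.all(np.abs(freqs - 0.2) < 0.05)

    def test_stratification_keeps_both_classes(self):
        ids = self._ids(30)
        act = {pid: i < 4 for i, pid in enumerate(ids)}  # 4 active only
        for rep in range(20):
            train, _ = cv.split_entire(ids, act, rep, seed=2)
            assert any(act[p] for p in train) and any(not act[p] for p in train)

    def test_allocation_sums(self):
        assert sum(_allocate([7, 13, 80], 20)) == 20


class TestSplitConsistent:
    def test_published_protocol_sizes(self):
        """132 consistent of 1020 patients -> test 100, train 920."""
        ids = [f"p{i:04d}" for i in range(1020)]
        consistent = {pid: i < 132 for i, pid in enumerate(ids)}
        for rep in range(5):
            train, test = cv.split_consistent(ids, consistent, rep, seed=4, test_size=100)
            assert len(test) == 100 and len(train) == 920
            assert all(consistent[p] for p in test)
            assert not set(train) & set(test)

    def test_pool_exactly_test_size(self):
        ids = [f"p{i}" for i in range(150)]
        consistent = {pid: i < 100 for i, pid in enumerate(ids)}
        _, test = cv.split_consistent(ids, consistent, 0, seed=0, test_size=100)
        assert sorted(test) == sorted(pid for pid in ids if consistent[pid])

    def test_too_few_consistent(self):
        ids = [f"p{i}" for i in range(50)]
        consistent = {pid: i < 10 for i, pid in enumerate(ids)}
        with pytest.raises(ValueError, match="10"):
            cv.split_consistent(ids, consistent, 0, seed=0, test_size=100)


class TestBinaryMetrics:
    def test_perfect(self):
        refs = [True, True, False, False]
        assert cv.binary_metrics(refs, refs, [2.0, 1.5, -1.0, -2.0]) == (1.0, 1.0, 1.0)

    def test_counting_oracle(self):
        sens, spec, _ = cv.binary_metrics(
            [1, 1, 0, 0], [1, 0, 0, 0], [0.9, 0.1, 0.2, 0.05]
        )
        assert sens == 0.5 and spec == 1.0

    def test_all_tied_scores_auc_half(self):
        _, _, auc = cv.binary_metrics([1, 0, 1, 0], [1, 0, 1, 0], [0.3] * 4)
        assert auc == 0.5

    def test_single_class_refs(self):
        with pytest.raises(ValueError, match="single class"):
            cv.binary_metrics([True, True], [True, False], [0.1, 0.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.booleans(), st.floats(-5, 5)), min_size=4, max_size=40))
    def test_rank_auc_equals_trapezoid_on_tie_free_scores(self, data):
        """Mann-Whitney AUC vs trapezoidal ROC integration (independent oracle)."""
        refs = [r for r, _ in data]
        if len(set(refs)) < 2:
            return
        # force tie-free scores by adding distinct offsets
        scores = [s + i * 1e-6 for i, (_, s) in enumerate(data)]
        if len(set(scores)) < len(scores):
            return
        _, _, auc = cv.binary_metrics(refs, refs, scores)
        # trapezoid oracle over all thresholds
        order = np.argsort(scores)[::-1]
        r = np.asarray(refs)[order]
        tpr = np.concatenate([[0], np.cumsum(r) / r.sum()])
        fpr = np.concatenate([[0], np.cumsum(~r) / (~r).sum()])
        assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-9)


class TestAggregateCi:
    def test_degenerate_zero_width(self):
        m = cv.aggregate_ci([0.8, 0.8, 0.8])
        assert m.mean == pytest.approx(0.8)
        assert m.ci_low == m.mean == m.ci_high

    def test_symmetric_mean(self):
        m = cv.aggregate_ci([0.4, 0.6, 0.45, 0.55])
        assert m.mean == pytest.approx(0.5)
        assert m.ci_low <= m.mean <= m.ci_high

    def test_t_interval_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.8, 0.05, size=30)
        m = cv.aggregate_ci(vals)
        lo, hi = stats.t.interval(0.95, 29, loc=vals.mean(), scale=stats.sem(vals))
        assert m.ci_low == pytest.approx(lo) and m.ci_high == pytest.approx(hi)
        assert m.ci_low <= 0.8 <= m.ci_high

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            cv.aggregate_ci([0.5])


class TestConfusionAndAgreement:
    def test_single_pair(self):
        cm = cv.pool_confusion([(3, 3)])
        assert cm.total == 1 and cm.matrix[3, 3] == 1

    def test_row_sums_are_reference_histogram(self):
        rng = np.random.default_rng(1)
        pairs = [(int(r), int(p)) for r, p in rng.integers(0, 8, size=(500, 2))]
        cm = cv.pool_confusion(pairs)
        hist = np.bincount([r for r, _ in pairs], minlength=8)
        assert np.array_equal(cm.matrix.sum(axis=1), hist)
        assert cm.total == 500

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cv.pool_confusion([(8, 0)])

    def test_diagonal_mass(self):
        m = np.zeros((8, 8), dtype=int)
        np.fill_diagonal(m, 5)
        assert cv.agreement_stats(cv.CasConfusion(m)) == (100.0, 100.0)

    def test_embedded_2x2_hand_enumeration(self):
        m = np.zeros((8, 8), dtype=int)
        m[0, 0] = m[0, 1] = m[1, 0] = m[1, 1] = 1
        exact, within1 = cv.agreement_stats(cv.CasConfusion(m))
        assert exact == 50.0 and within1 == 100.0

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="empty"):
            cv.agreement_stats(cv.CasConfusion(np.zeros((8, 8), dtype=int)))

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 7), st.integers(0, 7)), min_size=1, max_size=60))
    def test_within1_bounds_and_pairwise_oracle(self, pairs):
        """within-1 >= exact, and both match a direct |ref-pred| enumeration."""
        cm = cv.pool_confusion(pairs)
        exact, within1 = cv.agreement_stats(cm)
        n = len(pairs)
        oracle_exact = 100.0 * sum(r == p for r, p in pairs) / n
        oracle_within1 = 100.0 * sum(abs(r - p) <= 1 for r, p in pairs) / n
        assert exact == pytest.approx(oracle_exact)
        assert within1 == pytest.approx(oracle_within1)
        assert within1 >= exact


class TestRunExperiment:
    def test_deterministic_reports(self, high_signal_cohort, high_signal_features):
        cfg = cv.ExperimentConfig(n_repeats=1, seed=33)
        kw = dict(
            C_grid=TINY_C_GRID,
            n_components_grid=TINY_NC_GRID,
            features=high_signal_features,
        )
        a = cv.run_experiment(high_signal_cohort, cfg, **kw).to_dict()
        b = cv.run_experiment(high_signal_cohort, cfg, **kw).to_dict()
        assert a == b

    def test_high_signal_recovery_small(self, high_signal_cohort, high_signal_features):
        """On the linearly separable fixture every sign is recovered well."""
        cfg = cv.ExperimentConfig(n_repeats=2, seed=7)
        rep = cv.run_experiment(
            high_signal_cohort,
            cfg,
            C_grid=TINY_C_GRID,
            n_components_grid=TINY_NC_GRID,
            features=high_signal_features,
        )
        assert rep.completed_repeats == 2
        for sign in IMAGE_SIGNS:
            assert rep.per_sign[sign]["auc"].mean >= 0.9, sign
        assert rep.confusion.total > 0
        assert rep.within1_agreement.mean >= rep.exact_agreement.mean

    def test_all_pains_missing_yields_undefined_cas_sections(self):
        spec = cv.CohortSpec(
            n_patients=40,
            seed=3,
            missing_pain_fraction=1.0,
            intensity_range=(1.0, 1.0),
            raters=tuple(cv.RaterProfile(0.98, 0.98) for _ in range(3)),
            consensus_flip_prob=0.0,
        )
        cohort = cv.generate_cohort(spec)
        cfg = cv.ExperimentConfig(n_repeats=1, seed=0, stratify=False)
        rep = cv.run_experiment(
            cohort, cfg, C_grid=(1.0,), n_components_grid=(8,)
        )
        assert rep.confusion.total == 0
        assert rep.cas_undefined_reason == "missing_pain"
        assert rep.per_sign  # sign metrics still produced
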