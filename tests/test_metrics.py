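import numpy as np
import pandas as pd
import pytest

from peprank.metrics import (
    METRIC_NAMES,
    RankedPredictions,
    UndefinedMetricError,
    auc,
    average_rank,
    best_per_metric,
    hit_rate,
    hybrid_metric,
    hybrid_scores,
    metric_report,
    ranks_from_scores,
    roc_t,
)
from peprank.preprocessing import normalize_affinity
from peprank.simulate import generate_ranked_fixture

B500 = normalize_affinity(500.0)
B100 = normalize_affinity(100.0)


def _b(positive, strong=False):
    if strong:
        return B100 + 0.1
    return B500 + 0.05 if positive else B500 - 0.1


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_ranks(scores):
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    ranks = [0] * len(scores)
    for r, i in enumerate(order):
        ranks[i] = r + 1
    return ranks


def oracle_ar(scores, pos):
    ranks = oracle_ranks(scores)
    vals = [ranks[i] for i in range(len(scores)) if pos[i]]
    return sum(vals) / len(vals)


def oracle_hr(scores, pos):
    ranks = oracle_ranks(scores)
    t = sum(pos)
    hits = sum(1 for i in range(len(scores)) if pos[i] and ranks[i] <= t)
    return hits / t


def oracle_auc(scores, pos):
    wins = total = 0
    for i in range(len(scores)):
        for j in range(len(scores)):
            if pos[i] and not pos[j]:
                total += 1
                wins += scores[i] > scores[j]
    return wins / total


def oracle_roc_t(scores, pos, t):
    neg = sorted((scores[i] for i in range(len(scores)) if not pos[i]), reverse=True)
    top = neg[:t]
    n_pos = sum(pos)
    wins = sum(
        1 for i in range(len(scores)) if pos[i] for s in top if scores[i] > s
    )
    return wins / (n_pos * t)


class TestExamples:
    def test_average_rank(self):
        scores = [4.0, 3.0, 2.0, 1.0]
        b = [_b(True), _b(False), _b(True), _b(False)]
        assert average_rank(scores, b, 500.0) == pytest.approx(2.0)

    def test_average_rank_extremes(self):
        n, k = 10, 3
        b = [_b(True)] * k + [_b(False)] * (n - k)
        top = list(range(n, 0, -1))
        assert average_rank(top, b, 500.0) == pytest.approx((k + 1) / 2)
        bottom = list(range(1, n + 1))
        assert average_rank(bottom, b, 500.0) == pytest.approx(n - (k - 1) / 2)

    def test_hit_rate(self):
        scores = [4.0, 3.0, 2.0, 1.0]
        b = [_b(True), _b(False), _b(True), _b(False)]
        assert hit_rate(scores, b, 500.0) == pytest.approx(0.5)
        perfect = [4.0, 1.0, 3.0, 2.0]
        assert hit_rate(perfect, b, 500.0) == pytest.approx(1.0)

    def test_auc(self):
        scores = [0.9, 0.7, 0.8, 0.2]
        b = [_b(True), _b(True), _b(False), _b(False)]
        assert auc(scores, b) == pytest.approx(0.75)

    def test_auc_all_ties_zero_under_strict_indicator(self):
        scores = [0.5, 0.5, 0.5, 0.5]
        b = [_b(True), _b(True), _b(False), _b(False)]
        assert auc(scores, b) == 0.0

    def test_roc_t(self):
        scores = [0.9, 0.7, 0.8, 0.2]
        b = [_b(True), _b(True), _b(False), _b(False)]
        assert roc_t(scores, b, 1) == pytest.approx(0.5)
        assert roc_t(scores, b, 2) == pytest.approx(auc(scores, b))

    def test_undefined_signals(self):
        with pytest.raises(UndefinedMetricError):
            auc([1.0, 2.0], [_b(True), _b(True)])
        with pytest.raises(UndefinedMetricError):
            average_rank([1.0], [_b(False)], 500.0)
        with pytest.raises(UndefinedMetricError):
            roc_t([1.0, 2.0], [_b(True), _b(False)], 5)


class TestOracleEquivalence:
    """All ranking metrics against exhaustive brute force on random
    instances of up to 12 peptides."""

    def test_500_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n = int(rng.integers(3, 13))
            scores = rng.normal(size=n)
            pos = rng.random(n) < 0.5
            if not pos.any() or pos.all():
                pos[0] = True
                pos[-1] = False
            b = np.where(pos, _b(True), _b(False))
            assert average_rank(scores, b, 500.0) == pytest.approx(
                oracle_ar(scores, pos)
            )
            assert hit_rate(scores, b, 500.0) == pytest.approx(
                oracle_hr(scores, pos)
            )
            assert auc(scores, b) == pytest.approx(oracle_auc(scores, pos))
            n_neg = int((~pos).sum())
            t = int(rng.integers(1, n_neg + 1))
            assert roc_t(scores, b, t) == pytest.approx(
                oracle_roc_t(scores, pos, t)
            )

    def test_sklearn_cross_check_on_tie_free_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(20):
            scores = rng.normal(size=30)
            pos = rng.random(30) < 0.4
            if not pos.any() or pos.all():
                continue
            b = np.where(pos, _b(True), _b(False))
            assert auc(scores, b) == pytest.approx(roc_auc_score(pos, scores))


class TestInvariances:
    def test_monotone_transform_invariance(self):
        fixture = generate_ranked_fixture(6, 10, seed=3)
        transformed = np.exp(2.0 * fixture.scores) + 5.0
        for fn in (lambda s: auc(s, fixture.b), lambda s: roc_t(s, fixture.b, 4)):
            assert fn(fixture.scores) == pytest.approx(fn(transformed))

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=40)
        ranks = ranks_from_scores(scores)
        assert sorted(ranks) == list(range(1, 41))

    def test_metric_report_handles_undefined(self):
        # no peptide under 100 nM: AR100/HR100 undefined -> NaN
        b = [_b(True), _b(True), _b(False), _b(False)]
        report = metric_report([4.0, 3.0, 2.0, 1.0], b)
        assert np.isnan(report["AR100"]) and np.isnan(report["ROC5"])
        assert report["AUC"] == 1.0


class TestHybridMetric:
    def test_single_config_is_zero(self):
        values = dict(zip(METRIC_NAMES, [3.0, 0.5, 5.0, 0.6, 0.9, 0.8, 0.85]))
        table = pd.DataFrame([values])
        assert hybrid_scores(table).iloc[0] == pytest.approx(0.0)

    def test_dominating_config_wins(self):
        good = dict(zip(METRIC_NAMES, [2.0, 0.9, 3.0, 0.8, 0.95, 0.9, 0.92]))
        bad = dict(zip(METRIC_NAMES, [4.0, 0.5, 6.0, 0.6, 0.85, 0.7, 0.75]))
        table = pd.DataFrame([good, bad])
        h = hybrid_scores(table)
        assert h.iloc[0] == pytest.approx(0.0)
        # termwise direct evaluation of the dominated config
        best = best_per_metric(table)
        expected = 0.0
        for m in METRIC_NAMES:
            sign = 1.0 if m.startswith("AR") else -1.0
            expected += sign * (bad[m] - best[m]) / best[m]
        assert h.iloc[1] == pytest.approx(expected)
        assert h.iloc[1] > 0

    def test_undefined_metric_raises(self):
        values = dict(zip(METRIC_NAMES, [3.0, 0.5, 5.0, 0.6, np.nan, 0.8, 0.85]))
        with pytest.raises(UndefinedMetricError):
            hybrid_metric(values, {m: 1.0 for m in METRIC_NAMES})


class TestRankedPredictions:
    def test_frame_round_trip(self):
        fixture = generate_ranked_fixture(3, 4, seed=9)
        back = RankedPredictions.from_frame(fixture.to_frame())
        np.testing.assert_allclose(back.scores, fixture.scores)
        np.testing.assert_allclose(back.b, fixture.b)
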