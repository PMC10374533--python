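"""Q75 pooling, PR curves, average precision, threshold choice, TPR/TNR."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from botopam.evaluation import (
    PRCurve,
    average_precision,
    micro_map,
    pr_curve,
    q75_scores,
    q75_summarize,
    select_threshold,
    tpr_tnr_at,
)


def _brute_force_ap(labels, scores):
    """Independent step-integral oracle: enumerate thresholds, sum rectangles."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.sort(np.unique(scores))
    points = []
    for t in thresholds:
        pred = scores >= t
        tp = np.sum(pred & labels)
        ppv = tp / pred.sum()
        tpr = tp / labels.sum()
        points.append((tpr, ppv))
    points.append((0.0, 1.0))  # boundary convention
    return sum(
        (points[i][0] - points[i + 1][0]) * points[i][1]
        for i in range(len(points) - 1)
    )


class TestQ75:
    def test_constant_vector(self):
        assert q75_summarize(np.full(16, 0.42)) == pytest.approx(0.42)

    def test_arithmetic_sequence(self):
        # values 1..16 scaled: mean of top four = (13+14+15+16)/4/16
        raw = np.arange(1, 17) / 16.0
        assert q75_summarize(raw) == pytest.approx(0.90625)

    def test_single_spike(self):
        raw = np.zeros(16)
        raw[5] = 1.0
        assert q75_summarize(raw) == pytest.approx(0.25)

    def test_matches_bruteforce_topk_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            raw = rng.random(16)
            expected = np.mean(sorted(raw)[-4:])
            assert abs(q75_summarize(raw) - expected) < 1e-12

    def test_vectorized_agrees_with_scalar(self, rng):
        arr = rng.random((7, 16, 3))
        q = q75_scores(arr)
        for i in range(7):
            for c in range(3):
                assert q[i, c] == pytest.approx(q75_summarize(arr[i, :, c]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            q75_summarize(np.array([]))
        with pytest.raises(ValueError):
            q75_summarize(np.array([0.1, np.nan]))

    @given(arrays(np.float64, 16, elements=st.floats(0, 1)))
    def test_permutation_invariant(self, raw):
        rng = np.random.default_rng(0)
        assert q75_summarize(raw) == pytest.approx(
            q75_summarize(rng.permutation(raw))
        )

    @given(
        arrays(np.float64, 16, elements=st.floats(0, 1)),
        st.integers(0, 15),
        st.floats(0, 1),
    )
    def test_monotone_in_every_coordinate(self, raw, idx, bump):
        raised = raw.copy()
        raised[idx] = min(1.0, raised[idx] + bump)
        assert q75_summarize(raised) >= q75_summarize(raw) - 1e-12


class TestPRCurve:
    def test_three_point_example(self):
        curve = pr_curve(np.array([1, 0, 1]), np.array([0.9, 0.8, 0.3]))
        # ascending thresholds 0.3, 0.8, 0.9 -> (TPR, PPV) =
        # (1, 2/3), (1/2, 1/2), (1/2, 1); boundary (0, 1)
        assert np.allclose(curve.thresholds, [0.3, 0.8, 0.9])
        assert np.allclose(curve.tpr, [1.0, 0.5, 0.5, 0.0])
        assert np.allclose(curve.ppv, [2 / 3, 0.5, 1.0, 1.0])

    def test_perfect_separation_hits_corner(self):
        curve = pr_curve(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1]))
        corner = np.flatnonzero(np.isclose(curve.ppv, 1) & np.isclose(curve.tpr, 1))
        assert corner.size >= 1

    def test_inverted_scores_ppv_at_full_recall_is_prevalence(self):
        labels = np.array([1, 1, 0, 0, 0])
        scores = np.array([0.1, 0.2, 0.8, 0.9, 0.7])
        curve = pr_curve(labels, scores)
        assert curve.ppv[0] == pytest.approx(2 / 5)  # lowest threshold: all predicted
        assert curve.tpr[0] == pytest.approx(1.0)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve(np.zeros(4), np.ones(4) * 0.5)

    def test_tpr_non_increasing(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[0] = 1
        scores = rng.random(50)
        curve = pr_curve(labels, scores)
        assert np.all(np.diff(curve.tpr) <= 1e-12)


class TestAveragePrecision:
    def test_perfect_classifier_ap_is_one(self):
        curve = pr_curve(np.array([1, 1, 0]), np.array([0.9, 0.8, 0.1]))
        assert average_precision(curve) == pytest.approx(1.0)

    def test_three_point_example_value(self):
        curve = pr_curve(np.array([1, 0, 1]), np.array([0.9, 0.8, 0.3]))
        # (1 - 1/2)*2/3 + (1/2 - 1/2)*1/2 + (1/2 - 0)*1
        assert average_precision(curve) == pytest.approx(1 / 3 + 1 / 2)

    def test_constant_scores_ap_is_prevalence(self):
        labels = np.array([1, 0, 0, 1, 0])
        curve = pr_curve(labels, np.full(5, 0.6))
        assert average_precision(curve) == pytest.approx(0.4)

    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 50)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[rng.integers(n)] = 1
            scores = np.round(rng.random(n), 2)  # force ties regularly
            curve = pr_curve(labels, scores)
            assert average_precision(curve) == pytest.approx(
                _brute_force_ap(labels, scores), abs=1e-12
            )

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for seed in range(50):
            r = np.random.default_rng(seed)
            n = r.integers(5, 80)
            labels = r.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            scores = r.random(n)
            ours = average_precision(pr_curve(labels, scores))
            assert ours == pytest.approx(average_precision_score(labels, scores))


class TestMicroMap:
    def test_single_class_equals_class_ap(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[0] = 1
        scores = rng.random(30)
        ap = average_precision(pr_curve(labels, scores))
        assert micro_map({"click": labels}, {"click": scores}) == pytest.approx(ap)

    def test_duplicated_class_leaves_map_unchanged(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[0] = 1
        scores = rng.random(30)
        single = micro_map({"a": labels}, {"a": scores})
        double = micro_map(
            {"a": labels, "b": labels}, {"a": scores, "b": scores}
        )
        assert double == pytest.approx(single)

    def test_class_order_invariant(self, rng):
        data = {
            c: (rng.integers(0, 2, 20), rng.random(20))
            for c in ("click", "boat", "rain")
        }
        for c in data:
            data[c][0][0] = 1
        fwd = micro_map({c: v[0] for c, v in data.items()},
                        {c: v[1] for c, v in data.items()})
        rev = micro_map(
            {c: data[c][0] for c in reversed(list(data))},
            {c: data[c][1] for c in reversed(list(data))},
        )
        assert fwd == pytest.approx(rev)

    def test_pooled_matches_bruteforce(self, rng):
        labels = {c: rng.integers(0, 2, 25) for c in ("click", "boat", "rain")}
        scores = {c: rng.random(25) for c in labels}
        for c in labels:
            labels[c][0] = 1
        pooled_l = np.concatenate([labels[c] for c in sorted(labels)])
        pooled_s = np.concatenate([scores[c] for c in sorted(labels)])
        assert micro_map(labels, scores) == pytest.approx(
            _brute_force_ap(pooled_l, pooled_s)
        )


class TestSelectThreshold:
    def test_exact_equality_point_returned(self):
        curve = PRCurve(
            thresholds=np.array([0.2, 0.7, 0.9]),
            ppv=np.array([0.5, 0.8, 1.0, 1.0]),
            tpr=np.array([1.0, 0.8, 0.3, 0.0]),
        )
        assert select_threshold(curve) == pytest.approx(0.7)

    def test_perfect_classifier_highest_equality_threshold(self):
        curve = pr_curve(np.array([1, 1, 0]), np.array([0.9, 0.8, 0.1]))
        assert select_threshold(curve) == pytest.approx(0.8)

    def test_matches_exhaustive_scan(self, rng):
        for seed in range(30):
            r = np.random.default_rng(seed)
            labels = r.integers(0, 2, 40)
            labels[0] = 1
            scores = r.random(40)
            curve = pr_curve(labels, scores)
            gaps = np.abs(curve.ppv[:-1] - curve.tpr[:-1])
            best_gap = gaps.min()
            chosen = select_threshold(curve)
            idx = np.flatnonzero(np.isclose(curve.thresholds, chosen))[0]
            assert gaps[idx] == pytest.approx(best_gap)
            # ties break toward the higher threshold
            later = np.flatnonzero(np.isclose(gaps, best_gap))
            assert idx == later[-1]


class TestTprTnr:
    def test_perfect_classifier(self):
        labels = np.r_[np.ones(40), np.zeros(40)]
        scores = np.r_[np.full(40, 0.9), np.full(40, 0.1)]
        tpr, tnr = tpr_tnr_at(labels, scores, 0.5, seed=0)
        assert (tpr, tnr) == (1.0, 1.0)

    def test_counting_on_constructed_pool(self):
        # 30 predicted positives with exactly 2 false, 30 predicted
        # negatives with exactly 3 false -> TPR = 28/31, TNR = 27/29
        labels = np.r_[np.ones(28), np.zeros(2), np.zeros(27), np.ones(3)]
        scores = np.r_[np.full(30, 0.9), np.full(30, 0.1)]
        tpr, tnr = tpr_tnr_at(labels, scores, 0.5, n_sample=60, seed=1)
        assert tpr == pytest.approx(28 / 31)
        assert tnr == pytest.approx(27 / 29)

    def test_degenerate_sample_flags_undefined_rate(self):
        # no true positives in the pool: TPR has an empty denominator
        labels = np.zeros(10)
        scores = np.full(10, 0.2)
        with pytest.warns(UserWarning):
            tpr, tnr = tpr_tnr_at(labels, scores, 0.9, seed=0)
        assert tpr is None
        assert tnr == 1.0

    def test_small_stratum_taken_whole(self):
        labels = np.r_[np.ones(3), np.zeros(50)]
        scores = np.r_[np.full(3, 0.95), np.full(50, 0.05)]
        with pytest.warns(UserWarning, match="fewer"):
            tpr, tnr = tpr_tnr_at(labels, scores, 0.5, n_sample=60, seed=0)
        assert tpr == 1.0 and tnr == 1.0
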