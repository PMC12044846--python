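"""ROC estimator, DeLong inference, Youden cutoff, power and linearity QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evscore.evaluation import (
    PowerSpec,
    accuracy_from_sens_spec,
    auroc,
    confusion_metrics,
    delong_ci,
    delong_paired,
    delong_variance,
    group_compare,
    linearity_fit,
    power_paired_auroc,
    roc_summary,
    youden_cutoff,
)


def brute_force_auroc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    distinct = np.unique(scores)
    cands = [-np.inf, *((distinct[:-1] + distinct[1:]) / 2.0), np.inf]
    best = None
    for t in cands:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        key = (sens + spec - 1.0, spec, -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


class TestAuroc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([2, 3, 0, 1], [1, 1, 0, 0], 1.0),
            ([1, 1], [1, 0], 0.5),
            ([3, 1, 2, 0], [1, 1, 0, 0], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert auroc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1.0, 2.0], [1, 1])

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=50),
        st.data(),
    )
    def test_matches_pairwise_enumeration(self, scores, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        if not (any(labels) and not all(labels)):
            labels[0], labels[-1] = True, False
        assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels))


class TestYouden:
    def test_separated_groups(self):
        cutoff, sens, spec = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert (cutoff, sens, spec) == (0.5, 1.0, 1.0)

    def test_degenerate_identical_scores(self):
        cutoff, sens, spec = youden_cutoff([1.0] * 6, [0, 0, 0, 1, 1, 1])
        assert sens + spec - 1.0 == pytest.approx(0.0)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.integers(0, 8), min_size=4, max_size=20), st.data())
    def test_matches_exhaustive_search(self, scores, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        labels[0], labels[-1] = True, False
        got = youden_cutoff(scores, labels)
        want = brute_force_youden(scores, labels)
        assert got == pytest.approx(want)


class TestDeLong:
    def test_perfect_separation_degenerate_ci(self):
        with pytest.warns(UserWarning, match="zero DeLong variance"):
            low, high = delong_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert (low, high) == (1.0, 1.0)

    def test_null_coverage_near_nominal(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 500
        for _ in range(reps):
            scores = rng.normal(size=60)
            labels = np.repeat([True, False], 30)
            low, high = delong_ci(scores, labels)
            hits += low <= 0.5 <= high
        assert hits / reps == pytest.approx(0.95, abs=0.03)

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([True, False], 20)
        scores = np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)])
        var = delong_variance(scores, labels)
        boots = []
        for _ in range(2000):
            idx_p = rng.integers(0, 20, 20)
            idx_n = 20 + rng.integers(0, 20, 20)
            boots.append(auroc(scores[np.r_[idx_p, idx_n]], labels))
        boot_var = np.var(boots, ddof=1)
        assert var == pytest.approx(boot_var, rel=0.2)

    def test_paired_identical_scores_p_one(self):
        s = [0.3, 0.6, 0.1, 0.9, 0.5, 0.7]
        assert delong_paired(s, s, [1, 1, 1, 0, 0, 0]) == 1.0

    def test_paired_detects_strong_difference(self):
        rng = np.random.default_rng(7)
        labels = np.repeat([True, False], 50)
        good = np.concatenate([rng.normal(5, 1, 50), rng.normal(0, 1, 50)])
        bad = rng.normal(size=100)
        assert delong_paired(good, bad, labels) < 1e-3

    def test_paired_symmetric_in_assays(self):
        rng = np.random.default_rng(8)
        labels = np.repeat([True, False], 15)
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert delong_paired(a, b, labels) == pytest.approx(delong_paired(b, a, labels))


class TestConfusion:
    def test_all_correct(self):
        assert confusion_metrics([1, 1, 0], [1, 1, 0]) == (1.0, 1.0, 1.0)

    def test_all_positive_calls(self):
        sens, spec, acc = confusion_metrics([1, 1, 1, 1], [1, 0, 1, 0])
        assert (sens, spec) == (1.0, 0.0)
        assert acc == pytest.approx(0.5)

    def test_hand_counts(self):
        calls = [1] * 26 + [0] * 8 + [0] * 15 + [1] * 2
        labels = [1] * 34 + [0] * 17
        sens, spec, acc = confusion_metrics(calls, labels)
        assert acc == pytest.approx(41 / 51)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class TestAccuracyFromRates:
    @pytest.mark.parametrize(
        "sens, spec, n_pos, n_neg, expected",
        [
            (0.765, 0.882, 34, 17, 0.804),
            (0.818, 0.875, 33, 16, 0.837),
            (1.0, 1.0, 10, 5, 1.0),
        ],
    )
    def test_reported_rates_reproduce_reported_accuracy(
        self, sens, spec, n_pos, n_neg, expected
    ):
        assert accuracy_from_sens_spec(sens, spec, n_pos, n_neg) == pytest.approx(
            expected, abs=5e-4
        )

    @settings(deadline=None, max_examples=40)
    @given(st.integers(1, 40), st.integers(1, 40), st.data())
    def test_exact_for_integer_ratios(self, n_pos, n_neg, data):
        tp = data.draw(st.integers(0, n_pos))
        tn = data.draw(st.integers(0, n_neg))
        acc = accuracy_from_sens_spec(tp / n_pos, tn / n_neg, n_pos, n_neg)
        assert acc == pytest.approx((tp + tn) / (n_pos + n_neg), abs=1e-12)


class TestPower:
    def test_null_design_rejects_at_alpha(self):
        spec = PowerSpec(0.75, 0.75, corr=0.5, n_pos=32, n_neg=16, reps=600, seed=1)
        power, mc_se = power_paired_auroc(spec)
        assert power == pytest.approx(0.05, abs=3 * mc_se + 0.02)

    def test_perfectly_correlated_equal_assays_never_reject(self):
        spec = PowerSpec(0.8, 0.8, corr=1.0, n_pos=16, n_neg=16, reps=200, seed=2)
        power, _ = power_paired_auroc(spec)
        assert power == 0.0

    def test_monotone_in_auroc_gap(self):
        powers = [
            power_paired_auroc(
                PowerSpec(a, 0.6, corr=0.5, n_pos=32, n_neg=16, reps=400, seed=3)
            )[0]
            for a in (0.7, 0.8, 0.9)
        ]
        assert powers[0] <= powers[1] <= powers[2]

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(0.8, 0.6, corr=0.5, n_pos=10, n_neg=10, reps=50)


class TestLinearity:
    def test_exact_line(self):
        series = pd.DataFrame(
            {"level": [0, 1, 2, 4], "gene": "g", "copies": [0, 2, 4, 8]}
        )
        fit = linearity_fit(series)[0]
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_line_high_r2(self):
        from evscore.synthetic import gen_linearity_series

        good = 0
        for seed in range(10):
            series = gen_linearity_series(
                [0, 1, 2, 4, 8, 16, 32], {"g": 50.0}, noise_cv=0.05, seed=seed
            )
            good += linearity_fit(series)[0].r_squared >= 0.99
        assert good >= 8

    def test_shuffled_response_near_zero_r2(self):
        rng = np.random.default_rng(9)
        r2 = []
        for _ in range(30):
            y = 2.0 * np.arange(8.0)
            rng.shuffle(y)
            series = pd.DataFrame({"level": np.arange(8.0), "gene": "g", "copies": y})
            r2.append(linearity_fit(series)[0].r_squared)
        assert np.mean(r2) < 0.3

    def test_constant_response_rejected(self):
        series = pd.DataFrame({"level": [0, 1, 2], "gene": "g", "copies": [5, 5, 5]})
        with pytest.raises(ValueError, match="variance"):
            linearity_fit(series)


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        _, p = group_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_disjoint_groups_minimal_p(self):
        u, p = group_compare([1, 2, 3], [10, 11, 12])
        assert u in (0.0, 9.0)
        assert p < 0.1

    def test_symmetric(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 3.0, 8.0, 0.5]
        assert group_compare(a, b)[1] == pytest.approx(group_compare(b, a)[1])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])


def test_roc_summary_consistency():
    rng = np.random.default_rng(10)
    scores = np.concatenate([rng.normal(1.5, 1, 40), rng.normal(0, 1, 40)])
    labels = np.repeat([True, False], 40)
    summary = roc_summary(scores, labels)
    assert summary.ci_low <= summary.auroc <= summary.ci_high
    assert summary.n_pos == summary.n_neg == 40
    calls = scores >= summary.cutoff
    sens, spec, acc = confusion_metrics(calls, labels)
    assert (sens, spec, acc) == (
        pytest.approx(summary.sensitivity),
        pytest.approx(summary.specificity),
        pytest.approx(summary.accuracy),
    )
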