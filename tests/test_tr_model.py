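"""Published TR model arithmetic, refitting, cross-validation, LASSO."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from evscore import (
    GeneWeights,
    SimConfig,
    build_score_records,
    classify,
    fit_tr,
    gen_tr_cohort,
    kfold_auroc,
    lasso_auroc,
    loocv_auroc,
    published_model,
    tr_score,
)
from evscore.evaluation import auroc
from evscore.tr_model import stratified_folds


def make_records(post, delta, labels):
    return pd.DataFrame(
        {
            "post_score": post,
            "delta_score": delta,
            "label": ["viable" if v else "nonviable" for v in labels],
        },
        index=[f"P{i}" for i in range(len(post))],
    )


def simulated_records(n, seed, beta=(-1.0, 1.5, 1.0), noise=True):
    rng = np.random.default_rng(seed)
    post = rng.normal(0, 1, n)
    delta = rng.normal(0, 1, n)
    lp = beta[0] + beta[1] * post + beta[2] * delta
    y = rng.uniform(size=n) < 1 / (1 + np.exp(-lp)) if noise else lp > 0
    return make_records(post, delta, y)


class TestPublishedModel:
    def test_frozen_coefficients_and_cutoff(self):
        m = published_model()
        assert (m.intercept, m.beta_post, m.beta_delta, m.cutoff) == (
            -8.132,
            1.226,
            1.146,
            0.76,
        )
        assert m.provenance == "published"

    def test_immutable(self):
        with pytest.raises(dataclasses.FrozenInstanceError):
            published_model().intercept = 0.0

    def test_linear_predictor_values(self):
        m = published_model()
        assert tr_score(m, 0.0, 0.0) == pytest.approx(-8.132)
        assert tr_score(m, 1.0, 1.0) == pytest.approx(-5.760)

    def test_affine_in_post_score(self):
        m = published_model()
        for x in (0.5, 2.0, -3.0):
            diff = tr_score(m, 1.0 + x, 0.3) - tr_score(m, 1.0, 0.3)
            assert diff == pytest.approx(m.beta_post * x)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            tr_score(published_model(), np.nan, 0.0)


class TestClassify:
    @pytest.mark.parametrize(
        "score, call", [(0.76, "viable"), (0.75, "nonviable"), (10.0, "viable")]
    )
    def test_cutoff_boundary(self, score, call):
        assert classify(published_model(), score) == call

    def test_monotone_in_score(self):
        m = published_model()
        calls = [classify(m, s) for s in np.linspace(-5, 5, 101)]
        flips = sum(a != b for a, b in zip(calls, calls[1:]))
        assert flips == 1


class TestFitTR:
    def test_recovers_generating_coefficients(self):
        cfg = SimConfig(seed=11, tr_coefficients=(-8.132, 1.226, 1.146))
        table, _, truth = gen_tr_cohort(1500, 1500, cfg)
        w = GeneWeights(
            weights=pd.Series({g: 1.0 for g in cfg.panel_genes}),
            reference_stats=pd.DataFrame(columns=["mean", "sd"]),
        )
        records = build_score_records(table, w)
        m = fit_tr(records)
        est = np.array([m.intercept, m.beta_post, m.beta_delta])
        true = np.array(truth.tr_coefficients)
        assert np.all(np.abs((est - true) / true) < 0.25)

    def test_label_swap_negates_coefficients(self):
        records = simulated_records(300, seed=12)
        swapped = records.copy()
        swapped["label"] = np.where(records["label"] == "viable", "nonviable", "viable")
        m1, m2 = fit_tr(records), fit_tr(swapped)
        assert m2.intercept == pytest.approx(-m1.intercept, abs=1e-4)
        assert m2.beta_post == pytest.approx(-m1.beta_post, abs=1e-4)
        assert m2.beta_delta == pytest.approx(-m1.beta_delta, abs=1e-4)

    def test_separable_data_flagged_and_finite(self):
        records = make_records(
            [3.0, 4.0, 5.0, -3.0, -4.0, -5.0],
            [1.0, 2.0, 3.0, -1.0, -2.0, -3.0],
            [1, 1, 1, 0, 0, 0],
        )
        m = fit_tr(records)
        assert "penalized_separation_fallback" in m.flags
        assert np.isfinite([m.intercept, m.beta_post, m.beta_delta]).all()

    def test_single_class_rejected(self):
        records = make_records([1, 2, 3], [0, 0, 0], [1, 1, 1])
        with pytest.raises(ValueError):
            fit_tr(records)


class TestCrossValidation:
    def test_loocv_matches_brute_force_refits(self):
        # deterministic overlapping toy set: every leave-one-out fold converges
        records = make_records(
            [2.0, 3.0, 1.0, 2.5, 0.5, 1.5, 2.2, 0.8, 3.2, 1.2],
            [0.5, 1.0, -0.5, 0.2, 0.8, -1.0, 0.4, -0.2, -0.8, 0.6],
            [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
        )
        X = records[["post_score", "delta_score"]].to_numpy()
        y = (records["label"] == "viable").to_numpy()
        heldout = np.empty(len(y))
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            res = sm.Logit(y[mask].astype(float), sm.add_constant(X[mask])).fit(disp=0)
            heldout[i] = res.params[0] + X[i] @ res.params[1:]
        assert loocv_auroc(records) == pytest.approx(auroc(heldout, y))

    def test_kfold_with_k_equal_n_is_loocv(self):
        records = simulated_records(14, seed=14)
        assert kfold_auroc(records, k=len(records), seed=0) == pytest.approx(
            loocv_auroc(records)
        )

    def test_kfold_deterministic_in_seed(self):
        records = simulated_records(40, seed=15)
        a = kfold_auroc(records, k=5, seed=42)
        b = kfold_auroc(records, k=5, seed=42)
        assert a == b

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(16)
        records = simulated_records(60, seed=16)
        aucs = []
        for _ in range(20):
            shuffled = records.copy()
            shuffled["label"] = rng.permutation(records["label"].to_numpy())
            aucs.append(kfold_auroc(shuffled, k=5, seed=1))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.07)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_auroc(simulated_records(8, seed=17), k=9)

    def test_stratified_folds_partition_all_indices(self):
        y = np.repeat([True, False], [14, 7])
        folds = stratified_folds(y, 5, seed=3)
        combined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(combined, np.arange(21))


class TestLasso:
    def test_vanishing_penalty_reproduces_mle(self):
        from evscore.tr_model import _fit_logistic, _l1_fit

        records = simulated_records(200, seed=18)
        X = records[["post_score", "delta_score"]].to_numpy()
        y = (records["label"] == "viable").to_numpy()
        X_std = (X - X.mean(axis=0)) / X.std(axis=0)
        mle, _ = _fit_logistic(X_std, y)
        l1 = _l1_fit(X_std, y, lam=1e-8)
        np.testing.assert_allclose(l1, mle, atol=1e-3)

    def test_infinite_penalty_gives_chance_auroc(self):
        from evscore.tr_model import _l1_fit

        records = simulated_records(100, seed=19)
        X = records[["post_score", "delta_score"]].to_numpy()
        y = (records["label"] == "viable").to_numpy()
        X_std = (X - X.mean(axis=0)) / X.std(axis=0)
        params = _l1_fit(X_std, y, lam=1e3)
        np.testing.assert_allclose(params[1:], 0.0, atol=1e-8)

    def test_deterministic_and_informative(self):
        records = simulated_records(80, seed=20)
        a1, lam1 = lasso_auroc(records, seed=5)
        a2, lam2 = lasso_auroc(records, seed=5)
        assert (a1, lam1) == (a2, lam2)
        assert a1 > 0.6

    def test_zero_variance_predictor_rejected(self):
        records = make_records([1.0] * 8, [0.1, 0.2] * 4, [1, 0] * 4)
        with pytest.raises(ValueError, match="variance"):
            lasso_auroc(records)


def test_cv_auroc_not_above_resubstitution_on_average():
    gaps = []
    for seed in range(5):
        records = simulated_records(60, seed=100 + seed)
        m = fit_tr(records)
        X = records[["post_score", "delta_score"]].to_numpy()
        y = (records["label"] == "viable").to_numpy()
        lp = m.intercept + X @ np.array([m.beta_post, m.beta_delta])
        gaps.append(auroc(lp, y) - kfold_auroc(records, k=10, seed=seed))
    assert np.mean(gaps) >= -0.01
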