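"""Multinomial regression: likelihood optimum, softmax inversion, AIC."""

import numpy as np
import pytest

from parkmlr import CLASS_ORDER, fit_multinomial, predict_probabilities
from parkmlr.mlr import MultinomialFit
from parkmlr.ssm import SubjectScores


def make_scores(values, labels):
    values = np.asarray(values, dtype=float)
    return SubjectScores(
        scores=values,
        component_indices=tuple(range(1, values.shape[1] + 1)),
        subject_ids=[f"s{i}" for i in range(values.shape[0])],
        labels=list(labels),
    )


def softmax_cohort(rng, n_per_class=10, n_components=2, coef_scale=1.0):
    """Labels drawn from a softmax over random scores: overlapping classes."""
    n = 4 * n_per_class
    x = rng.normal(size=(n, n_components))
    b = coef_scale * rng.normal(size=(n_components + 1, 3))
    eta = np.column_stack([np.ones(n), x]) @ b
    eta = np.column_stack([eta, np.zeros(n)])
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    labels = [CLASS_ORDER[rng.choice(4, p=row)] for row in p]
    # softmax sampling may miss a class at tiny n; force presence
    for i, c in enumerate(CLASS_ORDER):
        labels[i] = c
    return make_scores(x, labels)


class TestFit:
    def test_no_signal_gives_flat_probabilities(self, rng):
        # scores independent of labels, balanced classes: intercept-only limit
        labels = [c for c in CLASS_ORDER for _ in range(60)]
        scores = make_scores(rng.normal(size=(240, 1)), labels)
        fit = fit_multinomial(scores, labels)
        assert np.abs(fit.coefficients[1:, :]).max() < 0.3
        probs = predict_probabilities(fit, scores).to_numpy()
        assert np.abs(probs - 0.25).max() < 0.1

    def test_missing_class_rejected(self, rng):
        labels = ["PD"] * 5 + ["MSA"] * 5 + ["PSP"] * 5
        scores = make_scores(rng.normal(size=(15, 2)), labels)
        with pytest.raises(ValueError, match="UD"):
            fit_multinomial(scores, labels)

    def test_constant_column_rejected(self):
        labels = [c for c in CLASS_ORDER for _ in range(3)]
        scores = make_scores(np.ones((12, 1)), labels)
        with pytest.raises(ValueError, match="constant"):
            fit_multinomial(scores, labels)

    def test_parameter_count(self, rng):
        scores = softmax_cohort(rng, n_per_class=20, n_components=1)
        fit = fit_multinomial(scores, scores.labels)
        assert fit.n_parameters == 6

    def test_matches_reference_implementation(self, rng):
        """Coefficients and log-likelihood agree with statsmodels MNLogit."""
        import statsmodels.api as sm

        scores = softmax_cohort(rng, n_per_class=10, n_components=3)
        fit = fit_multinomial(scores, scores.labels)
        y = np.array([CLASS_ORDER.index(lab) for lab in scores.labels])
        y = (y + 1) % 4  # UD -> code 0 so statsmodels uses it as reference
        res = sm.MNLogit(y, sm.add_constant(scores.scores)).fit(disp=0, tol=1e-10)
        ref = res.params.to_numpy() if hasattr(res.params, "to_numpy") else np.asarray(res.params)
        np.testing.assert_allclose(fit.coefficients, ref, atol=1e-4)
        assert fit.log_likelihood == pytest.approx(res.llf, abs=1e-6)

    def test_separation_flagged_not_fatal(self):
        labels = [c for c in CLASS_ORDER for _ in range(5)]
        x = np.zeros((20, 2))
        x[:5] = (3, 0)
        x[5:10] = (-3, 0)
        x[10:15] = (0, 3)
        scores = make_scores(x + np.random.default_rng(0).normal(scale=0.01, size=x.shape), labels)
        with pytest.warns(UserWarning, match="separat"):
            fit = fit_multinomial(scores, labels)
        assert fit.separation_flag
        probs = predict_probabilities(fit, scores).to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)

    def test_likelihood_at_least_intercept_only(self, rng):
        scores = softmax_cohort(rng, n_per_class=8, n_components=2)
        full = fit_multinomial(scores, scores.labels)
        null_scores = SubjectScores(
            np.zeros((len(scores.labels), 0)), (), scores.subject_ids, scores.labels
        )
        null = fit_multinomial(null_scores, scores.labels)
        assert full.log_likelihood >= null.log_likelihood - 1e-10


class TestPredict:
    def test_zero_coefficients_give_quarter_each(self, rng):
        fit = MultinomialFit(np.zeros((3, 3)), (1, 2), 0.0, True)
        scores = make_scores(rng.normal(size=(5, 2)), ["PD"] * 5)
        probs = predict_probabilities(fit, scores).to_numpy()
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_closed_form_softmax(self):
        # eta = (ln 2, 0, 0) -> p = (2/5, 1/5, 1/5, 1/5)
        coef = np.zeros((1, 3))
        coef[0, 0] = np.log(2.0)
        fit = MultinomialFit(coef, (), 0.0, True)
        scores = make_scores(np.zeros((1, 0)), ["PD"])
        probs = predict_probabilities(fit, scores).to_numpy()[0]
        np.testing.assert_allclose(probs, [0.4, 0.2, 0.2, 0.2], atol=1e-12)

    def test_component_mismatch_rejected(self, rng):
        fit = MultinomialFit(np.zeros((3, 3)), (1, 2), 0.0, True)
        scores = SubjectScores(rng.normal(size=(2, 2)), (1, 3), ["a", "b"], ["PD", "PD"])
        with pytest.raises(ValueError, match="components"):
            predict_probabilities(fit, scores)

    def test_probabilities_sum_to_one(self, rng):
        scores = softmax_cohort(rng, n_per_class=6)
        fit = fit_multinomial(scores, scores.labels)
        probs = predict_probabilities(fit, scores).to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)

    def test_score_shift_changes_only_intercepts(self, rng):
        scores = softmax_cohort(rng, n_per_class=10, n_components=2)
        fit1 = fit_multinomial(scores, scores.labels)
        shifted = make_scores(scores.scores + np.array([5.0, 0.0]), scores.labels)
        fit2 = fit_multinomial(shifted, scores.labels)
        np.testing.assert_allclose(fit1.coefficients[1:], fit2.coefficients[1:], atol=1e-6)
        p1 = predict_probabilities(fit1, scores).to_numpy()
        p2 = predict_probabilities(fit2, shifted).to_numpy()
        np.testing.assert_allclose(p1, p2, atol=1e-8)


class TestAIC:
    def test_formula(self):
        fit = MultinomialFit(np.zeros((2, 3)), (1,), 0.0, True)
        assert fit.n_parameters == 6
        assert fit.aic == 12.0

    def test_noise_component_penalized(self, rng):
        """Adding a pure-noise component never lowers lnL and costs +6 AIC."""
        scores = softmax_cohort(rng, n_per_class=10, n_components=1)
        base = fit_multinomial(scores, scores.labels)
        widened = SubjectScores(
            np.column_stack([scores.scores, rng.normal(size=len(scores.labels))]),
            (1, 2),
            scores.subject_ids,
            scores.labels,
        )
        wide = fit_multinomial(widened, scores.labels)
        assert wide.log_likelihood >= base.log_likelihood - 1e-8
        assert wide.n_parameters == base.n_parameters + 3
        # AIC penalty is +6 per component; lnL gain from noise is small
        assert wide.aic >= base.aic - 2 * (wide.log_likelihood - base.log_likelihood)
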