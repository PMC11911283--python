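"""Multinomial logistic regression on principal-component scores.

The class label (PD, MSA, PSP, or the constructed UD reference) is
regressed on the selected subject scores. With UD as the reference
category the model is three log-odds equations

    ln p(c) / p(UD) = B_0c + sum_k B_kc * s_k,   c in {PD, MSA, PSP},

inverted by the softmax; the four predicted probabilities sum to one.
Fitting is full Newton on the stacked multinomial likelihood with
step-halving — the exact Hessian is cheap because at most a handful of
components are ever selected. A tiny L2 ridge keeps the optimum finite
under complete separation, which clean cohorts can and do produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ssm import SubjectScores

__all__ = ["MultinomialFit", "fit", "predict", "aic", "CLASS_ORDER"]

#: Fixed class order everywhere: three diseases then the UD reference.
CLASS_ORDER = ("PD", "MSA", "PSP", "UD")

#: L2 ridge on the slope coefficients (intercepts stay unpenalized, so
#: shifting a score column moves only intercepts); keeps separated fits
#: finite with negligible bias elsewhere.
RIDGE = 1e-8

_MAX_ITER = 200
# formally "gradient norm < 1e-8"; run tighter so downstream identities
# (shift invariance, reference-fitter agreement) hold to their tolerances
_GRAD_TOL = 1e-10
#: In-sample log-likelihood this close to its supremum 0 means every subject
#: is predicted (almost) perfectly: complete or quasi-complete separation.
_SEPARATION_LL = -1e-2


@dataclass
class MultinomialFit:
    """Fitted coefficients and fit statistics of the multinomial model.

    ``coefficients`` is (P+1) x 3: the intercept row followed by one row
    per selected component, one column per non-reference class in
    CLASS_ORDER. ``log_likelihood`` is the unpenalized value at the
    optimum; ``aic = 2 * n_parameters - 2 * log_likelihood``.
    """

    coefficients: np.ndarray
    component_indices: tuple[int, ...]
    log_likelihood: float
    converged: bool
    separation_flag: bool = False
    ridge: float = RIDGE

    @property
    def n_parameters(self) -> int:
        return 3 * (len(self.component_indices) + 1)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_parameters - 2.0 * self.log_likelihood


def _design(scores: SubjectScores) -> np.ndarray:
    n = scores.scores.shape[0]
    return np.column_stack([np.ones(n), scores.scores])


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    """Unpenalized multinomial log-likelihood; eta is (n, 3), UD eta = 0."""
    eta_full = np.column_stack([eta, np.zeros(eta.shape[0])])
    m = eta_full.max(axis=1)
    lse = m + np.log(np.exp(eta_full - m[:, None]).sum(axis=1))
    picked = eta_full[np.arange(eta.shape[0]), y]
    return float((picked - lse).sum())


def _probabilities(eta: np.ndarray) -> np.ndarray:
    """Softmax over (PD, MSA, PSP, UD) with the reference predictor at 0."""
    eta_full = np.column_stack([eta, np.zeros(eta.shape[0])])
    eta_full -= eta_full.max(axis=1, keepdims=True)
    e = np.exp(eta_full)
    return e / e.sum(axis=1, keepdims=True)


def fit(scores: SubjectScores, labels: list[str], ridge: float = RIDGE) -> MultinomialFit:
    """Maximum-likelihood fit of class on scores with UD as reference.

    All four classes must be present. Newton iterations with step-halving
    run until the penalized gradient norm drops below 1e-8 (or 200
    iterations); complete separation is flagged, not fatal, thanks to the
    ridge.
    """
    present = set(labels)
    if not set(CLASS_ORDER) <= present:
        missing = sorted(set(CLASS_ORDER) - present)
        raise ValueError(f"all four classes must be present; missing {missing}")
    unknown = present - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")

    x = _design(scores)
    n, p1 = x.shape
    if n != len(labels):
        raise ValueError("scores and labels length mismatch")
    col_sd = x[:, 1:].std(axis=0) if p1 > 1 else np.array([1.0])
    if p1 > 1 and np.any(col_sd == 0):
        raise ValueError("constant score column: model is unidentifiable")
    y = np.array([CLASS_ORDER.index(lab) for lab in labels])
    y_ind = np.zeros((n, 3))
    for c in range(3):
        y_ind[y == c, c] = 1.0

    pen_mask = np.ones((p1, 1))
    pen_mask[0, 0] = 0.0  # intercept unpenalized

    def _penalty(b):
        return 0.5 * ridge * ((pen_mask * b) ** 2).sum()

    beta = np.zeros((p1, 3))
    eta = x @ beta
    ll_pen = _log_likelihood(eta, y) - _penalty(beta)
    converged = False
    for _ in range(_MAX_ITER):
        prob = _probabilities(eta)[:, :3]
        grad = x.T @ (y_ind - prob) - ridge * pen_mask * beta  # (p1, 3)
        if np.abs(grad).max() < _GRAD_TOL:
            converged = True
            break
        # exact Hessian of the stacked likelihood, 3*p1 x 3*p1
        hess = np.zeros((3 * p1, 3 * p1))
        for c in range(3):
            for d in range(3):
                w = prob[:, c] * ((1.0 if c == d else 0.0) - prob[:, d])
                block = -(x.T * w) @ x
                if c == d:
                    block -= ridge * np.diag(pen_mask[:, 0])
                hess[c * p1:(c + 1) * p1, d * p1:(d + 1) * p1] = block
        step = np.linalg.solve(hess, -grad.T.ravel()).reshape(3, p1).T
        # step-halving keeps the penalized likelihood monotone
        scale = 1.0
        for _half in range(40):
            cand = beta + scale * step
            eta_c = x @ cand
            ll_c = _log_likelihood(eta_c, y) - _penalty(cand)
            if ll_c >= ll_pen - 1e-13:
                beta, eta, ll_pen = cand, eta_c, ll_c
                break
            scale *= 0.5
        else:
            break

    log_likelihood = _log_likelihood(eta, y)
    separated = bool(log_likelihood > _SEPARATION_LL)
    if separated:
        warnings.warn(
            "in-sample fit is (near-)perfect: classes are separated and the "
            "coefficients are capped only by the L2 ridge",
            stacklevel=2,
        )
    return MultinomialFit(
        coefficients=beta,
        component_indices=scores.component_indices,
        log_likelihood=log_likelihood,
        converged=converged,
        separation_flag=separated,
        ridge=ridge,
    )


def predict(fit_: MultinomialFit, scores: SubjectScores) -> pd.DataFrame:
    """Predicted class probabilities (columns PD, MSA, PSP, UD; rows subjects).

    The scores must carry exactly the components the model was fitted on.
    Each row sums to one.
    """
    if scores.component_indices != fit_.component_indices:
        raise ValueError(
            f"scores carry components {scores.component_indices} but the model "
            f"was fitted on {fit_.component_indices}"
        )
    eta = _design(scores) @ fit_.coefficients
    prob = _probabilities(eta)
    return pd.DataFrame(prob, columns=list(CLASS_ORDER), index=scores.subject_ids)


def aic(fit_: MultinomialFit) -> float:
    """Akaike information criterion, 2k - 2 lnL with k = 3 (P+1)."""
    return fit_.aic
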