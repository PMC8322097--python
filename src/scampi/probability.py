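"""Logistic regression mapping discriminant projections to class probabilities.

The single covariate is the scalar FLD projection; the fitted model gives each
image a probability of belonging to the second (high-projecting) class.
Fitting is Newton / iteratively reweighted least squares on the Bernoulli
log-likelihood; complete separation is detected and flagged rather than
silently regularised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Probability clamp applied when the data are separated.
PROB_CLAMP = 1e-12
#: |slope| beyond which a monotonically improving fit is declared separated.
SEPARATION_SLOPE = 1e3


@dataclass(frozen=True)
class LogisticModel:
    """Binary logistic model ``P(y=1|x) = 1 / (1 + exp(-(a + b x)))``."""

    intercept: float
    slope: float
    converged: bool
    n_iter: int
    log_likelihood: float
    separated: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "slope": self.slope,
                    "converged": self.converged,
                    "n_iter": self.n_iter,
                    "log_likelihood": self.log_likelihood,
                    "separated": self.separated,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "LogisticModel":
        return cls(**json.loads(Path(path).read_text()))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def logistic_fit(
    projections: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by Newton's method (IRLS).

    Converges when the maximum absolute score drops below ``score_tol`` or the
    relative log-likelihood change falls below ``ll_tol``.  Complete or
    quasi-complete separation — non-overlapping class supports on the single
    covariate, or a monotonically improving likelihood with ``|slope|``
    diverging past ``SEPARATION_SLOPE`` — is reported via ``separated=True``
    (predicted probabilities then saturate and are clamped to
    ``[1e-12, 1 - 1e-12]`` by :func:`logistic_predict`).
    """
    x = np.asarray(projections, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("projections and labels must have equal length")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError(
            f"labels must contain both classes 0 and 1, got {classes.tolist()}"
        )

    # with a single covariate, complete/quasi-complete separation is exactly
    # the absence of overlap between the class supports
    x0, x1 = x[y == 0.0], x[y == 1.0]
    separated = bool(x1.min() >= x0.max() or x0.min() >= x1.max())

    X = np.column_stack([np.ones_like(x), x])
    theta = np.zeros(2)
    ll = _log_likelihood(y, _sigmoid(X @ theta))
    ll_monotone = True
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(X @ theta)
        score = X.T @ (y - p)
        w = p * (1.0 - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            break
        theta = theta + step
        ll_new = _log_likelihood(y, _sigmoid(X @ theta))
        if ll_new < ll - 1e-12:
            ll_monotone = False
        if abs(theta[1]) > SEPARATION_SLOPE and ll_monotone:
            ll = ll_new
            break
        if np.max(np.abs(score)) < score_tol:
            ll = ll_new
            converged = True
            break
        if abs(ll_new - ll) < ll_tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    separated = separated or bool(abs(theta[1]) > SEPARATION_SLOPE and ll_monotone)
    return LogisticModel(
        intercept=float(theta[0]),
        slope=float(theta[1]),
        converged=converged,
        n_iter=it,
        log_likelihood=ll,
        separated=separated,
    )


def logistic_predict(model: LogisticModel, projection) -> np.ndarray | float:
    """Predicted probability of class 1 at the given projection(s).

    Strictly increasing in the projection when ``slope > 0``; clamped away
    from exactly 0/1 when the model was fitted on separated data.
    """
    x = np.asarray(projection, dtype=np.float64)
    p = _sigmoid(model.intercept + model.slope * x)
    if model.separated:
        p = np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    if np.ndim(projection) == 0:
        return float(p)
    return p
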