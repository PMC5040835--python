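"""Logistic link model: posterior, likelihood, MLE fit, percentile scores.

Link prediction is cast as two-class classification.  For a pair with
feature vector phi and weight vector w the posterior link probability is
the logistic function of w.phi (no intercept by default — the feature
channels are already on a common [0, 1] scale).  Weights are fitted by
maximising the log likelihood

    sum_i [ x_i w.phi_i - ln(1 + exp(w.phi_i)) ]  -  ridge * ||w||^2 / 2,

a concave problem with a unique optimum whenever ridge > 0.  The
unpenalised likelihood has no maximiser on linearly separable data; that
condition is detected and reported rather than silently truncated.

Because a fixed probability cutoff is hard to interpret across networks,
the final score of a pair is the percentile of its posterior among all
scored pairs: q_i = |{j : p_i >= p_j}| / n.  Ties share the higher
percentile and the top-ranked pair always scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .features import FeatureTable, PairIndex

__all__ = [
    "WeightVector",
    "TrainingSet",
    "ScoreTable",
    "FitDivergedError",
    "posterior",
    "log_likelihood",
    "fit_weights",
    "final_scores",
    "score_pairs",
    "sample_negative_pairs",
    "write_model",
    "read_model",
]

DEFAULT_RIDGE = 1e-4


class FitDivergedError(RuntimeError):
    """The likelihood has no finite maximiser (separable data, ridge = 0)."""


@dataclass
class WeightVector:
    """Fitted (or true) weights, one per feature column."""

    weights: np.ndarray
    ridge: float = DEFAULT_RIDGE
    include_bias: bool = False
    feature_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.ridge < 0:
            raise ValueError("ridge must be nonnegative")
        if self.feature_labels is not None:
            expected = len(self.feature_labels) + (1 if self.include_bias else 0)
            if len(self.weights) != expected:
                raise ValueError("weight length does not match feature labels")


@dataclass
class TrainingSet:
    """Feature table plus binary labels, one per pair."""

    features: FeatureTable
    labels: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.labels, dtype=float).ravel()
        if len(y) != len(self.features.pair_index):
            raise ValueError("label count does not match pair count")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("labels must be 0/1")
        self.labels = y


@dataclass
class ScoreTable:
    """Posterior probabilities and percentile final scores per pair."""

    pair_index: PairIndex
    posterior: np.ndarray
    final: np.ndarray

    def __post_init__(self) -> None:
        self.posterior = np.asarray(self.posterior, dtype=float).ravel()
        self.final = np.asarray(self.final, dtype=float).ravel()
        n = len(self.pair_index)
        if len(self.posterior) != n or len(self.final) != n:
            raise ValueError("score lengths do not match pair index")


def _design(phi: np.ndarray, include_bias: bool) -> np.ndarray:
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if include_bias:
        phi = np.hstack([phi, np.ones((phi.shape[0], 1))])
    return phi


def posterior(phi: np.ndarray, w: WeightVector) -> np.ndarray:
    """Logistic posterior P(link | phi, w); overflow-safe for any w.phi."""
    x = _design(phi, w.include_bias)
    if x.shape[1] != len(w.weights):
        raise ValueError(
            f"feature length {x.shape[1]} does not match weights {len(w.weights)}"
        )
    p = expit(x @ w.weights)
    return p if p.size > 1 else float(p[0])


def log_likelihood(w: WeightVector, ts: TrainingSet) -> float:
    """Penalised Bernoulli log likelihood of the training labels."""
    x = _design(ts.features.values, w.include_bias)
    if x.shape[1] != len(w.weights):
        raise ValueError("weight length does not match feature count")
    z = x @ w.weights
    ll = float(np.sum(ts.labels * z - np.logaddexp(0.0, z)))
    if w.ridge > 0:
        ll -= 0.5 * w.ridge * float(w.weights @ w.weights)
    return ll


def _neg_ll_and_grad(beta: np.ndarray, x: np.ndarray, y: np.ndarray,
                     ridge: float) -> tuple[float, np.ndarray]:
    z = x @ beta
    nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
    grad = x.T @ (expit(z) - y)
    if ridge > 0:
        nll += 0.5 * ridge * float(beta @ beta)
        grad = grad + ridge * beta
    return nll, grad


def fit_weights(
    ts: TrainingSet,
    ridge: float = DEFAULT_RIDGE,
    tol: float = 1e-6,
    max_iter: int = 500,
    init: WeightVector | None = None,
    include_bias: bool = False,
) -> WeightVector:
    """Maximum-likelihood weights by deterministic convex optimisation.

    Starts from zero (or ``init``) and runs L-BFGS on the penalised
    negative log likelihood with its analytic gradient.  The gradient norm
    at the solution is verified against ``tol``; failure to reach it — the
    signature of separable data at ridge = 0 — raises
    :class:`FitDivergedError`.
    """
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    y = ts.labels
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")
    x = _design(ts.features.values, include_bias)
    d = x.shape[1]
    beta0 = np.zeros(d) if init is None else np.asarray(init.weights, dtype=float)
    if len(beta0) != d:
        raise ValueError("init weight length does not match feature count")

    beta = beta0.copy()
    nll, grad = _neg_ll_and_grad(beta, x, y, ridge)
    for _ in range(max_iter):
        if float(np.max(np.abs(grad))) <= tol:
            break
        z = x @ beta
        p = expit(z)
        s = np.maximum(p * (1.0 - p), 1e-12)
        hess = (x * s[:, None]).T @ x
        if ridge > 0:
            hess[np.diag_indices(d)] += ridge
        else:
            # tiny Levenberg damping keeps the solve well-posed; the
            # gradient check below still decides convergence
            hess[np.diag_indices(d)] += 1e-10
        step = np.linalg.solve(hess, grad)
        # backtracking line search on the penalised negative log likelihood
        t = 1.0
        for _ in range(60):
            cand = beta - t * step
            cand_nll, cand_grad = _neg_ll_and_grad(cand, x, y, ridge)
            if cand_nll <= nll - 1e-4 * t * float(grad @ step):
                break
            t *= 0.5
        beta, nll, grad = cand, cand_nll, cand_grad
    grad_norm = float(np.max(np.abs(grad)))
    if grad_norm > tol:
        raise FitDivergedError(
            f"no finite likelihood maximiser found (gradient norm {grad_norm:.3g} "
            f"> tol {tol:.3g}); data may be separable — use ridge > 0"
        )
    if ridge == 0.0:
        # if the fitted direction separates the classes with a strict
        # margin, scaling it up always increases the likelihood: the
        # unpenalised MLE does not exist even though the gradient vanishes
        margins = (2.0 * y - 1.0) * (x @ beta)
        if margins.size and margins.min() > 0.0:
            raise FitDivergedError(
                "training data is linearly separable; the unpenalised "
                "likelihood has no maximiser — use ridge > 0"
            )
    return WeightVector(beta, ridge=ridge, include_bias=include_bias,
                        feature_labels=ts.features.columns)


def final_scores(posteriors: np.ndarray) -> np.ndarray:
    """Percentile final score: fraction of pairs scoring at or below each pair.

    Non-strict comparison, self included, so ties share the higher
    percentile, every score is at least 1/n, and the maximum is exactly 1.
    """
    p = np.asarray(posteriors, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no posteriors to rank")
    return rankdata(p, method="max") / p.size


def score_pairs(table: FeatureTable, w: WeightVector) -> ScoreTable:
    """Posterior and percentile score for every pair in the table."""
    p = np.atleast_1d(posterior(table.values, w))
    return ScoreTable(table.pair_index, p, final_scores(p))


def sample_negative_pairs(
    w_mg: np.ndarray,
    positives: PairIndex,
    n_samples: int,
    rng: np.random.Generator,
    mirna_rows: np.ndarray | None = None,
) -> PairIndex:
    """Uniform sample of unknown (weight-0, non-positive) pairs.

    ``mirna_rows`` restricts candidates to a subset of miRNA rows.  If
    fewer unknown pairs exist than requested, all of them are returned.
    """
    w_mg = np.asarray(w_mg)
    known = set(positives.pairs)
    rows, cols = np.nonzero(w_mg == 0)
    if mirna_rows is not None:
        keep = np.isin(rows, np.asarray(mirna_rows))
        rows, cols = rows[keep], cols[keep]
    candidates = [(int(i), int(j)) for i, j in zip(rows, cols)
                  if (int(i), int(j)) not in known]
    if n_samples >= len(candidates):
        return PairIndex(tuple(candidates))
    picked = rng.choice(len(candidates), size=n_samples, replace=False)
    return PairIndex(tuple(candidates[k] for k in sorted(picked)))


def write_model(w: WeightVector, path: str) -> None:
    """Plain-text model file: header lines plus one label/weight row each."""
    labels = w.feature_labels
    if labels is None:
        labels = tuple(f"f{i}" for i in range(len(w.weights)))
        if w.include_bias:
            labels = labels[:-1]
    with open(path, "w") as fh:
        fh.write(f"#ridge\t{w.ridge!r}\n")
        fh.write(f"#include_bias\t{int(w.include_bias)}\n")
        rows = list(labels) + (["<bias>"] if w.include_bias else [])
        for label, weight in zip(rows, w.weights):
            fh.write(f"{label}\t{weight:.17g}\n")


def read_model(path: str) -> WeightVector:
    ridge = DEFAULT_RIDGE
    include_bias = False
    labels: list[str] = []
    weights: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, value = line.split("\t")
            if key == "#ridge":
                ridge = float(value)
            elif key == "#include_bias":
                include_bias = bool(int(value))
            else:
                labels.append(key)
                weights.append(float(value))
    if include_bias:
        labels = labels[:-1]
    return WeightVector(np.array(weights), ridge=ridge, include_bias=include_bias,
                        feature_labels=tuple(labels))
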