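"""Neighborhood component analysis weights and iterative size selection.

NCA learns one nonnegative weight per feature by maximising the
leave-one-out stochastic nearest-neighbour objective

    F(w) = sum_i sum_{j in class(i), j != i} p_ij  -  lambda * sum_l w_l^2,
    p_ij = exp(-d_ij) / sum_{j' != i} exp(-d_ij'),
    d_ij = sum_l w_l^2 |x_il - x_jl|,

i.e. the feature-selecting (diagonal) NCA variant with a weighted L1
distance, matching the pipeline's 1-NN classifier, plus a ridge
penalty. Optimisation is deterministic full-batch gradient ascent from
an all-ones start with backtracking step halving.

The iterative selector (INCA) ranks features by descending weight and
sweeps prefix sizes over an iteration range (default [100, 512],
clipped to the feature count), scoring each prefix by k-fold
cross-validated misclassification; the loss-minimising prefix wins,
ties going to the smaller size.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .classify import ClassifierSpec, crossval_predict

__all__ = ["INCAResult", "nca_weights", "inca_select"]

DEFAULT_SIZE_RANGE = (100, 512)


@dataclasses.dataclass
class INCAResult:
    """Feature ranking, loss-versus-size curve and the selected subset."""

    ranking: np.ndarray  # all features, by descending NCA weight
    sizes: np.ndarray  # evaluated subset sizes
    loss_curve: np.ndarray  # loss per evaluated size
    selected_size: int
    selected_indices: np.ndarray  # = ranking[:selected_size]
    weights: np.ndarray

    @property
    def selected_loss(self) -> float:
        return float(self.loss_curve.min())


def _objective_and_grad(w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float, sigma: float):
    """F(w) and dF/dw for the weighted-L1 diagonal NCA objective."""
    n = X.shape[0]
    w2 = w * w
    obj = 0.0
    grad = np.zeros_like(w)
    for i in range(n):
        A = np.abs(X - X[i])  # (n, p)
        d = (A @ w2) / sigma
        d[i] = np.inf  # exclude self
        logp = -d - _logsumexp(-d)
        p = np.exp(logp)
        same = y == y[i]
        same[i] = False
        p_i = p[same].sum()
        obj += p_i
        # d p_i / d w_l = (2 w_l / sigma) ( p_i sum_j p_ij A_jl - sum_{j in class} p_ij A_jl )
        coeff = p_i * p - np.where(same, p, 0.0)
        grad += (2.0 / sigma) * w * (coeff @ A)
    obj -= lam * np.dot(w, w)
    grad -= 2.0 * lam * w
    return obj, grad


def _auto_sigma(X: np.ndarray) -> float:
    """Kernel length-scale: mean pairwise L1 distance at unit weights."""
    n = X.shape[0]
    total = 0.0
    for i in range(n):
        total += np.abs(X - X[i]).sum()
    mean = total / (n * (n - 1))
    return mean if mean > 0 else 1.0


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v[np.isfinite(v)])
    return float(m + np.log(np.exp(v[np.isfinite(v)] - m).sum()))


def nca_weights(
    X,
    y,
    lam: float | None = None,
    n_iter: int = 100,
    initial_step: float = 1.0,
    sigma: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-feature NCA weights (nonnegative; larger = more informative).

    ``lam`` defaults to 1/n. ``sigma`` is the soft-neighbour kernel
    length-scale; by default it is set to the mean pairwise L1 distance
    at unit weights, which keeps the softmax responsive regardless of
    the feature count. The optimiser is deterministic (all-ones
    initialisation); ``seed`` is accepted for interface uniformity and
    reserved for stochastic variants.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two observations")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    if lam is None:
        lam = 1.0 / n
    if sigma is None:
        sigma = _auto_sigma(X)
    w = np.ones(p)
    step = initial_step
    obj, grad = _objective_and_grad(w, X, y, lam, sigma)
    for _ in range(n_iter):
        gnorm = np.max(np.abs(grad))
        if gnorm == 0:
            break
        # backtracking: shrink until the objective improves
        for _ in range(20):
            w_new = w + step * grad / gnorm
            obj_new, grad_new = _objective_and_grad(w_new, X, y, lam, sigma)
            if obj_new > obj:
                break
            step *= 0.5
        else:
            break
        w, obj, grad = w_new, obj_new, grad_new
        step *= 1.1
    return np.abs(w)


def inca_select(
    X,
    y,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    classifier: ClassifierSpec | str = "kNN",
    folds: int = 10,
    seed: int = 0,
    stride: int = 1,
    nca_lam: float | None = None,
    nca_iter: int = 100,
    nca_sigma: float | None = None,
) -> INCAResult:
    """Sweep prefix sizes of the NCA ranking and keep the loss minimiser.

    The size range is clipped to [1, p]; ``stride`` (default 1: every
    integer size) trades resolution for speed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    lo, hi = size_range
    if lo > hi:
        raise ValueError("size_range lower bound exceeds upper bound")
    hi = min(hi, p)
    lo = max(1, lo)
    if lo > hi:  # fewer features than the range: sweep everything
        lo = 1
    sizes = np.arange(lo, hi + 1, stride)
    if sizes.size == 0:
        raise ValueError("empty evaluated size range")
    if isinstance(classifier, str):
        classifier = ClassifierSpec(classifier)
    weights = nca_weights(X, y, lam=nca_lam, n_iter=nca_iter, sigma=nca_sigma, seed=seed)
    ranking = np.argsort(-weights, kind="stable")
    loss_curve = np.empty(sizes.size)
    for i, s in enumerate(sizes):
        pred = crossval_predict(X[:, ranking[:s]], y, classifier, folds=folds, seed=seed)
        loss_curve[i] = float(np.mean(pred != y))
    best = int(np.argmin(loss_curve))  # first minimum -> smallest size on ties
    selected_size = int(sizes[best])
    return INCAResult(
        ranking=ranking,
        sizes=sizes,
        loss_curve=loss_curve,
        selected_size=selected_size,
        selected_indices=ranking[:selected_size],
        weights=weights,
    )
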