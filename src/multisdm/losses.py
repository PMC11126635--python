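"""Training cost functions for single-positive multi-label records.

Two losses are provided. The cross-entropy loss (CEL) treats each record
as a multiclass example with the observed taxon as the only class — a
strictly proper scoring rule whose minimum is at the true conditional
observation probabilities, but which implicitly assumes all unobserved
taxa absent. The lambda-NDCG ranking loss instead asks only that the
observed taxon be ranked as relevant as possible among all taxa:

    l(s, y) = -sum_i sum_j log2 c_{pi_i, pi_j},
    c_{pi_i, pi_j} = sigmoid(s_{pi_i} - s_{pi_j}) ** (G_{pi_i} / D_i),

with pi the permutation sorting scores descending, discounts
D_i = log2(1 + i), gains G_{pi_i} = (2^{y_{pi_i}} - 1) / maxDCG, and the
double sum running over the top-n ranks. For single-positive relevance
(one-hot y) maxDCG = 1 and only the row at the observed item's rank
survives, so the loss collapses to

    l(s, y) = -(1 / D_{rank(o)}) * sum_{j=1..n} log2 sigmoid(s_o - s_{pi_j}).

Gradients follow the lambda-loss construction: ranks and discounts are
treated as constants of the current ordering and gradients flow only
through the score differences inside the sigmoids.

Conventions (configurable where noted): descending sort with ties broken
by taxon index (stable sort); the i = j self-pair (sigmoid(0) = 0.5) is
included, as the double sum's indices run over all pairs; ranking terms
use log2, the CEL uses the natural log.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cross_entropy_loss",
    "cross_entropy_value_and_grad",
    "lambda_ndcg_loss",
    "lambda_ndcg_value_and_grad",
    "ndcg_loss_reference",
    "softmax",
]

_LN2 = np.log(2.0)


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    s = s - np.max(s, axis=axis, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # log(sigmoid(x)) = -log1p(exp(-x)), numerically safe both tails
    return -np.logaddexp(0.0, -x)


def _as_batch(scores, observed):
    s = np.asarray(scores, dtype=float)
    single = s.ndim == 1
    if single:
        s = s[None, :]
    o = np.atleast_1d(np.asarray(observed, dtype=int))
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if np.any(o < 0) or np.any(o >= s.shape[1]):
        raise ValueError("observed index out of range")
    return s, o, single


def cross_entropy_value_and_grad(scores, observed):
    """Mean CEL over the batch and its gradient w.r.t. the scores."""
    s, o, _ = _as_batch(scores, observed)
    b = len(s)
    p = softmax(s, axis=1)
    logp = s - np.max(s, axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(b), o].mean()
    grad = p.copy()
    grad[np.arange(b), o] -= 1.0
    return float(loss), grad / b


def cross_entropy_loss(scores, observed) -> float:
    """-log softmax(s)[observed], natural log, mean over the batch."""
    return cross_entropy_value_and_grad(scores, observed)[0]


def _descending_order(s: np.ndarray) -> np.ndarray:
    """Stable permutation sorting scores descending, ties by taxon index."""
    return np.argsort(-s, axis=-1, kind="stable")


def lambda_ndcg_value_and_grad(
    scores, observed, n: int | None = None, include_self_pair: bool = True
):
    """Mean single-positive lambda-NDCG loss and its score gradient.

    ``n`` is the highest rank evaluated (the j-sum runs over the top-n
    items of the current ordering); defaults to the full taxon count.
    """
    s, o, _ = _as_batch(scores, observed)
    b, n_taxa = s.shape
    if n is None:
        n = n_taxa
    if not 1 <= n <= n_taxa:
        raise ValueError(f"rank cap n must lie in [1, {n_taxa}]")

    order = _descending_order(s)  # (b, S): order[:, i] = taxon at rank i+1
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_taxa)[None, :], axis=1)
    rank_o = ranks[np.arange(b), o]  # 0-based rank of the observed taxon
    inv_d = 1.0 / np.log2(2.0 + rank_o)  # 1 / log2(1 + rank)

    top = order[:, :n]  # taxa occupying ranks 1..n
    s_o = s[np.arange(b), o]
    diff = s_o[:, None] - np.take_along_axis(s, top, axis=1)
    if not include_self_pair:
        self_mask = top == o[:, None]
        logs = np.where(self_mask, 0.0, _log_sigmoid(diff))
        sig = np.where(self_mask, 1.0, _sigmoid(diff))
    else:
        logs = _log_sigmoid(diff)
        sig = _sigmoid(diff)

    loss = float(np.mean(-inv_d * logs.sum(axis=1) / _LN2))

    # d(-log2 sigmoid(x))/dx = -(1 - sigmoid(x)) / ln 2; ranks detached.
    # Per pair j: dL/ds_{top_j} = +g_j, dL/ds_o -= g_j (self-pairs cancel).
    g = inv_d[:, None] * (1.0 - sig) / _LN2  # (b, n), nonnegative
    if not include_self_pair:
        g = np.where(self_mask, 0.0, g)
    grad = np.zeros_like(s)
    np.add.at(grad, (np.arange(b)[:, None], top), g)
    grad[np.arange(b), o] -= g.sum(axis=1)
    return loss, grad / b


def lambda_ndcg_loss(
    scores, observed, n: int | None = None, include_self_pair: bool = True
) -> float:
    """Single-positive lambda-NDCG loss (mean over the batch)."""
    return lambda_ndcg_value_and_grad(scores, observed, n, include_self_pair)[0]


def ndcg_loss_reference(
    scores, relevance, n: int | None = None, include_self_pair: bool = True
) -> float:
    """Literal double-sum evaluation of the ranking loss (oracle).

    Accepts an arbitrary relevance vector ``y`` (not just one-hot) for a
    single instance; rows with zero gain contribute log2(c) = 0. If no
    item carries relevance (maxDCG = 0) the loss is 0. Non-differentiable
    reference implementation used for testing.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(relevance, dtype=float)
    if s.ndim != 1 or y.shape != s.shape:
        raise ValueError("reference oracle takes one instance at a time")
    n_taxa = len(s)
    if n is None:
        n = n_taxa
    if not 1 <= n <= n_taxa:
        raise ValueError(f"rank cap n must lie in [1, {n_taxa}]")

    order = _descending_order(s)
    d = np.log2(1.0 + np.arange(1, n_taxa + 1))
    ideal = np.sort(y)[::-1]
    max_dcg = np.sum((2.0 ** ideal[:n] - 1.0) / d[:n])
    if max_dcg == 0:
        return 0.0
    gains = (2.0 ** y[order] - 1.0) / max_dcg  # G_{pi_i}

    total = 0.0
    for i in range(n):
        if gains[i] == 0:
            continue
        for j in range(n):
            if not include_self_pair and i == j:
                continue
            x = s[order[i]] - s[order[j]]
            log2_c = (gains[i] / d[i]) * _log_sigmoid(np.array(x)) / _LN2
            total -= float(log2_c)
    return total
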