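"""Weight-diversity prior and comparison regularizers.

The diversity prior biases the RBM weight matrix toward mutually dissimilar
columns by penalizing pairwise squared cosine similarity,
p(W) ~ exp(-lambda * sum_{j != k} cos^2(W_.j, W_.k)).  During MAP learning
with unit-norm columns this reduces to a squared-dot-product penalty whose
gradient is analytic, so the prior adds a simple repulsive term to every
column update — a learning-phase stand-in for lateral inhibition between
neurons with similar receptive fields.

Two comparison regularizers from the sparse-RBM literature are provided in
their standard forms (the originating works give them only by citation
here): an l1/l2 penalty on the population of hidden activation
probabilities ("sparse group"), and a squared deviation of each unit's mean
activation from a low target ("selective").

Sign convention: every ``*_gradient`` function returns the gradient of the
*log prior* (i.e. minus the penalty gradient), the term ADDED to the
likelihood gradient during ascent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

EPS_NORM = 1e-12


@dataclass
class RegularizerGradient:
    """Additive update contribution from a regularizer.

    dW matches W's shape; db (hidden-bias term) is present only for the
    activation-based regularizers; penalty_value is the scalar penalty at
    the current parameters (>= 0).
    """

    dW: np.ndarray
    penalty_value: float
    db: np.ndarray | None = None


def _column_norms(W: np.ndarray, eps_guard: bool) -> np.ndarray:
    norms = np.linalg.norm(W, axis=0)
    if not eps_guard and np.any(norms == 0):
        raise ValueError("zero-norm column with eps guard disabled")
    return np.maximum(norms, EPS_NORM)


def squared_cosine_penalty(
    W: np.ndarray, normalized: bool = True, eps_guard: bool = True
) -> float:
    """Sum over ordered column pairs (j, k), k != j, of cos^2(W_.j, W_.k).

    Symmetric pairs are counted twice, so the value lies in
    [0, Nh*(Nh-1)] — 0 for mutually orthogonal columns, the maximum when all
    columns are parallel.  With ``normalized=False`` the raw squared dot
    products (W_.j'W_.k)^2 are summed instead; the two forms coincide when
    every column has unit norm.
    """
    W = np.asarray(W, dtype=float)
    if normalized:
        W = W / _column_norms(W, eps_guard)
    G = W.T @ W
    np.fill_diagonal(G, 0.0)
    return float((G**2).sum())


def prior_log_density_unnorm(W: np.ndarray, lambda_div: float) -> float:
    """Unnormalized log prior density: -lambda * squared_cosine_penalty(W)."""
    return -lambda_div * squared_cosine_penalty(W)


def diversity_potential(W: np.ndarray, lambda_div: float, C: float = 1.0) -> float:
    """The scalar potential whose exact negative gradient is the diversity
    update term: lambda * [sum over unordered pairs of (W_.j'W_.k)^2
    + C * sum_j (||W_.j|| - 1)^2]."""
    W = np.asarray(W, dtype=float)
    G = W.T @ W
    np.fill_diagonal(G, 0.0)
    norms = np.linalg.norm(W, axis=0)
    return float(lambda_div * (0.5 * (G**2).sum() + C * ((norms - 1) ** 2).sum()))


def diversity_gradient(
    W: np.ndarray, lambda_div: float, C: float = 1.0
) -> RegularizerGradient:
    """Diversity-prior update term for every column j:

        -2*lambda * ( sum_{k != j} (W_.k W_.k') W_.j
                      + C * (||W_.j|| - 1)/||W_.j|| * W_.j ).

    The first part repels column j from every other column in proportion to
    their overlap; the second softly pulls column norms to 1 (it vanishes
    for unit-norm columns, and is moot under hard renormalization).  This is
    the exact gradient of ``-diversity_potential``.
    """
    W = np.asarray(W, dtype=float)
    if lambda_div < 0 or C < 0:
        raise ValueError("lambda_div and C must be >= 0")
    if lambda_div == 0:
        return RegularizerGradient(np.zeros_like(W), 0.0)
    norms = _column_norms(W, eps_guard=True)
    G = W.T @ W
    np.fill_diagonal(G, 0.0)
    repulsion = W @ G  # column j: sum_{k != j} (W_.k' W_.j) W_.k
    norm_pull = ((norms - 1.0) / norms) * W
    dW = -2.0 * lambda_div * (repulsion + C * norm_pull)
    return RegularizerGradient(dW, diversity_potential(W, lambda_div, C))


def sparse_group_gradient(
    W: np.ndarray, b: np.ndarray, batch, weight: float = 0.1
) -> RegularizerGradient:
    """l1/l2 population-sparsity regularizer on hidden activations.

    Penalty = weight * mean over stimuli of ||p(h|v)||_1 / ||p(h|v)||_2,
    minimized at one-hot activation vectors (value 1 for a nonnegative
    vector).  The gradient is chained analytically through the logistic and
    returned with respect to both W and b (negated, log-prior convention).
    """
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    V = np.atleast_2d(np.asarray(getattr(batch, "patches", batch), dtype=float))
    if V.shape[0] == 0:
        raise ValueError("empty batch")
    if weight == 0:
        return RegularizerGradient(np.zeros_like(W), 0.0, np.zeros_like(b))
    L = V.shape[0]
    P = expit(V @ W + b)
    l1 = P.sum(axis=1)
    l2 = np.maximum(np.sqrt((P**2).sum(axis=1)), EPS_NORM)
    penalty = weight * float((l1 / l2).mean())
    # d penalty / dP, including the 1/L of the stimulus mean
    dP = (1.0 / l2[:, None] - (l1 / l2**3)[:, None] * P) / L
    dA = dP * P * (1.0 - P)
    return RegularizerGradient(
        dW=-weight * (V.T @ dA),
        penalty_value=penalty,
        db=-weight * dA.sum(axis=0),
    )


def selective_gradient(
    W: np.ndarray,
    b: np.ndarray,
    batch,
    weight: float = 0.1,
    target_activation: float = 0.02,
) -> RegularizerGradient:
    """Selectivity regularizer suppressing mean activation probabilities.

    Penalty = weight * sum_j (mean_l p(h_j=1|v_l) - target)^2, pushing each
    unit's average activation toward a low target rate.
    """
    if not 0 < target_activation < 1:
        raise ValueError("target_activation must be in (0, 1)")
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    V = np.atleast_2d(np.asarray(getattr(batch, "patches", batch), dtype=float))
    if V.shape[0] == 0:
        raise ValueError("empty batch")
    if weight == 0:
        return RegularizerGradient(np.zeros_like(W), 0.0, np.zeros_like(b))
    L = V.shape[0]
    P = expit(V @ W + b)
    m = P.mean(axis=0)
    penalty = weight * float(((m - target_activation) ** 2).sum())
    dP = (2.0 * (m - target_activation) / L)[None, :] * np.ones_like(P)
    dA = dP * P * (1.0 - P)
    return RegularizerGradient(
        dW=-weight * (V.T @ dA),
        penalty_value=penalty,
        db=-weight * dA.sum(axis=0),
    )
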