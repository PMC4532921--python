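"""Treves-Rolls activation statistics and dead-neuron bookkeeping.

Both measures share one functional form on a nonnegative response vector r:

    TR(r) = 1 - (sum r / N)^2 / (sum r^2 / N),

which is 0 for a constant vector and 1 - 1/N for a one-hot vector.
Applied across stimuli for one neuron it is *selectivity* (lifetime
sparseness); applied across the population for one stimulus it is
*sparsity* (population sparseness).  All statistics are computed on hidden
activation probabilities, never on binary samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rbm import RBMParams, prob_h_given_v

DEFAULT_DEAD_THRESHOLD = 0.1


def activation_matrix(params: RBMParams, patches) -> np.ndarray:
    """(L, Nh) matrix R with R[l, j] = p(h_j = 1 | v^(l))."""
    V = np.atleast_2d(np.asarray(getattr(patches, "patches", patches), dtype=float))
    return prob_h_given_v(params, V)


def _treves_rolls(r: np.ndarray) -> float:
    r = np.asarray(r, dtype=float).ravel()
    s2 = (r**2).mean()
    if s2 == 0:
        # all-zero responses: 0/0 in the definition; treat as maximally
        # non-selective (the unit is dead and counted as such elsewhere)
        return 0.0
    return float(1.0 - r.mean() ** 2 / s2)


def selectivity(responses: np.ndarray) -> float:
    """Lifetime sparseness of one neuron across L stimuli; in [0, 1-1/L]."""
    return _treves_rolls(responses)


def sparsity(responses: np.ndarray) -> float:
    """Population sparseness of one stimulus across Nh neurons; in
    [0, 1-1/Nh].  Same functional form as :func:`selectivity`."""
    return _treves_rolls(responses)


def mean_selectivity(R: np.ndarray) -> float:
    """Column-wise selectivity averaged over all neurons."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    return float(np.mean([_treves_rolls(R[:, j]) for j in range(R.shape[1])]))


def mean_sparsity(R: np.ndarray) -> float:
    """Row-wise sparsity averaged over all stimuli."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    return float(np.mean([_treves_rolls(R[l]) for l in range(R.shape[0])]))


def count_dead_neurons(
    R: np.ndarray, threshold: float = DEFAULT_DEAD_THRESHOLD
) -> int:
    """Number of units whose maximal activation probability over all
    stimuli is strictly below ``threshold`` (default 0.1)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    R = np.atleast_2d(np.asarray(R, dtype=float))
    return int((R.max(axis=0) < threshold).sum())


def summarize(
    params: RBMParams,
    patches,
    dead_threshold: float = DEFAULT_DEAD_THRESHOLD,
    max_stimuli: int | None = 10_000,
    seed: int = 0,
) -> dict:
    """Mean selectivity, mean sparsity and dead-neuron count for a model on
    a stimulus set (subsampled to ``max_stimuli`` rows for speed)."""
    V = np.atleast_2d(np.asarray(getattr(patches, "patches", patches), dtype=float))
    if max_stimuli is not None and V.shape[0] > max_stimuli:
        rng = np.random.default_rng(seed)
        V = V[rng.choice(V.shape[0], max_stimuli, replace=False)]
    R = prob_h_given_v(params, V)
    return {
        "mean_selectivity": mean_selectivity(R),
        "mean_sparsity": mean_sparsity(R),
        "dead_neurons": count_dead_neurons(R, dead_threshold),
        "n_stimuli": int(V.shape[0]),
        "n_neurons": int(R.shape[1]),
    }


def per_unit_table(R: np.ndarray) -> pd.DataFrame:
    """Per-neuron selectivity and maximum activation, as a frame."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    return pd.DataFrame(
        {
            "unit": np.arange(R.shape[1]),
            "selectivity": [_treves_rolls(R[:, j]) for j in range(R.shape[1])],
            "max_activation": R.max(axis=0),
        }
    )


def per_stimulus_table(R: np.ndarray) -> pd.DataFrame:
    """Per-stimulus population sparsity, as a frame."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    return pd.DataFrame(
        {
            "stimulus": np.arange(R.shape[0]),
            "sparsity": [_treves_rolls(R[l]) for l in range(R.shape[0])],
        }
    )
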