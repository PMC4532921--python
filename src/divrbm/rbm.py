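"""Binary restricted Boltzmann machine: energy, conditionals, exact
small-instance oracles, contrastive-divergence gradients, and training.

The model is a bipartite Markov network over binary visibles v (Nv units)
and binary hiddens h (Nh units) with joint density

    p(v, h) = exp(-E(v, h)) / Z,     E(v, h) = -v'Wh - h'b - v'c.

Hidden units are conditionally independent given v and vice versa, with
logistic conditionals.  Preprocessed image patches are continuous in [0, 1];
they are treated as visible activation probabilities throughout (positive
statistics and the final negative-phase statistics), while intermediate
Gibbs states are sampled as binary — the standard convention for real-valued
inputs to a binary RBM.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.special import expit

from .stimuli import PatchSet

#: exact enumeration is refused above 2**MAX_ENUM states in the smaller layer
MAX_ENUM_UNITS = 20

REGULARIZERS = ("none", "diversity", "sparse_group", "selective")


@dataclass
class RBMParams:
    """Weights and biases of a binary RBM.

    W : (Nv, Nh) symmetric inter-weights; column j is hidden unit j's basis
        image (the pattern it injects into the visible layer).
    b : (Nh,) hidden biases.  c : (Nv,) visible biases.
    """

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.c = np.asarray(self.c, dtype=float).ravel()
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (Nv x Nh)")
        nv, nh = self.W.shape
        if self.b.shape != (nh,) or self.c.shape != (nv,):
            raise ValueError("bias shapes do not match W")
        if not (
            np.all(np.isfinite(self.W))
            and np.all(np.isfinite(self.b))
            and np.all(np.isfinite(self.c))
        ):
            raise ValueError("parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.b.copy(), self.c.copy())

    def save(self, path, config: "TrainConfig | None" = None) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W)
            f.create_dataset("b", data=self.b)
            f.create_dataset("c", data=self.c)
            if config is not None:
                f.attrs["config"] = json.dumps(asdict(config))

    @classmethod
    def load(cls, path) -> "RBMParams":
        with h5py.File(path, "r") as f:
            return cls(f["W"][...], f["b"][...], f["c"][...])

    @classmethod
    def load_config(cls, path) -> "TrainConfig | None":
        with h5py.File(path, "r") as f:
            if "config" in f.attrs:
                return TrainConfig(**json.loads(f.attrs["config"]))
        return None


@dataclass
class TrainConfig:
    """Hyperparameters for CD training.

    lambda_div is the diversity-prior weight (the reference-scale default is
    1e-3); C the soft norm-penalty constant, irrelevant when hard column
    renormalization is active.  k is the number of block-Gibbs alternations
    in CD-k.
    """

    lambda_div: float = 1e-3
    C: float = 1.0
    k: int = 1
    learning_rate: float = 0.05
    epochs: int = 400
    batch_size: int = 100
    seed: int = 0
    regularizer: str = "diversity"
    renormalize_columns: bool = True
    sparse_weight: float = 1.0
    selective_weight: float = 3.0
    target_activation: float = 0.02
    #: per-column cap (in weight units) on the regularizer step per update;
    #: a trust-region safeguard that keeps strong priors (large lambda) on a
    #: stable descent path without changing their direction
    prior_step_cap: float = 0.5

    def __post_init__(self):
        if self.regularizer not in REGULARIZERS:
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.lambda_div < 0 or self.C < 0:
            raise ValueError("lambda_div and C must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class GradientSet:
    dW: np.ndarray
    db: np.ndarray
    dc: np.ndarray


def initialize(
    n_visible: int, n_hidden: int, seed: int = 0, weight_sd: float = 0.01
) -> RBMParams:
    """Gaussian weight init (sd 0.01 default), zero biases, seeded."""
    rng = np.random.default_rng(seed)
    return RBMParams(
        W=weight_sd * rng.standard_normal((n_visible, n_hidden)),
        b=np.zeros(n_hidden),
        c=np.zeros(n_visible),
    )


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, PatchSet):
        data = data.patches
    return np.atleast_2d(np.asarray(data, dtype=float))


def energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """E(v, h) = -v'Wh - h'b - v'c for one joint configuration."""
    v = np.asarray(v, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("configuration shapes do not match parameters")
    return float(-v @ params.W @ h - h @ params.b - v @ params.c)


def prob_h_given_v(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) = logistic(v'W_.j + b_j); accepts a vector or a
    (L, Nv) matrix of visibles (rows treated independently)."""
    v = np.asarray(v, dtype=float)
    return expit(v @ params.W + params.b)


def prob_v_given_h(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """p(v_i = 1 | h) = logistic(W_i. h + c_i); vector or (L, Nh) matrix."""
    h = np.asarray(h, dtype=float)
    return expit(h @ params.W.T + params.c)


def _check_enumerable(params: RBMParams) -> None:
    if min(params.n_visible, params.n_hidden) > MAX_ENUM_UNITS:
        raise ValueError(
            "exact computation refused: smaller layer has "
            f"{min(params.n_visible, params.n_hidden)} units "
            f"(> {MAX_ENUM_UNITS}); use the CD estimator instead"
        )


def _binary_states(n: int) -> np.ndarray:
    """All 2^n binary vectors, one per row."""
    ints = np.arange(2**n)[:, None]
    return ((ints >> np.arange(n)[None, :]) & 1).astype(float)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def exact_log_partition(params: RBMParams) -> float:
    """log Z by enumerating the smaller layer; the other layer is
    marginalized analytically through the free energy."""
    _check_enumerable(params)
    if params.n_hidden <= params.n_visible:
        H = _binary_states(params.n_hidden)
        # log sum_h exp(b'h + sum_i softplus((Wh)_i + c_i))
        terms = H @ params.b + _softplus(H @ params.W.T + params.c).sum(axis=1)
    else:
        V = _binary_states(params.n_visible)
        terms = V @ params.c + _softplus(V @ params.W + params.b).sum(axis=1)
    m = terms.max()
    return float(m + np.log(np.exp(terms - m).sum()))


def free_energy(params: RBMParams, v) -> np.ndarray:
    """-F(v) such that log p(v) = -F(v) - log Z (hiddens marginalized)."""
    V = _as_matrix(v)
    return V @ params.c + _softplus(V @ params.W + params.b).sum(axis=1)


def exact_log_likelihood(params: RBMParams, data) -> float:
    """Average log p(v) over data rows; tractable only for small layers."""
    _check_enumerable(params)
    return float(free_energy(params, data).mean() - exact_log_partition(params))


def exact_gradient(params: RBMParams, data) -> GradientSet:
    """Exact likelihood gradient: data expectation minus model expectation,
    the latter by enumeration of the smaller layer."""
    _check_enumerable(params)
    V = _as_matrix(data)
    L = V.shape[0]
    PH = prob_h_given_v(params, V)
    pos_W = V.T @ PH / L
    pos_b = PH.mean(axis=0)
    pos_c = V.mean(axis=0)

    if params.n_hidden <= params.n_visible:
        H = _binary_states(params.n_hidden)
        terms = H @ params.b + _softplus(H @ params.W.T + params.c).sum(axis=1)
        terms -= terms.max()
        p = np.exp(terms)
        p /= p.sum()
        PV = prob_v_given_h(params, H)  # E[v | h] rows
        neg_W = (PV * p[:, None]).T @ H
        neg_b = p @ H
        neg_c = p @ PV
    else:
        Vs = _binary_states(params.n_visible)
        terms = Vs @ params.c + _softplus(Vs @ params.W + params.b).sum(axis=1)
        terms -= terms.max()
        p = np.exp(terms)
        p /= p.sum()
        PHs = prob_h_given_v(params, Vs)
        neg_W = (Vs * p[:, None]).T @ PHs
        neg_b = p @ PHs
        neg_c = p @ Vs
    return GradientSet(pos_W - neg_W, pos_b - neg_b, pos_c - neg_c)


def cd_gradient(
    params: RBMParams, batch, k: int = 1, rng: np.random.Generator | None = None
) -> GradientSet:
    """CD-k gradient estimate.

    Positive phase uses the data rows v and p(h|v).  The negative phase runs
    k block-Gibbs alternations starting from the data: hiddens are sampled
    binary at every step; intermediate visibles are sampled binary, but the
    final visible state is the reconstruction *probability* p(v|h) and the
    final hidden statistics use p(h|v^-), as the CD update is written in
    probabilities.  Reproducible given the generator state.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    V = _as_matrix(batch)
    if V.shape[0] == 0:
        raise ValueError("empty batch")
    L = V.shape[0]
    ph_pos = prob_h_given_v(params, V)
    ph = ph_pos
    v_neg = None
    for step in range(k):
        h_samp = (rng.random(ph.shape) < ph).astype(float)
        pv = prob_v_given_h(params, h_samp)
        if step == k - 1:
            v_neg = pv
        else:
            v_cur = (rng.random(pv.shape) < pv).astype(float)
            ph = prob_h_given_v(params, v_cur)
    ph_neg = prob_h_given_v(params, v_neg)
    return GradientSet(
        dW=(V.T @ ph_pos - v_neg.T @ ph_neg) / L,
        db=(ph_pos - ph_neg).mean(axis=0),
        dc=(V - v_neg).mean(axis=0),
    )


def reconstruction_cross_entropy(params: RBMParams, batch) -> float:
    """Mean elementwise cross-entropy between v and its deterministic
    one-step reconstruction sigma(W p(h|v) + c); a training progress probe."""
    V = _as_matrix(batch)
    vr = prob_v_given_h(params, prob_h_given_v(params, V))
    eps = 1e-12
    ce = -(V * np.log(vr + eps) + (1 - V) * np.log(1 - vr + eps))
    return float(ce.mean())


def _regularizer_terms(params: RBMParams, batch, config: TrainConfig):
    """Return (dW, db, penalty_value) for the configured regularizer."""
    from . import priors

    if config.regularizer == "diversity" and config.lambda_div > 0:
        g = priors.diversity_gradient(params.W, config.lambda_div, config.C)
        return g.dW, None, g.penalty_value
    if config.regularizer == "sparse_group":
        g = priors.sparse_group_gradient(
            params.W, params.b, batch, config.sparse_weight
        )
        return g.dW, g.db, g.penalty_value
    if config.regularizer == "selective":
        g = priors.selective_gradient(
            params.W,
            params.b,
            batch,
            config.selective_weight,
            config.target_activation,
        )
        return g.dW, g.db, g.penalty_value
    return None, None, 0.0


def train(
    initial: RBMParams,
    patches,
    config: TrainConfig,
    gradient_fn=None,
    callback=None,
) -> tuple[RBMParams, pd.DataFrame]:
    """Mini-batch gradient ascent on the (regularized) log-likelihood.

    One epoch is a full pass over the (seeded-shuffled) data in mini-batches.
    Update = learning_rate * (CD-k gradient + log-prior gradient).  With
    ``renormalize_columns`` (the default) every weight column is rescaled to
    unit norm after each update — the hard form of the MAP problem's
    unit-norm constraint, applied identically in every arm so that
    regularizers are compared under a matched constraint (a "diversity" run
    at lambda_div = 0 is then bit-identical to a "none" run).  Regularizer
    steps larger than ``prior_step_cap`` per column are rescaled to the cap,
    which keeps very strong priors numerically stable.

    ``gradient_fn(params, batch, rng) -> GradientSet`` may replace the CD
    estimator (e.g. with the exact gradient on tiny instances).

    Returns the trained parameters and a history frame with per-epoch mean
    reconstruction cross-entropy and the diversity penalty value.
    """
    from . import priors

    V = _as_matrix(patches)
    if V.shape[0] == 0:
        raise ValueError("empty training set")
    params = initial.copy()
    rng = np.random.default_rng(config.seed)
    hist: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(V.shape[0])
        ce_sum, n_batches = 0.0, 0
        penalty = 0.0
        for start in range(0, V.shape[0], config.batch_size):
            batch = V[order[start : start + config.batch_size]]
            if gradient_fn is not None:
                grad = gradient_fn(params, batch, rng)
            else:
                grad = cd_gradient(params, batch, config.k, rng)
            reg_dW, reg_db, penalty = _regularizer_terms(params, batch, config)
            if reg_dW is not None and config.prior_step_cap > 0:
                # trust-region cap: rescale any regularizer column whose
                # step (after the learning rate) would exceed the cap, so
                # strong priors descend stably without changing direction
                steps = config.learning_rate * np.linalg.norm(reg_dW, axis=0)
                scale = np.minimum(1.0, config.prior_step_cap / np.maximum(steps, 1e-30))
                reg_dW = reg_dW * scale
            dW = grad.dW if reg_dW is None else grad.dW + reg_dW
            db = grad.db if reg_db is None else grad.db + reg_db
            params.W += config.learning_rate * dW
            params.b += config.learning_rate * db
            params.c += config.learning_rate * grad.dc
            if config.renormalize_columns:
                norms = np.linalg.norm(params.W, axis=0)
                params.W /= np.maximum(norms, 1e-12)
            ce_sum += reconstruction_cross_entropy(params, batch)
            n_batches += 1
        if not (
            np.all(np.isfinite(params.W))
            and np.all(np.isfinite(params.b))
            and np.all(np.isfinite(params.c))
        ):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: non-finite parameters "
                f"(lr={config.learning_rate}, lambda={config.lambda_div}, "
                f"regularizer={config.regularizer})"
            )
        row = {
            "epoch": epoch,
            "recon_cross_entropy": ce_sum / max(n_batches, 1),
            "penalty": penalty,
            "cos2_penalty": priors.squared_cosine_penalty(params.W),
        }
        hist.append(row)
        if callback is not None:
            callback(epoch, params, row)
    return params, pd.DataFrame(hist, columns=[
        "epoch", "recon_cross_entropy", "penalty", "cos2_penalty"
    ])
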