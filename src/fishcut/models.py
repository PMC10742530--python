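"""Head-cut-position regressors built from first principles.

Three predictors map principal-component scores of the demarcation line to
head length (mm):

* :func:`lssvm_fit` — least-squares SVM with an RBF kernel; training is one
  exact solve of the bordered Gram system, hyperparameters found by
  particle-swarm search over cross-validated RMSE (:func:`tune_lssvm`).
* :func:`pso_bp_fit` — a 1-hidden-layer (10 sigmoid units) back-propagation
  network whose weights are first located by PSO, then refined by full-batch
  gradient descent.
* :func:`lstm_fit` — a single-layer LSTM that consumes the score vector as a
  short univariate sequence, trained by backpropagation through time with
  global-norm gradient clipping and dropout on the output path.

All stochastic operations take explicit seeds; nothing touches global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidArgumentError, TrainingDivergedError

__all__ = [
    "PSOConfig",
    "LSSVMModel",
    "BPNetwork",
    "LSTMModel",
    "TrainedRegressor",
    "rbf_kernel",
    "lssvm_fit",
    "lssvm_predict",
    "pso_optimize",
    "tune_lssvm",
    "bp_forward",
    "bp_train",
    "pso_bp_fit",
    "lstm_forward",
    "lstm_fit",
    "train_regressor",
]

# Hyperparameter search boxes for the LS-SVM, by role: the regularization
# (penalty) parameter gam in [0.1, 100], the RBF width sig2 in [0.01, 100].
LSSVM_GAM_RANGE = (0.1, 100.0)
LSSVM_SIG2_RANGE = (0.01, 100.0)


# ---------------------------------------------------------------------------
# Particle swarm optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSOConfig:
    """Canonical PSO settings: inertia-decayed velocity updates in a box."""

    swarm_size: int = 20
    max_iter: int = 200
    c1: float = 2.0
    c2: float = 2.0
    inertia_max: float = 0.9
    inertia_min: float = 0.3
    position_bounds: tuple = ((-2.0, 2.0),)
    velocity_bounds: tuple = ((-1.0, 1.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise InvalidArgumentError("swarm_size must be >= 2")
        if self.max_iter < 1:
            raise InvalidArgumentError("max_iter must be >= 1")
        if not (self.inertia_max >= self.inertia_min > 0):
            raise InvalidArgumentError("need inertia_max >= inertia_min > 0")
        for lo, hi in self.position_bounds:
            if not lo < hi:
                raise InvalidArgumentError("position bounds must be non-empty intervals")
        for lo, hi in self.velocity_bounds:
            if not lo < hi:
                raise InvalidArgumentError("velocity bounds must be non-empty intervals")


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    config: PSOConfig,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``objective`` over the configured position box.

    Velocity update ``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``
    with the inertia weight decayed linearly from ``inertia_max`` to
    ``inertia_min``; velocities and positions are clipped to their boxes.
    Returns ``(best_position, best_value, history)`` where ``history`` is
    the running global best after initialization and after each iteration
    (length ``max_iter + 1``, non-increasing).  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pb = np.asarray(config.position_bounds, dtype=float)
    vb = np.asarray(config.velocity_bounds, dtype=float)
    dim = pb.shape[0]
    if vb.shape[0] == 1 and dim > 1:
        vb = np.repeat(vb, dim, axis=0)
    if vb.shape[0] != dim:
        raise InvalidArgumentError("velocity_bounds dimension mismatch")

    x = rng.uniform(pb[:, 0], pb[:, 1], size=(config.swarm_size, dim))
    v = rng.uniform(vb[:, 0], vb[:, 1], size=(config.swarm_size, dim))
    fitness = np.array([float(objective(xi)) for xi in x])
    if not np.all(np.isfinite(fitness)):
        raise InvalidArgumentError("objective is not finite on the position box")
    pbest = x.copy()
    pbest_val = fitness.copy()
    g = int(np.argmin(fitness))
    gbest = x[g].copy()
    gbest_val = float(fitness[g])
    history = [gbest_val]

    denom = max(config.max_iter - 1, 1)
    for it in range(config.max_iter):
        w = config.inertia_max - (config.inertia_max - config.inertia_min) * (it / denom)
        r1 = rng.random((config.swarm_size, dim))
        r2 = rng.random((config.swarm_size, dim))
        v = w * v + config.c1 * r1 * (pbest - x) + config.c2 * r2 * (gbest - x)
        v = np.clip(v, vb[:, 0], vb[:, 1])
        x = np.clip(x + v, pb[:, 0], pb[:, 1])
        fitness = np.array([float(objective(xi)) for xi in x])
        improved = fitness < pbest_val
        pbest[improved] = x[improved]
        pbest_val[improved] = fitness[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest_val = float(pbest_val[g])
            gbest = pbest[g].copy()
        history.append(gbest_val)
    return gbest, gbest_val, np.asarray(history)


# ---------------------------------------------------------------------------
# LS-SVM
# ---------------------------------------------------------------------------

@dataclass
class LSSVMModel:
    """Dual solution of the least-squares SVM regression problem."""

    support_inputs: np.ndarray   # (n, m) training score vectors
    alphas: np.ndarray           # (n,)
    bias: float
    gam: float                   # regularization (penalty) parameter
    sig2: float                  # RBF kernel width parameter


def rbf_kernel(u: np.ndarray, v: np.ndarray, sig2: float) -> float:
    """Gaussian RBF kernel ``exp(-||u-v||^2 / (2 sig2))``."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvalidArgumentError("rbf_kernel: dimension mismatch")
    if sig2 <= 0:
        raise InvalidArgumentError("sig2 must be > 0")
    d2 = float(np.sum((u - v) ** 2))
    return math.exp(-d2 / (2.0 * sig2))


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    a2 = np.sum(A * A, axis=1)[:, None]
    b2 = np.sum(B * B, axis=1)[None, :]
    return np.maximum(a2 + b2 - 2.0 * (A @ B.T), 0.0)


def _gram(A: np.ndarray, B: np.ndarray, sig2: float) -> np.ndarray:
    return np.exp(-_sq_dists(A, B) / (2.0 * sig2))


def lssvm_fit(X: np.ndarray, y: np.ndarray, gam: float, sig2: float) -> LSSVMModel:
    """Exact solve of the LS-SVM dual system.

    Solves ``[[0, 1^T], [1, K + I/gam]] [b; alpha] = [0; y]`` with ``K`` the
    RBF Gram matrix of the training scores; no iteration.  The first block
    row enforces ``sum(alpha) = 0``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n or n < 1:
        raise InvalidArgumentError("X and y sizes disagree or are empty")
    if gam <= 0 or sig2 <= 0:
        raise InvalidArgumentError("gam and sig2 must be > 0")
    K = _gram(X, X, sig2)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gam
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(A)
        raise np.linalg.LinAlgError(
            f"LS-SVM system singular (cond ~ {cond:.3g})"
        ) from exc
    return LSSVMModel(support_inputs=X, alphas=sol[1:], bias=float(sol[0]),
                      gam=float(gam), sig2=float(sig2))


def lssvm_predict(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """Kernel expansion ``f(x) = sum_i alpha_i k(x, x_i) + b``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.support_inputs.shape[1]:
        raise InvalidArgumentError("query dimension mismatch")
    K = _gram(X, model.support_inputs, model.sig2)
    return K @ model.alphas + model.bias


def _cv_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [idx[i::k] for i in range(k)]


def tune_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    config: PSOConfig | None = None,
    n_folds: int = 5,
) -> tuple[LSSVMModel, np.ndarray]:
    """PSO search for (gam, sig2) minimizing k-fold cross-validated RMSE.

    The search runs in log10-space over the role-mapped boxes
    (:data:`LSSVM_GAM_RANGE`, :data:`LSSVM_SIG2_RANGE`); folds are fixed
    from the PSO seed, so the objective is deterministic.  Returns the model
    refit on all data at the optimum plus the PSO fitness history.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise InvalidArgumentError("need n >= 4 for cross-validation")
    if config is None:
        config = PSOConfig(max_iter=100)
    lb = (math.log10(LSSVM_GAM_RANGE[0]), math.log10(LSSVM_SIG2_RANGE[0]))
    ub = (math.log10(LSSVM_GAM_RANGE[1]), math.log10(LSSVM_SIG2_RANGE[1]))
    config = replace(
        config,
        position_bounds=((lb[0], ub[0]), (lb[1], ub[1])),
        velocity_bounds=((-1.0, 1.0), (-1.0, 1.0)),
    )
    folds = _cv_folds(n, min(n_folds, n), np.random.default_rng(config.seed))
    D2 = _sq_dists(X, X)

    def objective(pos: np.ndarray) -> float:
        gam = 10.0 ** pos[0]
        sig2 = 10.0 ** pos[1]
        K = np.exp(-D2 / (2.0 * sig2))
        sse = 0.0
        for test in folds:
            train = np.setdiff1d(np.arange(n), test, assume_unique=False)
            ntr = train.size
            A = np.zeros((ntr + 1, ntr + 1))
            A[0, 1:] = 1.0
            A[1:, 0] = 1.0
            A[1:, 1:] = K[np.ix_(train, train)] + np.eye(ntr) / gam
            sol = np.linalg.solve(A, np.concatenate([[0.0], y[train]]))
            pred = K[np.ix_(test, train)] @ sol[1:] + sol[0]
            sse += float(np.sum((pred - y[test]) ** 2))
        return math.sqrt(sse / n)

    best, _, history = pso_optimize(objective, config)
    model = lssvm_fit(X, y, gam=10.0 ** best[0], sig2=10.0 ** best[1])
    return model, history


# ---------------------------------------------------------------------------
# Back-propagation network (+ PSO weight initialization)
# ---------------------------------------------------------------------------

@dataclass
class BPNetwork:
    """1-hidden-layer network: sigmoid hidden units, linear output."""

    input_weights: np.ndarray    # (n_in, n_hidden)
    input_biases: np.ndarray     # (n_hidden,)
    output_weights: np.ndarray   # (n_hidden,)
    output_bias: float
    learning_rate: float = 0.09
    max_iter: int = 1000
    goal: float = 1e-5           # target mean squared error

    @property
    def n_inputs(self) -> int:
        return int(self.input_weights.shape[0])

    @property
    def n_hidden(self) -> int:
        return int(self.input_weights.shape[1])

    def n_parameters(self) -> int:
        return self.input_weights.size + self.input_biases.size + \
            self.output_weights.size + 1

    def flatten(self) -> np.ndarray:
        return np.concatenate([
            self.input_weights.ravel(), self.input_biases,
            self.output_weights, [self.output_bias],
        ])

    def with_parameters(self, theta: np.ndarray) -> "BPNetwork":
        ni, nh = self.n_inputs, self.n_hidden
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_parameters():
            raise InvalidArgumentError("parameter vector length mismatch")
        W = theta[: ni * nh].reshape(ni, nh)
        b1 = theta[ni * nh : ni * nh + nh]
        w2 = theta[ni * nh + nh : ni * nh + 2 * nh]
        b2 = float(theta[-1])
        return replace(self, input_weights=W.copy(), input_biases=b1.copy(),
                       output_weights=w2.copy(), output_bias=b2)


def new_bp_network(n_inputs: int = 3, n_hidden: int = 10, seed: int = 0,
                   **kwargs) -> BPNetwork:
    """Random small-weight initialization (uniform in [-0.5, 0.5])."""
    rng = np.random.default_rng(seed)
    return BPNetwork(
        input_weights=rng.uniform(-0.5, 0.5, size=(n_inputs, n_hidden)),
        input_biases=rng.uniform(-0.5, 0.5, size=n_hidden),
        output_weights=rng.uniform(-0.5, 0.5, size=n_hidden),
        output_bias=float(rng.uniform(-0.5, 0.5)),
        **kwargs,
    )


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def bp_forward(net: BPNetwork, X: np.ndarray) -> np.ndarray:
    """Forward pass: sigmoid hidden layer, linear output unit."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.n_inputs:
        raise InvalidArgumentError(
            f"input dimension {X.shape[1]} != network {net.n_inputs}"
        )
    hidden = _sigmoid(X @ net.input_weights + net.input_biases)
    return hidden @ net.output_weights + net.output_bias


def bp_loss_and_grad(net: BPNetwork, X: np.ndarray, y: np.ndarray
                     ) -> tuple[float, np.ndarray]:
    """Mean-squared-error loss and its analytic gradient (flattened)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    hidden = _sigmoid(X @ net.input_weights + net.input_biases)
    pred = hidden @ net.output_weights + net.output_bias
    resid = pred - y
    loss = float(np.mean(resid**2))
    d = (2.0 / n) * resid                      # dL/dpred
    gw2 = hidden.T @ d
    gb2 = float(np.sum(d))
    dh = np.outer(d, net.output_weights)
    da = dh * hidden * (1.0 - hidden)
    gW1 = X.T @ da
    gb1 = da.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])
    return loss, grad


def bp_train(net: BPNetwork, X: np.ndarray, y: np.ndarray,
             keep_best: bool = True) -> BPNetwork:
    """Full-batch gradient descent on MSE.

    Stops at ``net.max_iter`` updates or as soon as the loss reaches
    ``net.goal`` (checked before the first update, so a network already at
    goal is returned untouched).  With ``keep_best`` the parameters with the
    lowest observed full-batch loss are returned, so refinement can never
    end worse than it started.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 1:
        raise InvalidArgumentError("need at least one training sample")
    theta = net.flatten()
    loss, grad = bp_loss_and_grad(net, X, y)
    best_theta, best_loss = theta.copy(), loss
    for _ in range(net.max_iter):
        if loss <= net.goal:
            break
        theta = theta - net.learning_rate * grad
        candidate = net.with_parameters(theta)
        loss, grad = bp_loss_and_grad(candidate, X, y)
        if not np.isfinite(loss):
            raise TrainingDivergedError("BP training loss became non-finite")
        if loss < best_loss:
            best_loss, best_theta = loss, theta.copy()
    return net.with_parameters(best_theta if keep_best else theta)


def pso_bp_fit(X: np.ndarray, y: np.ndarray,
               pso_config: PSOConfig | None = None,
               net_config: dict | None = None,
               refine: bool = True) -> BPNetwork:
    """PSO weight search followed by gradient refinement.

    All network parameters (``n_in*n_hidden + n_hidden + n_hidden + 1``; 51
    for the default 3-input, 10-unit net) are flattened into particle
    positions searched in the [-2, 2] box with velocities in [-1, 1]; the
    best particle initializes :func:`bp_train`.  ``refine=False`` returns
    the pure-PSO solution.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 4:
        raise InvalidArgumentError("need n >= 4 samples")
    net_config = dict(net_config or {})
    n_hidden = net_config.pop("n_hidden", 10)
    seed = net_config.pop("seed", 0)
    proto = new_bp_network(n_inputs=X.shape[1], n_hidden=n_hidden, seed=seed,
                           **net_config)
    dim = proto.n_parameters()
    if pso_config is None:
        pso_config = PSOConfig(seed=seed)
    pso_config = replace(
        pso_config,
        position_bounds=tuple([(-2.0, 2.0)] * dim),
        velocity_bounds=tuple([(-1.0, 1.0)] * dim),
    )

    def objective(theta: np.ndarray) -> float:
        return bp_loss_and_grad(proto.with_parameters(theta), X, y)[0]

    best, _, _ = pso_optimize(objective, pso_config)
    net = proto.with_parameters(best)
    if refine:
        net = bp_train(net, X, y, keep_best=True)
    return net


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

_GATES = ("f", "i", "o", "g")  # forget, input, output, candidate


@dataclass
class LSTMModel:
    """Single-layer LSTM + dense output for a short univariate sequence.

    ``W[k]`` are input-to-gate weights (hidden_size,), ``V[k]`` recurrent
    weights (hidden_size, hidden_size) and ``b[k]`` gate biases for
    ``k in {'f','i','o','g'}`` (forget / input / output gates and the tanh
    candidate path).  The final hidden state maps through ``dense_weights``
    / ``dense_bias`` to one output.
    """

    W: dict
    V: dict
    b: dict
    dense_weights: np.ndarray
    dense_bias: float
    hidden_size: int = 16
    dropout_rate: float = 0.2
    learning_rate: float = 0.005
    gradient_clip: float = 1.0
    max_iter: int = 200
    seed: int = 0

    def flatten(self) -> np.ndarray:
        parts = []
        for k in _GATES:
            parts += [self.W[k], self.V[k].ravel(), self.b[k]]
        parts += [self.dense_weights, [self.dense_bias]]
        return np.concatenate(parts)

    def with_parameters(self, theta: np.ndarray) -> "LSTMModel":
        H = self.hidden_size
        theta = np.asarray(theta, dtype=float)
        W, V, b = {}, {}, {}
        pos = 0
        for k in _GATES:
            W[k] = theta[pos : pos + H].copy(); pos += H
            V[k] = theta[pos : pos + H * H].reshape(H, H).copy(); pos += H * H
            b[k] = theta[pos : pos + H].copy(); pos += H
        dense = theta[pos : pos + H].copy(); pos += H
        bias = float(theta[pos]); pos += 1
        if pos != theta.size:
            raise InvalidArgumentError("parameter vector length mismatch")
        return replace(self, W=W, V=V, b=b, dense_weights=dense, dense_bias=bias)


def new_lstm(hidden_size: int = 16, seed: int = 0, **kwargs) -> LSTMModel:
    """Small random initialization; forget-gate bias starts at 1."""
    rng = np.random.default_rng(seed)
    H = hidden_size
    W = {k: rng.normal(0.0, 0.2, size=H) for k in _GATES}
    V = {k: rng.normal(0.0, 0.2 / math.sqrt(H), size=(H, H)) for k in _GATES}
    b = {k: np.zeros(H) for k in _GATES}
    b["f"] = np.ones(H)
    dense = rng.normal(0.0, 0.2, size=H)
    return LSTMModel(W=W, V=V, b=b, dense_weights=dense, dense_bias=0.0,
                     hidden_size=H, seed=seed, **kwargs)


def _lstm_pass(model: LSTMModel, X: np.ndarray):
    """Forward pass over a batch; returns predictions and per-step caches."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, T = X.shape
    H = model.hidden_size
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    caches = []
    for t in range(T):
        xt = X[:, t][:, None]
        a = {k: xt * model.W[k] + h @ model.V[k] + model.b[k] for k in _GATES}
        f = _sigmoid(a["f"]); i = _sigmoid(a["i"]); o = _sigmoid(a["o"])
        g = np.tanh(a["g"])
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        caches.append(dict(x=X[:, t], f=f, i=i, o=o, g=g, c=c, tc=tc,
                           c_prev=c_prev, h_prev=h_prev))
    return h, caches


def lstm_forward(model: LSTMModel, X: np.ndarray,
                 dropout_mask: np.ndarray | None = None) -> np.ndarray:
    """Predictions for score vectors consumed as T-step univariate sequences.

    Standard cell recurrences (sigmoid forget/input/output gates, tanh
    candidate, ``c_t = f c_{t-1} + i g``, ``h_t = o tanh(c_t)``) from a zero
    initial state; the final hidden state feeds a dense layer with one
    output.  ``dropout_mask`` (training only) scales the hidden-to-output
    path.
    """
    for k in _GATES:
        if not (np.all(np.isfinite(model.W[k])) and np.all(np.isfinite(model.V[k]))
                and np.all(np.isfinite(model.b[k]))):
            raise InvalidArgumentError("LSTM parameters are not finite")
    h, _ = _lstm_pass(model, X)
    hd = h if dropout_mask is None else h * dropout_mask
    return hd @ model.dense_weights + model.dense_bias


def lstm_loss_and_grad(model: LSTMModel, X: np.ndarray, y: np.ndarray,
                       dropout_mask: np.ndarray | None = None
                       ) -> tuple[float, np.ndarray]:
    """MSE loss and analytic BPTT gradient, flattened like ``flatten()``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, T = X.shape
    H = model.hidden_size
    h, caches = _lstm_pass(model, X)
    mask = np.ones_like(h) if dropout_mask is None else dropout_mask
    hd = h * mask
    pred = hd @ model.dense_weights + model.dense_bias
    resid = pred - y
    loss = float(np.mean(resid**2))

    d = (2.0 / n) * resid
    g_dense = hd.T @ d
    g_bias = float(np.sum(d))
    dh = np.outer(d, model.dense_weights) * mask
    dc = np.zeros((n, H))
    gW = {k: np.zeros(H) for k in _GATES}
    gV = {k: np.zeros((H, H)) for k in _GATES}
    gb = {k: np.zeros(H) for k in _GATES}
    for t in range(T - 1, -1, -1):
        cc = caches[t]
        do = dh * cc["tc"]
        dc = dc + dh * cc["o"] * (1.0 - cc["tc"] ** 2)
        df = dc * cc["c_prev"]
        di = dc * cc["g"]
        dg = dc * cc["i"]
        da = {
            "f": df * cc["f"] * (1.0 - cc["f"]),
            "i": di * cc["i"] * (1.0 - cc["i"]),
            "o": do * cc["o"] * (1.0 - cc["o"]),
            "g": dg * (1.0 - cc["g"] ** 2),
        }
        dh_prev = np.zeros((n, H))
        for k in _GATES:
            gW[k] += cc["x"] @ da[k]
            gV[k] += cc["h_prev"].T @ da[k]
            gb[k] += da[k].sum(axis=0)
            dh_prev += da[k] @ model.V[k].T
        dh = dh_prev
        dc = dc * cc["f"]

    parts = []
    for k in _GATES:
        parts += [gW[k], gV[k].ravel(), gb[k]]
    parts += [g_dense, [g_bias]]
    return loss, np.concatenate(parts)


def _clip_global_norm(grad: np.ndarray, clip: float) -> np.ndarray:
    norm = float(np.linalg.norm(grad))
    if clip > 0 and norm > clip:
        return grad * (clip / norm)
    return grad


def lstm_fit(X: np.ndarray, y: np.ndarray,
             hidden_size: int = 16, dropout_rate: float = 0.2,
             learning_rate: float = 0.005, gradient_clip: float = 1.0,
             max_iter: int = 200, seed: int = 0,
             validation: tuple[np.ndarray, np.ndarray] | None = None,
             ) -> tuple[LSTMModel, dict]:
    """Train an LSTM regressor by full-batch BPTT with Adam steps.

    Gradients are clipped to global norm ``gradient_clip``; dropout (rate
    ``dropout_rate``) is applied to the hidden-to-output path during
    training only, with a fresh mask per epoch.  Returns the model and a
    history dict with per-epoch training (and optional validation) loss.
    Deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 4:
        raise InvalidArgumentError("need n >= 4 samples")
    model = new_lstm(hidden_size=hidden_size, seed=seed,
                     dropout_rate=dropout_rate, learning_rate=learning_rate,
                     gradient_clip=gradient_clip, max_iter=max_iter)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5e9)))
    theta = model.flatten()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    train_hist, val_hist = [], []
    for epoch in range(1, max_iter + 1):
        if dropout_rate > 0:
            keep = (rng.random((y.size, hidden_size)) >= dropout_rate)
            dmask = keep / (1.0 - dropout_rate)
        else:
            dmask = None
        cur = model.with_parameters(theta)
        loss, grad = lstm_loss_and_grad(cur, X, y, dropout_mask=dmask)
        if not np.isfinite(loss):
            raise TrainingDivergedError("LSTM training loss became non-finite")
        grad = _clip_global_norm(grad, gradient_clip)
        m = beta1 * m + (1.0 - beta1) * grad
        v = beta2 * v + (1.0 - beta2) * grad * grad
        mh = m / (1.0 - beta1**epoch)
        vh = v / (1.0 - beta2**epoch)
        theta = theta - learning_rate * mh / (np.sqrt(vh) + eps)
        clean_loss, _ = lstm_loss_and_grad(model.with_parameters(theta), X, y)
        train_hist.append(clean_loss)
        if validation is not None:
            Xv, yv = validation
            pv = lstm_forward(model.with_parameters(theta), Xv)
            val_hist.append(float(np.mean((pv - np.ravel(yv)) ** 2)))
    final = model.with_parameters(theta)
    history = {"train_loss": np.asarray(train_hist)}
    if validation is not None:
        history["val_loss"] = np.asarray(val_hist)
    return final, history


# ---------------------------------------------------------------------------
# Unified trained-regressor wrapper
# ---------------------------------------------------------------------------

@dataclass
class TrainedRegressor:
    """A fitted predictor with its input/target standardization statistics.

    ``kind`` is one of ``{"lssvm", "psobp", "lstm"}``.  Inputs are
    standardized by training-set mean/sd before the inner model sees them
    and predictions are mapped back to mm.
    """

    kind: str
    model: object
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    extra: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.x_mean) / self.x_sd
        if self.kind == "lssvm":
            z = lssvm_predict(self.model, Xs)
        elif self.kind == "psobp":
            z = bp_forward(self.model, Xs)
        elif self.kind == "lstm":
            z = lstm_forward(self.model, Xs)
        else:
            raise InvalidArgumentError(f"unknown regressor kind {self.kind!r}")
        return z * self.y_sd + self.y_mean


def train_regressor(kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0,
                    **settings) -> TrainedRegressor:
    """Standardize, dispatch to the requested trainer and wrap the result.

    ``settings`` are forwarded: LS-SVM accepts ``pso_config``/``n_folds`` or
    explicit ``gam``/``sig2``; the networks accept their trainer keywords.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1)) or 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd
    extra: dict = {}
    if kind == "lssvm":
        if "gam" in settings and "sig2" in settings:
            inner = lssvm_fit(Xs, ys, settings["gam"], settings["sig2"])
        else:
            pso = settings.get("pso_config") or PSOConfig(max_iter=100, seed=seed)
            inner, history = tune_lssvm(Xs, ys, pso,
                                        n_folds=settings.get("n_folds", 5))
            extra["pso_history"] = history
    elif kind == "psobp":
        pso = settings.get("pso_config") or PSOConfig(max_iter=200, seed=seed)
        net_config = dict(settings.get("net_config") or {})
        net_config.setdefault("seed", seed)
        inner = pso_bp_fit(Xs, ys, pso, net_config,
                           refine=settings.get("refine", True))
    elif kind == "lstm":
        keys = ("hidden_size", "dropout_rate", "learning_rate",
                "gradient_clip", "max_iter")
        kw = {k: settings[k] for k in keys if k in settings}
        inner, history = lstm_fit(Xs, ys, seed=seed, **kw)
        extra["history"] = history
    else:
        raise InvalidArgumentError(f"unknown regressor kind {kind!r}")
    return TrainedRegressor(kind=kind, model=inner, x_mean=x_mean, x_sd=x_sd,
                            y_mean=y_mean, y_sd=y_sd, extra=extra)
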