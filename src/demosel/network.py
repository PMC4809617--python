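"""Deep feed-forward network with a hybrid continuous + categorical head.

Hidden layers use the logistic activation f(z) = 1/(1+exp(-z)).  The
output layer has 3 linear nodes (the normalized size scaling factors)
and K = 4 softmax nodes (the selection class).  The joint training cost
is the sum of a squared-error head, a softmax cross-entropy head, and a
weight-decay penalty on the final layer:

    J = (1/m) sum_i 1/2 ||h_lin(x_i) - y_i||^2
        - (1/m) sum_i log p(class_i | x_i)
        + (lambda/2) sum (W_last)^2

Weights below the output layer are initialized by greedy layer-wise
sparse-autoencoder pretraining; the whole network is then fine-tuned
with L-BFGS.  The sparse-autoencoder objective adds a KL-divergence
penalty driving mean hidden activations toward a target rho, and weight
decay on both encoder and decoder.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

N_CONTINUOUS = 3
N_CLASSES = 4


class NetworkConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Architecture:
    """Layer sizes: input, hidden..., and the fixed 3+4 output head."""

    n_inputs: int = 345
    hidden: tuple[int, ...] = (25, 25, 10)

    def __post_init__(self):
        if len(self.hidden) < 1 or min(self.hidden) < 1 or self.n_inputs < 1:
            raise NetworkConfigurationError("need >=1 hidden layer, sizes >=1")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden, N_CONTINUOUS + N_CLASSES)

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)


@dataclass
class WeightSet:
    """W[l]: (u_l, u_{l+1}) weight matrices; b[l]: (u_{l+1},) biases."""

    W: list[np.ndarray]
    b: list[np.ndarray]

    def copy(self) -> "WeightSet":
        return WeightSet([w.copy() for w in self.W], [v.copy() for v in self.b])

    def flatten(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.W]
                              + [v.ravel() for v in self.b])

    @staticmethod
    def unflatten(theta: np.ndarray, arch: Architecture) -> "WeightSet":
        sizes = arch.layer_sizes
        W, b, k = [], [], 0
        for l in range(len(sizes) - 1):
            m = sizes[l] * sizes[l + 1]
            W.append(theta[k:k + m].reshape(sizes[l], sizes[l + 1]))
            k += m
        for l in range(len(sizes) - 1):
            b.append(theta[k:k + sizes[l + 1]])
            k += sizes[l + 1]
        return WeightSet(W, b)


@dataclass(frozen=True)
class TrainConfig:
    lambda_decay: float = 1e-4
    rho: float = 0.25
    beta: float = 3.0
    max_iter: int = 400
    pretrain_max_iter: int = 200
    seed: int = 0
    prior_bounds: tuple = ((3.0, 14.0), (0.5, 6.0), (2.0, 10.0))
    regression_weight: float = 1.0  # weight of the squared-error head

    def __post_init__(self):
        if self.lambda_decay < 0 or self.beta < 0 or not (0 < self.rho < 1):
            raise NetworkConfigurationError("invalid regularization settings")


@dataclass
class ForwardTrace:
    activations: list[np.ndarray]   # a^(1) = x, hidden activations
    linear: np.ndarray              # (m, 3)
    probs: np.ndarray               # (m, 4), rows sum to 1
    logits: np.ndarray


def feed_forward(X: np.ndarray, weights: WeightSet,
                 arch: Architecture | None = None) -> ForwardTrace:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != weights.W[0].shape[0]:
        raise NetworkConfigurationError(
            f"input width {X.shape[1]} != first layer {weights.W[0].shape[0]}")
    a = X
    acts = [a]
    for l in range(len(weights.W) - 1):
        a = expit(a @ weights.W[l] + weights.b[l])
        acts.append(a)
    out = a @ weights.W[-1] + weights.b[-1]
    linear = out[:, :N_CONTINUOUS]
    logits = out[:, N_CONTINUOUS:]
    logp = logits - logsumexp(logits, axis=1, keepdims=True)
    return ForwardTrace(acts, linear, np.exp(logp), logits)


def _responses(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return Y[:, :N_CONTINUOUS], Y[:, N_CONTINUOUS:]


def joint_cost(X: np.ndarray, Y: np.ndarray, weights: WeightSet,
               config: TrainConfig) -> float:
    trace = feed_forward(X, weights)
    y_cont, y_onehot = _responses(Y)
    m = trace.linear.shape[0]
    reg_term = 0.5 * np.sum((trace.linear - y_cont) ** 2) / m
    logp = trace.logits - logsumexp(trace.logits, axis=1, keepdims=True)
    xent = -np.sum(y_onehot * logp) / m
    decay = 0.5 * config.lambda_decay * np.sum(weights.W[-1] ** 2)
    return float(config.regression_weight * reg_term + xent + decay)


def backprop(X: np.ndarray, Y: np.ndarray, weights: WeightSet,
             config: TrainConfig) -> WeightSet:
    """Gradient of joint_cost; per-example contributions are independent
    sums, so they may be evaluated in any order or in parallel."""
    trace = feed_forward(X, weights)
    y_cont, y_onehot = _responses(Y)
    m = trace.linear.shape[0]
    delta = np.hstack([
        config.regression_weight * (trace.linear - y_cont),
        trace.probs - y_onehot,
    ]) / m
    gW = [np.zeros_like(w) for w in weights.W]
    gb = [np.zeros_like(v) for v in weights.b]
    for l in range(len(weights.W) - 1, -1, -1):
        a = trace.activations[l]
        gW[l] = a.T @ delta
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ weights.W[l].T) * a * (1.0 - a)
    gW[-1] += config.lambda_decay * weights.W[-1]
    return WeightSet(gW, gb)


def _cost_and_grad(theta, X, Y, arch, config):
    w = WeightSet.unflatten(theta, arch)
    return joint_cost(X, Y, w, config), backprop(X, Y, w, config).flatten()


# ---------------------------------------------------------------------------
# sparse autoencoder

_KL_EPS = 1e-10


def _ae_unflatten(theta, d, h):
    k = 0
    W1 = theta[k:k + d * h].reshape(d, h); k += d * h
    W2 = theta[k:k + h * d].reshape(h, d); k += h * d
    b1 = theta[k:k + h]; k += h
    b2 = theta[k:k + d]
    return W1, W2, b1, b2


def autoencoder_cost(X: np.ndarray, theta: np.ndarray, h: int,
                     config: TrainConfig, *, linear: bool = False,
                     with_grad: bool = True):
    """Sparse-autoencoder cost (and gradient) for a single hidden layer.

    linear=True replaces the logistic activation with the identity on
    both layers, in which case the hidden layer spans the data's
    principal subspace at the optimum.
    """
    X = np.atleast_2d(X)
    m, d = X.shape
    W1, W2, b1, b2 = _ae_unflatten(theta, d, h)
    z1 = X @ W1 + b1
    a = z1 if linear else expit(z1)
    z2 = a @ W2 + b2
    xhat = z2 if linear else expit(z2)
    resid = xhat - X
    cost = 0.5 * np.sum(resid ** 2) / m
    rho_hat = np.clip(a.mean(axis=0), _KL_EPS, 1.0 - _KL_EPS)
    rho = config.rho
    kl = np.sum(rho * np.log(rho / rho_hat)
                + (1 - rho) * np.log((1 - rho) / (1 - rho_hat)))
    cost += config.beta * kl
    cost += 0.5 * config.lambda_decay * (np.sum(W1 ** 2) + np.sum(W2 ** 2))
    if not with_grad:
        return cost
    d2 = resid / m if linear else resid * xhat * (1 - xhat) / m
    gW2 = a.T @ d2 + config.lambda_decay * W2
    gb2 = d2.sum(axis=0)
    dkl = config.beta * (-(rho / rho_hat) + (1 - rho) / (1 - rho_hat)) / m
    d1 = d2 @ W2.T + dkl[None, :]
    if not linear:
        d1 = d1 * a * (1 - a)
    gW1 = X.T @ d1 + config.lambda_decay * W1
    gb1 = d1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gW2.ravel(), gb1.ravel(), gb2.ravel()])
    return cost, grad


def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def train_autoencoder(X, h, config, rng, linear=False):
    """Train one sparse autoencoder with L-BFGS.

    Returns (encoder W, encoder b, hidden representation, OptimizeResult).
    """
    m, d = np.atleast_2d(X).shape
    theta0 = np.concatenate([
        _glorot(rng, d, h).ravel(), _glorot(rng, h, d).ravel(),
        np.zeros(h), np.zeros(d)])

    def fun(theta):
        return autoencoder_cost(X, theta, h, config, linear=linear)

    res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": config.pretrain_max_iter,
                            "ftol": 1e-13, "gtol": 1e-10})
    if not np.isfinite(res.fun):
        raise FloatingPointError("autoencoder cost became non-finite")
    W1, W2, b1, b2 = _ae_unflatten(res.x, d, h)
    z = X @ W1 + b1
    a = z if linear else expit(z)
    return W1.copy(), b1.copy(), a, res


def pretrain_stack(X: np.ndarray, arch: Architecture,
                   config: TrainConfig) -> WeightSet:
    """Greedy layer-wise autoencoder initialization of all layers below
    the output; decoder weights are discarded, the output layer is
    initialized with small seeded Gaussian weights."""
    rng = np.random.default_rng(config.seed)
    a = np.atleast_2d(np.asarray(X, dtype=float))
    W, b = [], []
    for li, h in enumerate(arch.hidden):
        try:
            W1, b1, a, _ = train_autoencoder(a, h, config, rng)
        except Exception as exc:
            raise RuntimeError(f"autoencoder pretraining failed at hidden "
                               f"layer {li + 1}: {exc}") from exc
        W.append(W1)
        b.append(b1)
    n_out = N_CONTINUOUS + N_CLASSES
    W.append(0.01 * rng.standard_normal((arch.hidden[-1], n_out)))
    b.append(np.zeros(n_out))
    return WeightSet(W, b)


def random_init(arch: Architecture, seed: int = 0,
                scheme: str = "glorot") -> WeightSet:
    """Random initialization of every layer.

    scheme="glorot": uniform in +/-sqrt(6/(fan_in+fan_out)) -- a modern
    scale-aware initialization under which deep logistic nets usually
    train acceptably even without pretraining.
    scheme="small_gaussian": 0.01 * standard normal -- the classical
    naive initialization; deep logistic nets started this way tend to
    stall on the single-class plateau, which is the behaviour the
    pretraining comparison is about.
    """
    rng = np.random.default_rng(seed)
    sizes = arch.layer_sizes
    if scheme == "glorot":
        W = [_glorot(rng, sizes[l], sizes[l + 1])
             for l in range(len(sizes) - 1)]
    elif scheme == "small_gaussian":
        W = [0.01 * rng.standard_normal((sizes[l], sizes[l + 1]))
             for l in range(len(sizes) - 1)]
    else:
        raise NetworkConfigurationError(f"unknown init scheme {scheme!r}")
    b = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]
    return WeightSet(W, b)


def fine_tune(X: np.ndarray, Y: np.ndarray, init_weights: WeightSet,
              config: TrainConfig, arch: Architecture | None = None
              ) -> tuple[WeightSet, dict]:
    """L-BFGS minimization of the joint cost from the given initialization.

    Returns the trained weights and an info dict with the cost trace over
    accepted iterates (monotone non-increasing).
    """
    if arch is None:
        arch = Architecture(n_inputs=init_weights.W[0].shape[0],
                            hidden=tuple(w.shape[1] for w in init_weights.W[:-1]))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise NetworkConfigurationError("empty training corpus")
    trace: list[float] = []

    def cb(theta):
        c = joint_cost(X, Y, WeightSet.unflatten(theta, arch), config)
        if not np.isfinite(c):
            raise FloatingPointError("cost became non-finite during training")
        trace.append(c)

    # tight tolerances: with a small output-layer initialization the early
    # iterations sit on a flat plateau and the scipy defaults declare
    # convergence prematurely
    res = minimize(_cost_and_grad, init_weights.flatten(),
                   args=(X, Y, arch, config), jac=True, method="L-BFGS-B",
                   callback=cb, options={"maxiter": config.max_iter,
                                         "ftol": 1e-13, "gtol": 1e-10})
    final = WeightSet.unflatten(res.x, arch)
    init_cost = joint_cost(X, Y, init_weights, config)
    final_cost = joint_cost(X, Y, final, config)
    if final_cost > init_cost:
        final = init_weights.copy()  # optimizer may only improve on the init
        final_cost = init_cost
    info = {"trace": trace, "init_cost": init_cost, "final_cost": final_cost,
            "n_iter": res.nit, "converged": bool(res.success)}
    return final, info


# ---------------------------------------------------------------------------
# target normalization and model container

def normalize_targets(lambdas: np.ndarray, prior_bounds) -> np.ndarray:
    """Affine map of each size scaling factor onto [0,1] by its prior
    bounds; values outside the prior pass through (they flag
    misspecification downstream)."""
    lam = np.atleast_2d(np.asarray(lambdas, dtype=float))
    bounds = np.asarray(prior_bounds, dtype=float)
    return (lam - bounds[:, 0]) / (bounds[:, 1] - bounds[:, 0])


def denormalize_targets(normalized: np.ndarray, prior_bounds) -> np.ndarray:
    z = np.atleast_2d(np.asarray(normalized, dtype=float))
    bounds = np.asarray(prior_bounds, dtype=float)
    return z * (bounds[:, 1] - bounds[:, 0]) + bounds[:, 0]


def feature_checksum(names) -> str:
    return hashlib.md5("\n".join(names).encode()).hexdigest()


@dataclass
class Model:
    arch: Architecture
    weights: WeightSet
    config: TrainConfig
    N_ref: float = 100_000.0
    feature_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def checksum(self) -> str:
        return feature_checksum(self.feature_names)

    def save(self, path: str | Path) -> None:
        header = json.dumps({
            "format": "demosel-model", "version": 1,
            "hidden": list(self.arch.hidden),
            "n_inputs": self.arch.n_inputs,
            "prior_bounds": [list(b) for b in self.config.prior_bounds],
            "lambda_decay": self.config.lambda_decay,
            "rho": self.config.rho, "beta": self.config.beta,
            "seed": self.config.seed, "N_ref": self.N_ref,
            "feature_names": list(self.feature_names),
            "feature_checksum": self.checksum,
        })
        arrays = {f"W{l}": w for l, w in enumerate(self.weights.W)}
        arrays.update({f"b{l}": v for l, v in enumerate(self.weights.b)})
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @staticmethod
    def load(path: str | Path) -> "Model":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            if header.get("format") != "demosel-model":
                raise ValueError("not a demosel model file")
            n_layers = len(header["hidden"]) + 1
            W = [data[f"W{l}"] for l in range(n_layers)]
            b = [data[f"b{l}"] for l in range(n_layers)]
        arch = Architecture(header["n_inputs"], tuple(header["hidden"]))
        cfg = TrainConfig(lambda_decay=header["lambda_decay"],
                          rho=header["rho"], beta=header["beta"],
                          seed=header["seed"],
                          prior_bounds=tuple(tuple(x) for x
                                             in header["prior_bounds"]))
        return Model(arch, WeightSet(W, b), cfg, header["N_ref"],
                     tuple(header["feature_names"]))


def train_model(X: np.ndarray, Y: np.ndarray, arch: Architecture,
                config: TrainConfig, *, pretrain: bool = True,
                N_ref: float = 100_000.0, feature_names=()) -> tuple[Model, dict]:
    """Pretrain (optionally) and fine-tune; returns the model and the
    fine-tuning info dict."""
    if pretrain:
        init = pretrain_stack(X, arch, config)
    else:
        init = random_init(arch, config.seed)
    weights, info = fine_tune(X, Y, init, config, arch)
    return Model(arch, weights, config, N_ref, tuple(feature_names)), info
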