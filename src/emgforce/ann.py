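"""Feed-forward network baseline trained by batch Levenberg-Marquardt.

Architecture: one hidden layer of 7 tangent-sigmoid neurons, linear output
layer, 4 output neurons.  Inputs are the preprocessed EMG envelopes plus
two lagged samples per channel (9 features for 3 channels).  When there
are fewer force targets than output neurons, the surplus outputs are
trained against zero and dropped at reporting time.

Levenberg-Marquardt is implemented directly on the full-batch residual
Jacobian: solve (J'J + lambda I) delta = -J'r, accept the step if the loss
decreases (then divide the damping by ``damping_factor``), otherwise
reject and multiply it.  With very large damping the step collapses to a
small gradient-descent step; with small damping it approaches Gauss-Newton.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signals import SignalTrace

__all__ = [
    "MLPConfig",
    "MLPWeights",
    "mlp_init",
    "mlp_forward",
    "residual_jacobian",
    "mlp_train_lm",
    "build_lag_features",
    "ann_estimate",
]


@dataclass(frozen=True)
class MLPConfig:
    """Network and training settings (counts must all be >= 1)."""

    n_inputs: int = 9
    n_hidden: int = 7
    n_outputs: int = 4
    damping0: float = 1e-2
    damping_factor: float = 10.0
    damping_max: float = 1e12
    max_iter: int = 200
    tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValueError("layer sizes must all be >= 1")


@dataclass
class MLPWeights:
    """Structured weights with an exact flat-vector round trip."""

    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_outputs, n_hidden)
    b2: np.ndarray  # (n_outputs,)

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2.ravel(), self.b2])

    def from_flat(self, theta: np.ndarray) -> "MLPWeights":
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError("flat vector length mismatch")
        h, i = self.W1.shape
        o = self.W2.shape[0]
        k = 0
        W1 = theta[k:k + h * i].reshape(h, i); k += h * i
        b1 = theta[k:k + h]; k += h
        W2 = theta[k:k + o * h].reshape(o, h); k += o * h
        b2 = theta[k:]
        return MLPWeights(W1=W1, b1=b1, W2=W2, b2=b2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {k: getattr(self, k).tolist() for k in ("W1", "b1", "W2", "b2")}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MLPWeights":
        d = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


def mlp_init(config: MLPConfig, scale: float = 1.0) -> MLPWeights:
    """Seeded uniform initialisation scaled by 1/sqrt(fan-in)."""
    rng = np.random.default_rng(config.seed)
    a1 = scale / np.sqrt(config.n_inputs)
    a2 = scale / np.sqrt(config.n_hidden)
    return MLPWeights(
        W1=rng.uniform(-a1, a1, size=(config.n_hidden, config.n_inputs)),
        b1=rng.uniform(-a1, a1, size=config.n_hidden),
        W2=rng.uniform(-a2, a2, size=(config.n_outputs, config.n_hidden)),
        b2=rng.uniform(-a2, a2, size=config.n_outputs),
    )


def mlp_forward(weights: MLPWeights, X: np.ndarray) -> np.ndarray:
    """Forward pass Y = W2 tanh(W1 x + b1) + b2, row-wise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != weights.W1.shape[1]:
        raise ValueError(f"expected {weights.W1.shape[1]} input columns, "
                         f"got {X.shape[1]}")
    A = np.tanh(X @ weights.W1.T + weights.b1)
    return A @ weights.W2.T + weights.b2


def residual_jacobian(weights: MLPWeights, X: np.ndarray,
                      Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual vector r = vec(Yhat - Y) and its Jacobian wrt the flat weights.

    Rows of the Jacobian are ordered sample-major, output-minor, matching
    ``r.ravel()``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, ni = X.shape
    h = weights.W1.shape[0]
    o = weights.W2.shape[0]
    A = np.tanh(X @ weights.W1.T + weights.b1)          # (n, h)
    Yhat = A @ weights.W2.T + weights.b2
    r = (Yhat - Y).ravel()
    D = 1.0 - A**2                                       # tanh' at hidden pre-act

    J = np.empty((n * o, weights.n_params))
    # dr/dW1[hid, in] = W2[out, hid] * D[n, hid] * X[n, in]
    G = weights.W2[None, :, :] * D[:, None, :]           # (n, o, h)
    J[:, : h * ni] = (G[:, :, :, None] * X[:, None, None, :]).reshape(n * o, h * ni)
    J[:, h * ni: h * ni + h] = G.reshape(n * o, h)       # dr/db1
    k = h * ni + h
    # dr/dW2[out, hid] = A[n, hid] for the matching output row, else 0
    block = np.zeros((n, o, o, h))
    rows = np.arange(o)
    block[:, rows, rows, :] = A[:, None, :]
    J[:, k: k + o * h] = block.reshape(n * o, o * h)
    k += o * h
    J[:, k:] = np.tile(np.eye(o), (n, 1))                # dr/db2
    return r, J


def mlp_train_lm(
    weights: MLPWeights,
    X: np.ndarray,
    Y: np.ndarray,
    config: MLPConfig | None = None,
) -> tuple[MLPWeights, list[dict]]:
    """Batch Levenberg-Marquardt training.

    Returns the trained weights and a history of dicts (iteration, loss,
    damping, accepted); the loss over accepted steps is non-increasing by
    construction.  Raises if the damped system stays singular up to the
    damping bound.
    """
    config = config or MLPConfig(n_inputs=np.atleast_2d(X).shape[1])
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to train")
    theta = weights.to_flat()
    w = weights
    r, J = residual_jacobian(w, X, Y)
    loss = 0.5 * float(r @ r)
    lam = config.damping0
    history = [{"iteration": 0, "loss": loss, "damping": lam, "accepted": True}]

    JtJ = J.T @ J
    g = J.T @ r
    for it in range(1, config.max_iter + 1):
        solved = False
        while lam <= config.damping_max:
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(theta.size), -g)
                if np.all(np.isfinite(delta)):
                    solved = True
                    break
            except np.linalg.LinAlgError:
                pass
            lam *= config.damping_factor
        if not solved:
            raise RuntimeError("LM system singular even at maximum damping")

        theta_new = theta + delta
        w_new = w.from_flat(theta_new)
        r_new = (mlp_forward(w_new, X) - Y).ravel()
        loss_new = 0.5 * float(r_new @ r_new)
        if loss_new < loss:
            improvement = loss - loss_new
            theta, w, loss = theta_new, w_new, loss_new
            lam = max(lam / config.damping_factor, 1e-15)
            history.append({"iteration": it, "loss": loss, "damping": lam,
                            "accepted": True})
            r, J = residual_jacobian(w, X, Y)
            JtJ = J.T @ J
            g = J.T @ r
            if improvement < config.tol * (1.0 + loss):
                break
        else:
            lam *= config.damping_factor
            history.append({"iteration": it, "loss": loss, "damping": lam,
                            "accepted": False})
            if lam > config.damping_max:
                break
    return w, history


def build_lag_features(envelopes: list[SignalTrace] | list[np.ndarray],
                       lags: tuple[int, ...] = (0, 50, 100)) -> np.ndarray:
    """Stack current + lagged envelope samples into a feature matrix.

    Lag l contributes x(k - l), with the record edge padded by the first
    sample.  Default lags (0, 50, 100) samples = current plus 50 ms and
    100 ms of history per channel at 1 kHz.
    """
    cols = []
    for env in envelopes:
        x = env.samples if isinstance(env, SignalTrace) else np.asarray(env, dtype=float)
        for l in lags:
            if l == 0:
                cols.append(x)
            else:
                cols.append(np.concatenate([np.full(l, x[0]), x[:-l]]))
    return np.column_stack(cols)


def ann_estimate(
    weights: MLPWeights,
    envelopes: list[SignalTrace],
    n_force_outputs: int = 2,
    lags: tuple[int, ...] = (0, 50, 100),
) -> list[SignalTrace]:
    """Predict force traces from preprocessed EMG envelopes.

    The first ``n_force_outputs`` network outputs are returned as traces;
    surplus outputs (trained against zero) are dropped.
    """
    X = build_lag_features(envelopes, lags=lags)
    Y = mlp_forward(weights, X)
    fs = envelopes[0].fs
    n_out = min(n_force_outputs, Y.shape[1])
    return [SignalTrace(Y[:, j], fs=fs, label=f"F_ann{j + 1}", kind="normalised")
            for j in range(n_out)]
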