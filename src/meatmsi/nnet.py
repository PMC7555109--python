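"""Two-hidden-layer perceptron trained by Levenberg-Marquardt.

The network is deliberately small (10 PLS scores -> n1 -> n2 -> 1, tanh
hidden units, linear output), so the full Jacobian of the residual vector
with respect to the weights is cheap to form and the damped Gauss-Newton
(Levenberg-Marquardt) step can be solved exactly each epoch.  An epoch is
one *accepted* LM step, so the training loss is monotone non-increasing by
construction.  Early stopping tracks validation RMSE with a patience
counter and the weights from the best-validation epoch are restored — the
classic feed-forward regression recipe in chemometrics toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ANNConfig:
    """Architecture and training options for one network."""

    n1l: int
    n2l: int
    max_epochs: int = 1000
    seed: int = 0
    patience: int = 6
    hidden_activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.n1l < 1 or self.n2l < 1:
            raise ValueError("hidden layer sizes must be >= 1")
        if not 1 <= self.max_epochs <= 1000:
            raise ValueError("max_epochs must be in 1..1000")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.hidden_activation != "tanh":
            raise ValueError("only tanh hidden units are implemented")


class TwoHiddenLayerNet:
    """10-n1-n2-1 feed-forward regressor with internal y standardization."""

    def __init__(self, n_inputs: int, config: ANNConfig):
        self.n_inputs = n_inputs
        self.config = config
        rng = np.random.default_rng(config.seed)
        n1, n2 = config.n1l, config.n2l
        self.W1 = rng.uniform(-1, 1, (n1, n_inputs)) / np.sqrt(n_inputs)
        self.b1 = rng.uniform(-0.5, 0.5, n1)
        self.W2 = rng.uniform(-1, 1, (n2, n1)) / np.sqrt(n1)
        self.b2 = rng.uniform(-0.5, 0.5, n2)
        self.w3 = rng.uniform(-1, 1, n2) / np.sqrt(n2)
        self.b3 = 0.0
        self.y_mean = 0.0
        self.y_scale = 1.0
        self.epoch_at_best: int = 0

    # -- forward ---------------------------------------------------------
    def _forward(self, X: np.ndarray):
        Z1 = np.tanh(X @ self.W1.T + self.b1)
        Z2 = np.tanh(Z1 @ self.W2.T + self.b2)
        yhat = Z2 @ self.w3 + self.b3
        return Z1, Z2, yhat

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict in original y units."""
        X = np.asarray(X, dtype=float)
        return self._forward(X)[2] * self.y_scale + self.y_mean

    # -- weight vector packing -------------------------------------------
    def _get_theta(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2.ravel(),
                               self.b2, self.w3, [self.b3]])

    def _set_theta(self, theta: np.ndarray) -> None:
        n1, n2, ni = self.config.n1l, self.config.n2l, self.n_inputs
        i = 0
        self.W1 = theta[i:i + n1 * ni].reshape(n1, ni); i += n1 * ni
        self.b1 = theta[i:i + n1]; i += n1
        self.W2 = theta[i:i + n2 * n1].reshape(n2, n1); i += n2 * n1
        self.b2 = theta[i:i + n2]; i += n2
        self.w3 = theta[i:i + n2]; i += n2
        self.b3 = float(theta[i])

    def _jacobian(self, X: np.ndarray):
        """d yhat_i / d theta for every sample (n x n_params)."""
        Z1, Z2, yhat = self._forward(X)
        n = X.shape[0]
        d_b3 = np.ones((n, 1))
        d_w3 = Z2
        dA2 = (1.0 - Z2 ** 2) * self.w3          # n x n2
        d_W2 = np.einsum("nj,nk->njk", dA2, Z1).reshape(n, -1)
        d_b2 = dA2
        dA1 = (dA2 @ self.W2) * (1.0 - Z1 ** 2)  # n x n1
        d_W1 = np.einsum("nj,nk->njk", dA1, X).reshape(n, -1)
        d_b1 = dA1
        J = np.concatenate([d_W1, d_b1, d_W2, d_b2, d_w3, d_b3], axis=1)
        return J, yhat


def train_ann(scores_train: np.ndarray, y_train: np.ndarray,
              scores_val: np.ndarray, y_val: np.ndarray,
              config: ANNConfig) -> tuple[TwoHiddenLayerNet, int]:
    """Train a 10-n1-n2-1 network by Levenberg-Marquardt with early stop.

    Targets are standardized to zero mean / unit variance on the training
    set (for conditioning) and back-transformed at prediction time.  Each
    epoch solves (J'J + lambda I) delta = -J'r and accepts the step only if
    the training SSE decreases, adapting lambda by factors of 10.  Training
    stops at ``max_epochs``, when validation RMSE has not improved for
    ``patience`` accepted epochs, or when lambda overflows.  Returns the
    network holding the best-validation weights and the epoch they were
    recorded at (0 = the untrained initialization was never beaten).
    """
    X = np.asarray(scores_train, dtype=float)
    Xv = np.asarray(scores_val, dtype=float)
    y = np.asarray(y_train, dtype=float)
    yv = np.asarray(y_val, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("scores_train and y_train sizes disagree")

    net = TwoHiddenLayerNet(X.shape[1], config)
    net.y_mean = float(y.mean())
    sd = float(y.std())
    net.y_scale = sd if sd > 0 else 1.0
    ys = (y - net.y_mean) / net.y_scale
    yvs = (yv - net.y_mean) / net.y_scale

    def val_rmse() -> float:
        r = net._forward(Xv)[2] - yvs
        return float(np.sqrt(np.mean(r ** 2)))

    lam = 1e-3
    sse = float(np.sum((net._forward(X)[2] - ys) ** 2))
    best_val = val_rmse()
    best_theta = net._get_theta()
    best_epoch = 0
    fails = 0
    n_params = best_theta.size
    eye = np.eye(n_params)

    for epoch in range(1, config.max_epochs + 1):
        J, yhat = net._jacobian(X)
        r = yhat - ys
        if not np.all(np.isfinite(r)):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch} "
                f"(n1l={config.n1l}, n2l={config.n2l}, seed={config.seed})")
        g = J.T @ r
        H = J.T @ J
        theta = net._get_theta()
        accepted = False
        while lam <= 1e10:
            try:
                delta = np.linalg.solve(H + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            net._set_theta(theta + delta)
            new_sse = float(np.sum((net._forward(X)[2] - ys) ** 2))
            if np.isfinite(new_sse) and new_sse < sse:
                sse = new_sse
                lam = max(lam / 10, 1e-12)
                accepted = True
                break
            lam *= 10
        if not accepted:
            net._set_theta(theta)
            break
        v = val_rmse()
        if v < best_val - 1e-15:
            best_val = v
            best_theta = net._get_theta()
            best_epoch = epoch
            fails = 0
        else:
            fails += 1
            if fails >= config.patience:
                break
        if sse <= 1e-20:
            break

    net._set_theta(best_theta)
    net.epoch_at_best = best_epoch
    return net, best_epoch
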