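"""Sequential network with a sigmoid head, Adam optimizer and BCE loss."""

from __future__ import annotations

import numpy as np

from .layers import Dense, Layer

__all__ = ["Network"]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Network:
    """Feature trunk + sigmoid classification head.

    ``trunk`` layers map input to the feature representation whose output
    downstream classifiers consume (the penultimate-activation convention);
    ``head`` is the final Dense(·, 1) producing the activity logit.
    """

    def __init__(self, trunk: list[Layer], head: Dense, feature_dim: int):
        self.trunk = trunk
        self.head = head
        self.feature_dim = feature_dim
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    # ---- inference -------------------------------------------------
    def features(self, x: np.ndarray) -> np.ndarray:
        for layer in self.trunk:
            x = layer.forward(x)
        return x

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.features(x))[:, 0]

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for lo in range(0, x.shape[0], batch_size):
            z = self.logits(x[lo : lo + batch_size])
            out.append(1.0 / (1.0 + np.exp(-np.clip(z, -40, 40))))
        return np.concatenate(out) if out else np.zeros(0)

    def predict(self, x: np.ndarray, cut: float = 0.5) -> np.ndarray:
        return (self.predict_proba(x) >= cut).astype(int)

    # ---- training --------------------------------------------------
    def params(self):
        out = []
        for layer in self.trunk:
            out.extend(layer.params())
        out.extend(self.head.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p, _ in self.params())

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        lr: float,
        seed: int = 0,
    ) -> "Network":
        """Minibatch Adam on binary cross-entropy; seeded shuffling.

        Raises on non-binary labels and on a NaN loss (reported with the
        epoch it appeared in).  ``epochs=0`` leaves the weights untouched.
        """
        y = np.asarray(y)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        y = y.astype(float)
        n = x.shape[0]
        rng = np.random.default_rng(seed)
        opt = Adam(self.params(), lr=lr)
        for epoch in range(epochs):
            order = rng.permutation(n)
            total_loss = 0.0
            correct = 0
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                xb, yb = x[idx], y[idx]
                z = self.logits(xb)
                # BCE with logits: softplus(z) - y*z, mean over batch
                loss = float(np.mean(_softplus(z) - yb * z))
                if np.isnan(loss):
                    raise FloatingPointError(f"NaN loss at epoch {epoch + 1}")
                p = 1.0 / (1.0 + np.exp(-np.clip(z, -40, 40)))
                dz = (p - yb) / len(idx)
                grad = self.head.backward(dz[:, None])
                for layer in reversed(self.trunk):
                    grad = layer.backward(grad)
                opt.step()
                total_loss += loss * len(idx)
                correct += int(np.sum((p >= 0.5) == yb))
            self.history["loss"].append(total_loss / n)
            self.history["accuracy"].append(correct / n)
        return self
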