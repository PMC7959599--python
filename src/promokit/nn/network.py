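"""Sequential network with Adam, mini-batch training and early stopping.

The final layer of a network emits raw logits; the loss couples the output
non-linearity (sigmoid for binary cross-entropy, softmax for sparse
categorical cross-entropy) with the loss for numerical stability, exactly
as the fused implementations in mainstream frameworks do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Dropout, Layer

__all__ = ["Sequential", "TrainingHistory"]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None

    @property
    def n_epochs_run(self) -> int:
        return len(self.loss)


class Sequential:
    """A plain layer stack for binary or multiclass sequence classification.

    Parameters
    ----------
    layers : list of Layer
        The stack; the last layer must output logits with 1 unit (binary)
        or ``n_classes`` units (multiclass).
    loss : {"bce", "sce"}
        Binary cross-entropy (with sigmoid) or sparse categorical
        cross-entropy (with softmax).
    """

    def __init__(self, layers: list[Layer], loss: str):
        if loss not in {"bce", "sce"}:
            raise ValueError("loss must be 'bce' or 'sce'")
        self.layers = layers
        self.loss = loss
        self._adam_m: list[np.ndarray] | None = None
        self._adam_v: list[np.ndarray] | None = None
        self._adam_buf: list[np.ndarray] | None = None
        self._adam_t = 0

    # ------------------------------------------------------------------ core
    def _forward(self, X, training: bool):
        out = X
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        """Class probabilities: (B,) for binary, (B, C) for multiclass."""
        chunks = []
        for i in range(0, len(X), batch_size):
            logits = self._forward(X[i : i + batch_size], training=False)
            if self.loss == "bce":
                chunks.append(_sigmoid(logits[:, 0]))
            else:
                chunks.append(_softmax(logits))
        return np.concatenate(chunks, axis=0)

    def _loss_and_grad(self, logits, y):
        n = len(y)
        if self.loss == "bce":
            z = logits[:, 0]
            # log(1 + e^-|z|) formulation is overflow-safe
            loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
            dlogits = ((_sigmoid(z) - y) / n)[:, None].astype(np.float32)
        else:
            p = _softmax(logits)
            loss = -np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None)))
            dlogits = p
            dlogits[np.arange(n), y] -= 1.0
            dlogits = (dlogits / n).astype(np.float32)
        return float(loss), dlogits

    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        params = [p for layer in self.layers for p in layer.params]
        grads = [g for layer in self.layers for g in layer.grads]
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(p) for p in params]
            self._adam_v = [np.zeros_like(p) for p in params]
            self._adam_buf = [np.empty_like(p) for p in params]
        self._adam_t += 1
        t = self._adam_t
        # bias-corrected step size; update arrays in place to avoid temporaries
        lr_t = lr * np.sqrt(1 - beta2**t) / (1 - beta1**t)
        eps_t = eps * np.sqrt(1 - beta2**t)
        for p, g, m, v, buf in zip(
            params, grads, self._adam_m, self._adam_v, self._adam_buf
        ):
            m *= beta1
            m += (1 - beta1) * g
            np.multiply(g, g, out=buf)
            v *= beta2
            buf *= 1 - beta2
            v += buf
            np.sqrt(v, out=buf)
            buf += eps_t
            np.divide(m, buf, out=buf)
            buf *= lr_t
            p -= buf

    def evaluate(self, X, y, batch_size: int = 256) -> tuple[float, float]:
        """Mean loss and accuracy without updating weights."""
        total_loss = 0.0
        correct = 0
        for i in range(0, len(X), batch_size):
            xb, yb = X[i : i + batch_size], y[i : i + batch_size]
            logits = self._forward(xb, training=False)
            loss, _ = self._loss_and_grad(logits, yb)
            total_loss += loss * len(yb)
            if self.loss == "bce":
                pred = (_sigmoid(logits[:, 0]) >= 0.5).astype(np.int64)
            else:
                pred = logits.argmax(axis=1)
            correct += int((pred == yb).sum())
        return total_loss / len(y), correct / len(y)

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        X,
        y,
        val_X,
        val_y,
        epochs: int = 10,
        batch_size: int = 128,
        learning_rate: float = 1e-3,
        patience: int | None = 2,
        seed: int = 0,
        verbose: bool = False,
    ) -> TrainingHistory:
        """Mini-batch Adam training with early stopping on validation loss.

        Stops when validation loss has not improved for ``patience``
        consecutive epochs (``patience=None`` disables early stopping,
        which then also permits an empty validation set).
        """
        if patience is not None and (val_X is None or len(val_X) == 0):
            raise ValueError("early stopping requires a non-empty validation set")
        y = np.asarray(y, dtype=np.int64)
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng
        history = TrainingHistory()
        best_val = np.inf
        stale = 0
        for epoch in range(epochs):
            order = rng.permutation(len(X))
            epoch_loss = 0.0
            correct = 0
            for i in range(0, len(X), batch_size):
                idx = order[i : i + batch_size]
                xb, yb = X[idx], y[idx]
                logits = self._forward(xb, training=True)
                loss, dlogits = self._loss_and_grad(logits, yb)
                epoch_loss += loss * len(yb)
                if self.loss == "bce":
                    pred = (logits[:, 0] >= 0.0).astype(np.int64)
                else:
                    pred = logits.argmax(axis=1)
                correct += int((pred == yb).sum())
                grad = dlogits
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                self._adam_step(learning_rate)
            history.loss.append(epoch_loss / len(y))
            history.acc.append(correct / len(y))
            if val_X is not None and len(val_X):
                vl, va = self.evaluate(val_X, val_y, batch_size=batch_size)
                history.val_loss.append(vl)
                history.val_acc.append(va)
                if verbose:
                    print(
                        f"epoch {epoch + 1}: loss={history.loss[-1]:.4f} "
                        f"acc={history.acc[-1]:.4f} val_loss={vl:.4f} val_acc={va:.4f}"
                    )
                if patience is not None:
                    if vl < best_val - 1e-6:
                        best_val = vl
                        stale = 0
                    else:
                        stale += 1
                        if stale >= patience:
                            history.stopped_epoch = epoch + 1
                            break
        return history
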