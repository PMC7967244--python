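"""NumPy implementation of the N-Net / MSN-Net classifier.

The computation graph follows :mod:`minet.network` exactly: independent
per-lead branches, per-scale paths of learnable-pooling + two valid kernel-3
convolutions (ReLU), global average pooling, feature concatenation, dropout,
and a softmax head, trained with Adam on categorical cross-entropy.

Lead branches are vectorized: each layer's weights carry a leading lead axis
and a single lead-batched GEMM evaluates all 12 branches at once.  Training
is deterministic given the initialization seed and the data order.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .network import ModelConfig, build_model_spec


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


@dataclass
class _ConvLayer:
    W: np.ndarray  # (leads, F, cin, K)
    b: np.ndarray  # (leads, F)
    stride: int


class NNetClassifier:
    """Estimator-style wrapper around the multi-lead multi-scale CNN.

    Parameters
    ----------
    config : ModelConfig
        Architecture hyperparameters (scales, filters, classes, ...).
    seed : int
        Seeds weight initialization and dropout; identical (config, seed,
        data, order) reproduces training exactly.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.spec = build_model_spec(config)
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
        L, F, P = config.num_leads, config.num_filters, config.pooling_factor

        self.paths: list[list[_ConvLayer]] = []
        for s in range(1, config.num_scales + 1):
            layers: list[_ConvLayer] = []
            cin = 1
            for _ in range(s - 1):
                layers.append(_ConvLayer(
                    W=_glorot(rng, (L, F, cin, P), cin * P, F * P),
                    b=np.zeros((L, F), dtype=np.float32),
                    stride=P,
                ))
                cin = F
            for _ in range(2):
                layers.append(_ConvLayer(
                    W=_glorot(rng, (L, F, cin, 3), cin * 3, F * 3),
                    b=np.zeros((L, F), dtype=np.float32),
                    stride=1,
                ))
                cin = F
            self.paths.append(layers)

        width = config.feature_width
        self.head_W = _glorot(rng, (width, config.num_classes), width, config.num_classes)
        self.head_b = np.zeros(config.num_classes, dtype=np.float32)
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))

    # -- parameters -------------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        params = []
        for path in self.paths:
            for layer in path:
                params.extend([layer.W, layer.b])
        params.extend([self.head_W, self.head_b])
        return params

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward / backward ----------------------------------------------

    # Activations flow in (leads, channels, batch, time) layout so that each
    # convolution is a single lead-batched GEMM on contiguous matrices.

    @staticmethod
    def _conv_forward(Z, layer: _ConvLayer):
        L, C, B, T = Z.shape
        K, stride = layer.W.shape[-1], layer.stride
        t_out = (T - K) // stride + 1
        win = np.empty((L, C, K, B, t_out), dtype=Z.dtype)
        for k in range(K):
            win[:, :, k] = Z[:, :, :, k : k + t_out * stride : stride]
        win_m = win.reshape(L, C * K, B * t_out)
        w_m = layer.W.reshape(L, layer.W.shape[1], C * K)
        pre = np.matmul(w_m, win_m).reshape(L, -1, B, t_out)
        pre += layer.b[:, :, None, None]
        mask = pre > 0
        return pre * mask, (win_m, mask, Z.shape)

    @staticmethod
    def _conv_backward(dY, layer: _ConvLayer, cache):
        win_m, mask, z_shape = cache
        L, C, B, T = z_shape
        K, stride = layer.W.shape[-1], layer.stride
        F, t_out = dY.shape[1], dY.shape[3]
        dY = dY * mask
        dy_m = dY.reshape(L, F, B * t_out)
        dW = np.matmul(dy_m, win_m.transpose(0, 2, 1)).reshape(layer.W.shape)
        db = dY.sum(axis=(2, 3))
        w_m = layer.W.reshape(L, F, C * K)
        dwin = np.matmul(w_m.transpose(0, 2, 1), dy_m).reshape(L, C, K, B, t_out)
        dZ = np.zeros(z_shape, dtype=dY.dtype)
        for k in range(K):
            dZ[:, :, :, k : k + t_out * stride : stride] += dwin[:, :, k]
        return dZ, dW, db

    def _forward(self, X, train=False):
        """X: (B, leads, L) -> probabilities (B, C) plus caches."""
        B = X.shape[0]
        X = np.asarray(X)
        if X.dtype != np.float64:  # float64 inputs keep full precision
            X = X.astype(np.float32)
        Z0 = np.ascontiguousarray(X.transpose(1, 0, 2))
        Z0 = Z0[:, None, :, :]  # (leads, 1, B, T)
        caches, feats = [], []
        for path in self.paths:
            Z = Z0
            path_caches = []
            for layer in path:
                Z, cache = self._conv_forward(Z, layer)
                path_caches.append(cache)
            t_len = Z.shape[3]
            feats.append(Z.mean(axis=3))  # GAP -> (leads, F, B)
            caches.append((path_caches, t_len))
        # concatenation order: lead-major, then scale, then filter
        feat = np.stack(feats, axis=1).transpose(3, 0, 1, 2).reshape(B, -1)

        drop_mask = None
        if train and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            drop_mask = (self._dropout_rng.random(feat.shape) < keep).astype(np.float32)
            drop_mask /= np.float32(keep)
            feat = feat * drop_mask

        logits = feat @ self.head_W + self.head_b
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        return probs, (caches, feat, drop_mask)

    def _backward(self, probs, y_onehot, cache):
        caches, feat, drop_mask = cache
        B = probs.shape[0]
        cfg = self.config
        dlogits = (probs - y_onehot) / B
        grads = {}
        grads["head_W"] = feat.T @ dlogits
        grads["head_b"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.head_W.T
        if drop_mask is not None:
            dfeat = dfeat * drop_mask
        dfeat = dfeat.reshape(B, cfg.num_leads, cfg.num_scales, cfg.num_filters)
        dfeat = dfeat.transpose(1, 2, 3, 0)  # (leads, S, F, B)

        conv_grads = []
        for p, (path, (path_caches, t_len)) in enumerate(zip(self.paths, caches)):
            # GAP backward: spread the gradient uniformly over time
            dZ = np.broadcast_to(
                (dfeat[:, p] / t_len)[:, :, :, None],
                (cfg.num_leads, cfg.num_filters, B, t_len),
            )
            path_grads = []
            for layer, layer_cache in zip(reversed(path), reversed(path_caches)):
                dZ, dW, db = self._conv_backward(dZ, layer, layer_cache)
                path_grads.append((dW, db))
            conv_grads.append(list(reversed(path_grads)))
        grads["conv"] = conv_grads
        return grads

    # -- training ---------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        learning_rate: float = 0.001,
        batch_size: int = 300,
        max_epochs: int = 200,
        patience: int = 20,
        monitor: str = "train_loss",
        order: np.ndarray | None = None,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        restore_best: bool = True,
    ) -> dict[str, list[float]]:
        """Train with Adam; early-stop when the monitored quantity fails to
        improve (strictly) for ``patience`` consecutive epochs.

        ``order`` is a fixed sample permutation reused every epoch (kept
        identical across model configurations to pin the data input order);
        default is the natural order.  Returns the per-epoch history and
        leaves the best-monitored-epoch weights in place.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if y.max() >= self.config.num_classes:
            raise ValueError(
                f"label {y.max()} out of range for {self.config.num_classes} classes"
            )
        if patience >= max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        n = X.shape[0]
        order = np.arange(n) if order is None else np.asarray(order, dtype=int)
        if order.shape != (n,):
            raise ValueError("order must be a permutation of the training set")
        onehot = np.eye(self.config.num_classes, dtype=np.float32)[y]

        params = self.parameters()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        step = 0

        history: dict[str, list[float]] = {
            "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        }
        best_value = np.inf
        best_weights = None
        mode = -1.0 if monitor.endswith("acc") else 1.0  # maximize accuracies
        since_improve = 0

        for _epoch in range(max_epochs):
            losses, hits = [], 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                probs, cache = self._forward(X[idx], train=True)
                p_true = np.clip(probs[np.arange(idx.size), y[idx]], 1e-12, None)
                losses.append(float(-np.mean(np.log(p_true))) * idx.size)
                hits += int((probs.argmax(axis=1) == y[idx]).sum())
                grads = self._backward(probs, onehot[idx], cache)

                flat = []
                for path_grads in grads["conv"]:
                    for dW, db in path_grads:
                        flat.extend([dW, db])
                flat.extend([grads["head_W"], grads["head_b"]])
                step += 1
                lr_t = learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for p, g, mi, vi in zip(params, flat, m, v):
                    mi[...] = beta1 * mi + (1 - beta1) * g
                    vi[...] = beta2 * vi + (1 - beta2) * g * g
                    p -= lr_t * mi / (np.sqrt(vi) + eps)

            history["train_loss"].append(sum(losses) / n)
            history["train_acc"].append(hits / n)
            if validation is not None:
                vl, va = self.evaluate(*validation)
                history["val_loss"].append(vl)
                history["val_acc"].append(va)

            value = mode * history[monitor][-1]
            if value < best_value:
                best_value = value
                since_improve = 0
                if restore_best:
                    best_weights = self.get_weights()
            else:
                since_improve += 1
                if since_improve >= patience:
                    break

        if restore_best and best_weights is not None:
            self.set_weights(best_weights)
        return history

    # -- inference --------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = []
        for start in range(0, X.shape[0], batch_size):
            probs, _ = self._forward(X[start : start + batch_size], train=False)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        probs = self.predict_proba(X)
        y = np.asarray(y, dtype=int)
        p_true = np.clip(probs[np.arange(y.size), y], 1e-12, None)
        loss = float(-np.mean(np.log(p_true)))
        acc = float((probs.argmax(axis=1) == y).mean())
        return loss, acc

    def clone_untrained(self) -> "NNetClassifier":
        return NNetClassifier(copy.deepcopy(self.config), self.seed)
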