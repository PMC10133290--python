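"""Minimal numpy neural networks for the learned window-feature extractors.

Two small binary classifiers are trained on labeled 3-s windows and then
decapitated: the 5-unit penultimate layer of each provides the learned
features fed to the boosted-tree top layer.

* ``ConvExtractor`` - two blocks of (1-D convolution, batch norm, ReLU,
  max-pool) followed by a 3-layer MLP with output widths (16, 5, 1).
* ``RecurrentExtractor`` - a bidirectional LSTM layer (final hidden states
  of both directions) followed by the same (16, 5, 1) MLP.

Everything (forward, backward, Adam) is implemented here in numpy; the
layer gradients are verified against numerical differentiation in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvExtractor", "RecurrentExtractor", "train_extractor"]

PENULTIMATE_DIM = 5


def _sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
                    np.exp(np.clip(x, -500, 500))
                    / (1.0 + np.exp(np.clip(x, -500, 500))))


class Dense:
    def __init__(self, rng, d_in, d_out):
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(scale=scale, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=True):
        self.x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[:] = self.x.T @ g
        self.db[:] = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x, train=True):
        self.mask = x > 0
        return x * self.mask

    def backward(self, g):
        return g * self.mask

    def params(self):
        return []


class Conv1d:
    """Same-padding 1-D convolution, stride 1, via an im2col matmul."""

    def __init__(self, rng, c_in, c_out, k=5):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(scale=scale, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k

    def _im2col(self, x):
        n, c, length = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = np.empty((n, length, c * self.k))
        for t in range(self.k):
            cols[:, :, t::self.k] = xp[:, :, t:t + length].transpose(0, 2, 1)
        return cols  # layout: channel-major blocks of k taps

    def forward(self, x, train=True):
        self.x_shape = x.shape
        self.cols = self._im2col(x)  # (n, L, c*k)
        w2 = self.W.reshape(self.W.shape[0], -1)  # (c_out, c_in*k)
        y = self.cols @ w2.T + self.b  # (n, L, c_out)
        return y.transpose(0, 2, 1)

    def backward(self, g):
        g = g.transpose(0, 2, 1)  # (n, L, c_out)
        w2 = self.W.reshape(self.W.shape[0], -1)
        self.dW[:] = np.einsum("nlo,nlc->oc", g, self.cols).reshape(self.W.shape)
        self.db[:] = g.sum(axis=(0, 1))
        dcols = g @ w2  # (n, L, c*k)
        n, c, length = self.x_shape
        pad = self.k // 2
        dxp = np.zeros((n, c, length + 2 * pad))
        for t in range(self.k):
            dxp[:, :, t:t + length] += dcols[:, :, t::self.k].transpose(0, 2, 1)
        return dxp[:, :, pad:pad + length]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm1d:
    """Per-channel normalization over the batch and time axes."""

    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.std = np.sqrt(var + self.eps)[None, :, None]
        self.xhat = (x - mean[None, :, None]) / self.std
        self.m = x.shape[0] * x.shape[2]
        return self.gamma[None, :, None] * self.xhat + self.beta[None, :, None]

    def backward(self, g):
        self.dgamma[:] = (g * self.xhat).sum(axis=(0, 2))
        self.dbeta[:] = g.sum(axis=(0, 2))
        gx = g * self.gamma[None, :, None]
        return (gx - gx.mean(axis=(0, 2), keepdims=True)
                - self.xhat * (gx * self.xhat).mean(axis=(0, 2), keepdims=True)
                ) / self.std

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class MaxPool1d:
    def __init__(self, k=2):
        self.k = k

    def forward(self, x, train=True):
        n, c, length = x.shape
        trim = (length // self.k) * self.k
        self.x_shape = x.shape
        self.trim = trim
        xr = x[:, :, :trim].reshape(n, c, trim // self.k, self.k)
        self.arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, g):
        n, c, length = self.x_shape
        out = np.zeros((n, c, length))
        l_out = self.trim // self.k
        idx = (np.arange(l_out)[None, None, :] * self.k + self.arg)
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(out, (ni, ci, idx), g)
        return out

    def params(self):
        return []


class Flatten:
    def forward(self, x, train=True):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self.shape)

    def params(self):
        return []


class BiLSTM:
    """Bidirectional LSTM; output is the concatenated final hidden states."""

    def __init__(self, rng, d_in, hidden):
        self.hidden = hidden
        self.cells = [self._init_cell(rng, d_in, hidden) for _ in range(2)]

    @staticmethod
    def _init_cell(rng, d_in, h):
        scale = 1.0 / np.sqrt(h)
        return {
            "Wx": rng.normal(scale=scale, size=(d_in, 4 * h)),
            "Wh": rng.normal(scale=scale, size=(h, 4 * h)),
            "b": np.zeros(4 * h),
            "dWx": np.zeros((d_in, 4 * h)),
            "dWh": np.zeros((h, 4 * h)),
            "db": np.zeros(4 * h),
        }

    def _run(self, cell, x):
        n, T, _ = x.shape
        h = np.zeros((n, self.hidden))
        c = np.zeros((n, self.hidden))
        # input projections for all timesteps in one matmul
        xW = (x.reshape(n * T, -1) @ cell["Wx"]).reshape(n, T, -1)
        cache = []
        for t in range(T):
            z = xW[:, t] + h @ cell["Wh"] + cell["b"]
            i, f, g_, o = np.split(z, 4, axis=1)
            i, f, o = _sigmoid(i), _sigmoid(f), _sigmoid(o)
            g_ = np.tanh(g_)
            c_new = f * c + i * g_
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((h, c, i, f, g_, o, tanh_c))
            h, c = h_new, c_new
        return h, cache

    def _back(self, cell, cache, x, dh_final, dx, reverse):
        T = len(cache)
        n = dh_final.shape[0]
        dh = dh_final
        dc = np.zeros_like(dh)
        dz_all = np.empty((n, T, 4 * self.hidden))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g_, o, tanh_c = cache[t]
            do = dh * tanh_c
            dct = dc + dh * o * (1 - tanh_c**2)
            di = dct * g_
            dg = dct * i
            df = dct * c_prev
            dc = dct * f
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g_**2), do * o * (1 - o)], axis=1)
            dz_all[:, t] = dz
            cell["dWh"] += h_prev.T @ dz
            dh = dz @ cell["Wh"].T
        dz_flat = dz_all.reshape(n * T, -1)
        cell["dWx"] += x.reshape(n * T, -1).T @ dz_flat
        cell["db"] += dz_flat.sum(axis=0)
        dx_src = (dz_flat @ cell["Wx"].T).reshape(n, T, -1)
        dx += dx_src[:, ::-1] if reverse else dx_src
        return dx

    def forward(self, x, train=True):
        # x arrives as (n, channels, T); run over time with features per step
        x = x.transpose(0, 2, 1)
        self.x_fwd = x
        self.x_bwd = x[:, ::-1]
        h_f, self.cache_f = self._run(self.cells[0], self.x_fwd)
        h_b, self.cache_b = self._run(self.cells[1], self.x_bwd)
        return np.concatenate([h_f, h_b], axis=1)

    def backward(self, g):
        H = self.hidden
        for cell in self.cells:
            cell["dWx"][:] = 0
            cell["dWh"][:] = 0
            cell["db"][:] = 0
        dx = np.zeros_like(self.x_fwd)
        dx = self._back(self.cells[0], self.cache_f, self.x_fwd,
                        g[:, :H], dx, reverse=False)
        dx = self._back(self.cells[1], self.cache_b, self.x_bwd,
                        g[:, H:], dx, reverse=True)
        return dx.transpose(0, 2, 1)

    def params(self):
        out = []
        for cell in self.cells:
            out += [(cell["Wx"], cell["dWx"]), (cell["Wh"], cell["dWh"]),
                    (cell["b"], cell["db"])]
        return out


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for k, (p, g) in enumerate(self.params):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _ExtractorBase:
    """Shared training loop, penultimate feature access, prediction."""

    kind = "?"

    def __init__(self):
        self.layers: list = []
        self.trained = False
        self.norm_mean = None
        self.norm_sd = None

    def _forward(self, x, train=True, upto=None):
        h = x
        layers = self.layers if upto is None else self.layers[:upto]
        for layer in layers:
            h = layer.forward(h, train=train)
        return h

    def _backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def _params(self):
        return [pg for layer in self.layers for pg in layer.params()]

    def _normalize(self, x):
        return (x - self.norm_mean) / self.norm_sd

    default_lr = 1e-3

    def fit(self, x, y, epochs=10, batch_size=256, lr=None, seed=0,
            pos_weight=None, verbose=False):
        """Binary cross-entropy training on window tensors (n, ch, T)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set must contain both classes")
        self.norm_mean = x.mean(axis=(0, 2), keepdims=True)
        self.norm_sd = x.std(axis=(0, 2), keepdims=True)
        self.norm_sd[self.norm_sd == 0] = 1.0
        xn = self._normalize(x)
        if pos_weight is None:
            pos_weight = float((y == 0).sum() / max((y == 1).sum(), 1))
        rng = np.random.default_rng(seed)
        opt = Adam(self._params(), lr=self.default_lr if lr is None else lr)
        n = len(xn)
        self.loss_history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, batch_size):
                idx = order[lo:lo + batch_size]
                xb, yb = xn[idx], y[idx]
                logits = self._forward(xb, train=True).ravel()
                p = _sigmoid(logits)
                wts = np.where(yb == 1, pos_weight, 1.0)
                eps = 1e-12
                loss = -(wts * (yb * np.log(p + eps)
                                + (1 - yb) * np.log(1 - p + eps))).mean()
                g = (wts * (p - yb) / len(yb)).reshape(-1, 1)
                self._backward(g)
                opt.step()
                epoch_loss += loss * len(yb)
            self.loss_history.append(epoch_loss / n)
            if verbose:
                print(f"{self.kind}: loss {self.loss_history[-1]:.4f}")
        self.trained = True
        return self

    def features(self, x, batch_size=512) -> np.ndarray:
        """Penultimate-layer activations, (n, 5)."""
        if not self.trained:
            raise RuntimeError("extractor is not trained")
        x = self._normalize(np.asarray(x, dtype=float))
        out = [self._forward(x[lo:lo + batch_size], train=False,
                             upto=len(self.layers) - 1)
               for lo in range(0, len(x), batch_size)]
        return np.vstack(out)

    def predict_proba(self, x, batch_size=512) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("extractor is not trained")
        x = self._normalize(np.asarray(x, dtype=float))
        out = [
            _sigmoid(self._forward(x[lo:lo + batch_size], train=False).ravel())
            for lo in range(0, len(x), batch_size)]
        return np.concatenate(out)


class ConvExtractor(_ExtractorBase):
    """conv-norm-pool x2 then MLP (16, 5, 1); penultimate width 5."""

    kind = "conv"

    def __init__(self, n_channels=3, n_samples=60, seed=0,
                 widths=(16, 32), kernel=5):
        super().__init__()
        rng = np.random.default_rng(seed)
        c1, c2 = widths
        flat = c2 * (n_samples // 4)
        self.layers = [
            Conv1d(rng, n_channels, c1, kernel), BatchNorm1d(c1), ReLU(),
            MaxPool1d(2),
            Conv1d(rng, c1, c2, kernel), BatchNorm1d(c2), ReLU(),
            MaxPool1d(2),
            Flatten(),
            Dense(rng, flat, 16), ReLU(),
            Dense(rng, 16, PENULTIMATE_DIM), ReLU(),
            Dense(rng, PENULTIMATE_DIM, 1),
        ]


class RecurrentExtractor(_ExtractorBase):
    """Bidirectional LSTM then MLP (16, 5, 1); penultimate width 5."""

    kind = "recurrent"
    default_lr = 5e-3  # BPTT over 60 steps converges slowly at the conv rate

    def __init__(self, n_channels=3, n_samples=60, seed=0, hidden=32):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.layers = [
            BiLSTM(rng, n_channels, hidden),
            Dense(rng, 2 * hidden, 16), ReLU(),
            Dense(rng, 16, PENULTIMATE_DIM), ReLU(),
            Dense(rng, PENULTIMATE_DIM, 1),
        ]


def train_extractor(kind: str, x, y, epochs=10, seed=0, **kwargs):
    """Train a learned feature extractor of the given kind on window
    tensors ``x`` (n, channels, samples) with binary labels ``y``."""
    n_channels, n_samples = x.shape[1], x.shape[2]
    if kind == "conv":
        model = ConvExtractor(n_channels, n_samples, seed=seed)
    elif kind == "recurrent":
        model = RecurrentExtractor(n_channels, n_samples, seed=seed)
    else:
        raise ValueError("kind must be 'conv' or 'recurrent'")
    return model.fit(x, y, epochs=epochs, seed=seed, **kwargs)
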