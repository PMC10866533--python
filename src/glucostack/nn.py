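"""A compact numpy recurrent-network core.

Implements exactly what the forecasting pipeline needs and nothing more:
LSTM layers (optionally peephole-augmented and/or bidirectional), a linear
dense head, mean-squared-error loss, backpropagation through time, and the
Adam optimizer with early stopping on validation loss.

The LSTM cell follows the gated recursion

    i_t = σ(W_i x_t + U_i h_{t−1} + b_i [+ p_i ⊙ c_{t−1}])
    f_t = σ(W_f x_t + U_f h_{t−1} + b_f [+ p_f ⊙ c_{t−1}])
    g_t = φ(W_c x_t + U_c h_{t−1} + b_c)
    c_t = f_t ⊙ c_{t−1} + i_t ⊙ g_t
    o_t = σ(W_o x_t + U_o h_{t−1} + b_o [+ p_o ⊙ c_t])
    h_t = o_t ⊙ φ(c_t)

where φ is the configurable cell activation (relu, tanh or linear) applied
both to the candidate and to the cell output, σ is the logistic sigmoid and
the bracketed peephole terms are enabled per layer.  Gradients are exact
analytic BPTT (verified against central finite differences in the tests).
"""

from __future__ import annotations

import numpy as np

_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(x.dtype)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
}


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng, shape, dtype):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class LSTMLayer:
    """One (unidirectional) LSTM layer with packed gate weights.

    Gate order in the packed matrices is (i, f, g, o).  The forget-gate bias
    is initialized to 1, a standard stabilization.
    """

    def __init__(self, d_in, units, *, activation="tanh", peephole=False,
                 rng=None, dtype=np.float32):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        rng = rng or np.random.default_rng()
        self.d_in, self.units = d_in, units
        self.activation = activation
        self.peephole = peephole
        self.dtype = dtype
        self.W = _glorot(rng, (d_in + units, 4 * units), dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units:2 * units] = 1.0  # forget gate bias
        self.p = np.zeros((3, units), dtype=dtype)  # peephole (i, f, o); unused if off

    # -- parameter plumbing ---------------------------------------------------
    def params(self):
        out = [("W", self.W), ("b", self.b)]
        if self.peephole:
            out.append(("p", self.p))
        return out

    def forward(self, X, *, return_sequences):
        """X: (batch, T, d_in) → H (batch, T, units) or last h (batch, units)."""
        phi, _ = _ACTIVATIONS[self.activation]
        B, T, _ = X.shape
        u = self.units
        h = np.zeros((B, u), dtype=self.dtype)
        c = np.zeros((B, u), dtype=self.dtype)
        cache = {"X": X, "steps": []}
        H = np.empty((B, T, u), dtype=self.dtype)
        for t in range(T):
            xt = X[:, t, :]
            z = np.concatenate([xt, h], axis=1) @ self.W + self.b
            zi, zf, zg, zo = (z[:, k * u:(k + 1) * u] for k in range(4))
            if self.peephole:
                zi = zi + self.p[0] * c
                zf = zf + self.p[1] * c
            i = _sigmoid(zi)
            f = _sigmoid(zf)
            g = phi(zg)
            c_prev = c
            c = f * c_prev + i * g
            if self.peephole:
                zo = zo + self.p[2] * c
            o = _sigmoid(zo)
            phi_c = phi(c)
            h_prev = cache["steps"][-1]["h"] if t else np.zeros_like(h)
            cache["steps"].append(dict(x=xt, h_prev=h_prev, c_prev=c_prev, zg=zg,
                                       i=i, f=f, g=g, o=o, c=c, phi_c=phi_c))
            h = o * phi_c
            cache["steps"][-1]["h"] = h
            H[:, t, :] = h
        cache["H"] = H
        return (H if return_sequences else h), cache

    def backward(self, cache, dH=None, dh_last=None):
        """BPTT. Provide dH (batch, T, units) and/or dh_last for the final step.

        Returns (dX, grads) with grads keyed like :meth:`params`.
        """
        phi, dphi = _ACTIVATIONS[self.activation]
        X = cache["X"]
        B, T, _ = X.shape
        u = self.units
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dp = np.zeros_like(self.p)
        dX = np.empty_like(X)
        dh = np.zeros((B, u), dtype=self.dtype)
        dc = np.zeros((B, u), dtype=self.dtype)
        if dh_last is not None:
            dh = dh + dh_last.astype(self.dtype)
        for t in range(T - 1, -1, -1):
            s = cache["steps"][t]
            if dH is not None:
                dh = dh + dH[:, t, :]
            o, i, f, g, c = s["o"], s["i"], s["f"], s["g"], s["c"]
            do = dh * s["phi_c"]
            dzo = do * o * (1 - o)
            dc_t = dh * o * dphi(c) + dc
            if self.peephole:
                dc_t = dc_t + dzo * self.p[2]
                dp[2] += (dzo * c).sum(axis=0)
            di = dc_t * g
            df = dc_t * s["c_prev"]
            dg = dc_t * i
            dzi = di * i * (1 - i)
            dzf = df * f * (1 - f)
            dzg = dg * dphi(s["zg"])
            dc = dc_t * f
            if self.peephole:
                dc = dc + dzi * self.p[0] + dzf * self.p[1]
                dp[0] += (dzi * s["c_prev"]).sum(axis=0)
                dp[1] += (dzf * s["c_prev"]).sum(axis=0)
            dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            inp = np.concatenate([s["x"], s["h_prev"]], axis=1)
            dW += inp.T @ dz
            db += dz.sum(axis=0)
            dcat = dz @ self.W.T
            dX[:, t, :] = dcat[:, :self.d_in]
            dh = dcat[:, self.d_in:]
        grads = [("W", dW), ("b", db)]
        if self.peephole:
            grads.append(("p", dp))
        return dX, grads


class Dense:
    """Linear layer y = x W + b."""

    def __init__(self, d_in, d_out, *, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.W = _glorot(rng, (d_in, d_out), dtype)
        self.b = np.zeros(d_out, dtype=dtype)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x):
        return x @ self.W + self.b, {"x": x}

    def backward(self, cache, dy):
        dW = cache["x"].T @ dy
        db = dy.sum(axis=0)
        dx = dy @ self.W.T
        return dx, [("W", dW), ("b", db)]


class LSTMNet:
    """A recurrent stack with a linear dense head and vector output.

    ``layer_specs`` is a list of dicts, each with keys ``units``,
    ``activation``, ``peephole`` and ``bidirectional``.  Every layer but the
    last emits its full hidden sequence; the last emits its final hidden
    state (the concatenated forward/backward final states when
    bidirectional), which the dense head maps to ``output_dim`` values.
    """

    def __init__(self, input_dim, layer_specs, output_dim, *, seed=0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.layers = []       # list of (fwd_layer, bwd_layer_or_None)
        d = input_dim
        for spec in layer_specs:
            fwd = LSTMLayer(d, spec["units"], activation=spec.get("activation", "tanh"),
                            peephole=spec.get("peephole", False), rng=rng, dtype=dtype)
            bwd = None
            if spec.get("bidirectional", False):
                bwd = LSTMLayer(d, spec["units"], activation=spec.get("activation", "tanh"),
                                peephole=spec.get("peephole", False), rng=rng, dtype=dtype)
            self.layers.append((fwd, bwd))
            d = spec["units"] * (2 if bwd is not None else 1)
        self.dense = Dense(d, output_dim, rng=rng, dtype=dtype)
        self.output_dim = output_dim

    # -- flat parameter access (for Adam and checkpointing) -------------------
    def parameters(self):
        out = []
        for li, (fwd, bwd) in enumerate(self.layers):
            for name, arr in fwd.params():
                out.append((f"layer{li}.fwd.{name}", arr))
            if bwd is not None:
                for name, arr in bwd.params():
                    out.append((f"layer{li}.bwd.{name}", arr))
        for name, arr in self.dense.params():
            out.append((f"dense.{name}", arr))
        return out

    def get_weights(self):
        return {k: v.copy() for k, v in self.parameters()}

    def set_weights(self, weights):
        for k, v in self.parameters():
            v[...] = weights[k]

    def forward(self, X, *, keep_cache=False):
        """X: (batch, T) or (batch, T, d) → predictions (batch, output_dim)."""
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 2:
            X = X[:, :, None]
        caches = []
        cur = X
        n_layers = len(self.layers)
        for li, (fwd, bwd) in enumerate(self.layers):
            last = li == n_layers - 1
            out_f, cache_f = fwd.forward(cur, return_sequences=not last)
            if bwd is None:
                cur = out_f
                caches.append((cache_f, None))
            else:
                rev = cur[:, ::-1, :]
                out_b, cache_b = bwd.forward(rev, return_sequences=not last)
                caches.append((cache_f, cache_b))
                if last:
                    cur = np.concatenate([out_f, out_b], axis=1)
                else:
                    cur = np.concatenate([out_f, out_b[:, ::-1, :]], axis=2)
        y, dense_cache = self.dense.forward(cur)
        if keep_cache:
            return y, (caches, dense_cache)
        return y

    def backward(self, cache, dy):
        """Return gradients keyed like :meth:`parameters` given d(loss)/d(output)."""
        caches, dense_cache = cache
        dy = dy.astype(self.dtype)
        dcur, dense_grads = self.dense.backward(dense_cache, dy)
        grads = {}
        n_layers = len(self.layers)
        for li in range(n_layers - 1, -1, -1):
            fwd, bwd = self.layers[li]
            cache_f, cache_b = caches[li]
            last = li == n_layers - 1
            if bwd is None:
                if last:
                    dX, g = fwd.backward(cache_f, dh_last=dcur)
                else:
                    dX, g = fwd.backward(cache_f, dH=dcur)
                for name, arr in g:
                    grads[f"layer{li}.fwd.{name}"] = arr
                dcur = dX
            else:
                u = fwd.units
                if last:
                    dX_f, g_f = fwd.backward(cache_f, dh_last=dcur[:, :u])
                    dX_b, g_b = bwd.backward(cache_b, dh_last=dcur[:, u:])
                else:
                    dX_f, g_f = fwd.backward(cache_f, dH=dcur[:, :, :u])
                    dX_b, g_b = bwd.backward(cache_b, dH=dcur[:, ::-1, u:])
                for name, arr in g_f:
                    grads[f"layer{li}.fwd.{name}"] = arr
                for name, arr in g_b:
                    grads[f"layer{li}.bwd.{name}"] = arr
                dcur = dX_f + dX_b[:, ::-1, :]
        for name, arr in dense_grads:
            grads[f"dense.{name}"] = arr
        return grads


class Adam:
    """Adam optimizer over a model's named parameter arrays."""

    def __init__(self, model, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7,
                 clip_norm=5.0):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.parameters()}
        self.v = {k: np.zeros_like(v) for k, v in model.parameters()}

    def step(self, grads):
        self.t += 1
        if self.clip_norm is not None:
            norm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                               for g in grads.values()))
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                grads = {k: g * g.dtype.type(scale) for k, g in grads.items()}
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, p in self.model.parameters():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def mse(y_true, y_pred):
    d = np.asarray(y_pred, dtype=np.float64) - np.asarray(y_true, dtype=np.float64)
    return float(np.mean(d * d))


def fit(model, X, y, *, X_val=None, y_val=None, lr=0.001, batch_size=32,
        max_epochs=500, patience=10, shuffle=True, seed=0, verbose=False):
    """Train ``model`` on MSE with Adam, minibatches and early stopping.

    Early stopping monitors validation loss; training halts when it fails to
    improve for ``patience`` consecutive epochs (or at ``max_epochs``), and
    the best-validation weights are restored.  With no validation set the
    full ``max_epochs`` are run and final weights kept.

    Returns a history dict with per-epoch ``train_loss``/``val_loss`` lists
    and ``epochs_run``.
    """
    X = np.asarray(X, dtype=model.dtype)
    y = np.asarray(y, dtype=model.dtype)
    rng = np.random.default_rng(seed)
    opt = Adam(model, lr=lr)
    n = len(X)
    history = {"train_loss": [], "val_loss": [], "epochs_run": 0}
    best_val = np.inf
    best_weights = None
    stall = 0
    monitor = X_val is not None and y_val is not None and patience is not None
    for epoch in range(max_epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        total, count = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            pred, cache = model.forward(xb, keep_cache=True)
            diff = (pred - yb).astype(np.float64)
            total += float((diff ** 2).sum())
            count += diff.size
            dy = (2.0 / diff.size) * diff
            grads = model.backward(cache, dy)
            opt.step(grads)
        history["train_loss"].append(total / count)
        history["epochs_run"] = epoch + 1
        if X_val is not None and y_val is not None:
            val_loss = mse(y_val, model.forward(X_val))
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = model.get_weights()
                stall = 0
            else:
                stall += 1
            if verbose:
                print(f"epoch {epoch + 1}: train {history['train_loss'][-1]:.6f} "
                      f"val {val_loss:.6f}")
            if monitor and stall >= patience:
                break
        elif verbose:
            print(f"epoch {epoch + 1}: train {history['train_loss'][-1]:.6f}")
    if best_weights is not None:
        model.set_weights(best_weights)
    return history
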