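"""Minimal feed-forward network engine used by the emulators.

Two input layouts are supported:

* flat — an ordinary MLP on a feature vector (used by the 3-feature
  allele-frequency emulators);
* positional — the per-SNP input is reshaped to an (n, c) matrix (n
  individuals, c channels, e.g. genotype and residual), the hidden
  layers are applied to each row with shared weights, and a final
  linear layer reads the flattened (n x last_hidden) activations.
  Sharing weights across individuals is what lets the network represent
  sums of per-individual terms such as X'R with few parameters.

Each hidden layer is dense -> batch normalization -> ReLU -> inverted
dropout; the output is a single linear unit.  Training is Adam on the
variance-preserving loss

    L = mean((pred - target)^2)            [dropout path]
        + lambda_var * (sd(pred) - sd(target))^2
        + l1 * sum_k |W_k|.

In the default "clean" vp_mode the sd penalty is evaluated on a
dropout-free forward pass so that the spread being preserved is that of
the deployed predictor, not of the dropout-noised training path; the
running batch-norm statistics follow the same clean path.  The two
passes are processed as one stacked tensor with a leading path axis, so
each layer still costs a single matrix product and the parameter
gradients of the two paths accumulate inside the stacked products.

Arithmetic is single precision with preallocated buffers (batches are
tiny, so call overhead and memory traffic dominate); hidden dense
biases are carried but never updated because batch normalization makes
their gradient exactly zero.  Everything is seeded: a given
(architecture, data, seed) triple reproduces the training history and
final weights bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["MLPConfig", "MLP", "vp_loss"]

_BN_EPS = 1e-3  # batch-norm variance floor
_BN_MOMENTUM = 0.99
_SD_EPS = 1e-12
_DT = np.float32


def vp_loss(pred: np.ndarray, target: np.ndarray, lambda_var: float = 1.0) -> float:
    """Variance-preserving loss: MSE plus a penalty on the sd mismatch."""
    pred = np.asarray(pred, float).ravel()
    target = np.asarray(target, float).ravel()
    if pred.size != target.size:
        raise ValueError("pred and target must have equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 values (sd undefined otherwise)")
    mse = float(np.mean((pred - target) ** 2))
    sd_p = float(np.std(pred))
    sd_t = float(np.std(target))
    return mse + lambda_var * (sd_p - sd_t) ** 2


@dataclass
class MLPConfig:
    n_features: int
    hidden: tuple[int, ...] = (64, 64, 32, 16)
    dropout: tuple[float, ...] = (0.1, 0.1, 0.1, 0.1)
    positions: int = 0  # 0 = flat input; else reshape to (positions, channels)
    l1: float = 0.01
    lambda_var: float = 10.0
    vp_mode: str = "clean"  # sd penalty on a dropout-free pass, or "batch"
    learning_rate: float = 0.001  # initial rate; see lr_schedule
    lr_schedule: str = "cosine"  # "cosine" decay to 0 or "constant"
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dropout) != len(self.hidden):
            raise ValueError("dropout must give one rate per hidden layer")
        if self.positions and self.n_features % self.positions:
            raise ValueError("n_features must be divisible by positions")
        if self.vp_mode not in ("clean", "batch"):
            raise ValueError("vp_mode must be 'clean' or 'batch'")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")

    @property
    def channels(self) -> int:
        return self.n_features // self.positions if self.positions else self.n_features


@njit(cache=False, fastmath=True)
def _bn_fwd_kernel(z, gamma, beta, u, rate, act, mask, mu, inv, eps):
    """Fused batch-norm + ReLU + dropout forward.

    z (P, M, H) is overwritten with xhat; act and mask are filled; mu and
    inv receive the per-path batch statistics.  Path 0 applies the
    dropout keep-mask u (already scaled by 1/(1-rate)); other paths are
    dropout-free.  Accumulation in double precision.
    """
    P, M, H = z.shape
    for p in range(P):
        s = np.zeros(H, dtype=np.float64)
        s2 = np.zeros(H, dtype=np.float64)
        for m in range(M):
            for h in range(H):
                v = z[p, m, h]
                s[h] += v
                s2[h] += v * v
        for h in range(H):
            mean = s[h] / M
            var = s2[h] / M - mean * mean
            if var < 0.0:
                var = 0.0
            mu[p, h] = mean
            inv[p, h] = 1.0 / np.sqrt(var + eps)
        drop = p == 0 and rate > 0.0
        for m in range(M):
            for h in range(H):
                xh = (z[p, m, h] - mu[p, h]) * inv[p, h]
                z[p, m, h] = xh
                a = gamma[h] * xh + beta[h]
                if a > 0.0:
                    k = u[m, h] if drop else np.float32(1.0)
                else:
                    k = np.float32(0.0)
                mask[p, m, h] = k
                act[p, m, h] = a * k


@njit(cache=False, fastmath=True)
def _bn_bwd_kernel(dh, mask, xhat, gamma, inv, ggamma_p, gbeta_p):
    """Fused dropout/ReLU/batch-norm backward.

    dh (P, M, H) enters as the gradient at the layer output and leaves
    as the gradient at the dense pre-activation; per-path sums of the
    scale/shift gradients are written to ggamma_p and gbeta_p.
    """
    P, M, H = dh.shape
    for p in range(P):
        sg = np.zeros(H, dtype=np.float64)
        sb = np.zeros(H, dtype=np.float64)
        for m in range(M):
            for h in range(H):
                d = dh[p, m, h] * mask[p, m, h]
                dh[p, m, h] = d
                sg[h] += d * xhat[p, m, h]
                sb[h] += d
        c1 = np.empty(H, dtype=np.float32)
        c2 = np.empty(H, dtype=np.float32)
        gi = np.empty(H, dtype=np.float32)
        for h in range(H):
            ggamma_p[p, h] = sg[h]
            gbeta_p[p, h] = sb[h]
            gi[h] = gamma[h] * inv[p, h]
            c1[h] = gi[h] * sg[h] / M
            c2[h] = gi[h] * sb[h] / M
        for m in range(M):
            for h in range(H):
                dh[p, m, h] = gi[h] * dh[p, m, h] - xhat[p, m, h] * c1[h] - c2[h]


class MLP:
    """Flat-parameter MLP; see module docstring for the training recipe."""

    def __init__(self, config: MLPConfig):
        self.config = config
        c = config
        dims = [c.channels, *c.hidden]
        head_in = c.hidden[-1] * c.positions if c.positions else c.hidden[-1]
        self._head_in = head_in
        shapes: list[tuple[int, ...]] = []
        for i in range(len(c.hidden)):
            shapes += [
                (dims[i], dims[i + 1]),
                (dims[i + 1],),  # bias (inert under batch norm)
                (dims[i + 1],),  # gamma
                (dims[i + 1],),  # beta
            ]
        shapes += [(head_in, 1), (1,)]
        total = sum(int(np.prod(s)) for s in shapes)
        self.theta = np.zeros(total, dtype=_DT)
        self.grad = np.zeros(total, dtype=_DT)
        self._m = np.zeros(total, dtype=_DT)
        self._v = np.zeros(total, dtype=_DT)
        self._t = 0
        self._total_steps = 0
        self.W, self.gW = [], []
        self.b, self.gb = [], []
        self.gamma, self.ggamma = [], []
        self.beta, self.gbeta = [], []
        off = 0

        def view(shape):
            nonlocal off
            k = int(np.prod(shape))
            t = self.theta[off : off + k].reshape(shape)
            g = self.grad[off : off + k].reshape(shape)
            off += k
            return t, g

        for i in range(len(c.hidden)):
            for lst, glst in ((self.W, self.gW), (self.b, self.gb),
                              (self.gamma, self.ggamma), (self.beta, self.gbeta)):
                t, g = view(shapes.pop(0))
                lst.append(t)
                glst.append(g)
        Wh, gWh = view(shapes.pop(0))
        bh, gbh = view(shapes.pop(0))
        self.W.append(Wh)
        self.gW.append(gWh)
        self.b.append(bh)
        self.gb.append(gbh)
        self.run_mean = [np.zeros(h, dtype=_DT) for h in c.hidden]
        self.run_var = [np.ones(h, dtype=_DT) for h in c.hidden]
        self._init_weights()
        self.history: list[float] = []
        self._bufs: dict[tuple, list] = {}
        self._u_empty = np.empty((1, 1), dtype=_DT)  # stand-in when rate == 0

    def _init_weights(self) -> None:
        rng = np.random.default_rng(np.random.SeedSequence(self.config.seed))
        self._rng = rng
        for W in self.W:
            fan_in, fan_out = W.shape
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            W[:] = rng.uniform(-limit, limit, size=W.shape).astype(_DT)
        for g in self.gamma:
            g[:] = 1.0

    def _rows(self, B: int) -> int:
        return B * self.config.positions if self.config.positions else B

    def _workspace(self, P: int, M: int) -> list:
        """Per-layer scratch (path-stacked): xhat, act, mask of shape (P, M, h)."""
        key = (P, M)
        if key not in self._bufs:
            self._bufs[key] = [
                (
                    np.empty((P, M, h), dtype=_DT),
                    np.empty((P, M, h), dtype=_DT),
                    np.empty((P, M, h), dtype=_DT),
                )
                for h in self.config.hidden
            ]
        return self._bufs[key]

    # ---------------------------------------------------------------- forward
    def _forward_train(self, x: np.ndarray, dual: bool):
        """Stacked training forward: path 0 carries dropout, path 1 (when
        ``dual``) is the dropout-free pass for the sd penalty.  Running
        batch-norm statistics follow the dropout-free path."""
        c = self.config
        B = x.shape[0]
        M = self._rows(B)
        P = 2 if dual else 1
        clean = P - 1  # index of the path that feeds running stats
        ws = self._workspace(P, M)
        h = np.broadcast_to(
            x.reshape(1, M, c.channels), (P, M, c.channels)
        ).reshape(P * M, c.channels)
        inputs, invs = [], []
        nh = len(c.hidden)
        for i in range(nh):
            xhat, act, mask = ws[i]
            hsz = xhat.shape[2]
            flat = xhat.reshape(P * M, hsz)
            np.matmul(h, self.W[i], out=flat)
            rate = c.dropout[i]
            if rate > 0:
                u = self._rng.random((M, hsz), dtype=_DT)
                np.greater_equal(u, rate, out=u)  # 0/1 keep mask as floats
                u *= _DT(1.0 / (1.0 - rate))
            else:
                u = self._u_empty
            mu = np.empty((P, hsz), dtype=_DT)
            inv = np.empty((P, hsz), dtype=_DT)
            _bn_fwd_kernel(
                xhat, self.gamma[i], self.beta[i], u, _DT(rate), act, mask,
                mu, inv, _DT(_BN_EPS),
            )
            self.run_mean[i] *= _BN_MOMENTUM
            self.run_mean[i] += (1.0 - _BN_MOMENTUM) * mu[clean]
            var_clean = 1.0 / (inv[clean] * inv[clean]) - _DT(_BN_EPS)
            self.run_var[i] *= _BN_MOMENTUM
            self.run_var[i] += (1.0 - _BN_MOMENTUM) * var_clean
            inputs.append(h)
            invs.append(inv)
            h = act.reshape(P * M, hsz)
        h_head = h.reshape(P * B, self._head_in)
        out = (h_head @ self.W[nh]).ravel() + self.b[nh]
        return out, (inputs, invs, ws, h_head, P, M, B)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout off, running batch-norm stats)."""
        c = self.config
        x = np.asarray(x, dtype=_DT)
        if x.ndim != 2 or x.shape[1] != c.n_features:
            raise ValueError(f"expected (rows, {c.n_features}) features")
        B = x.shape[0]
        h = x.reshape(self._rows(B), c.channels)
        nh = len(c.hidden)
        for i in range(nh):
            z = h @ self.W[i]
            z -= self.run_mean[i]
            z *= 1.0 / np.sqrt(self.run_var[i] + _BN_EPS)
            z *= self.gamma[i]
            z += self.beta[i]
            h = np.maximum(z, 0.0, out=z)
        out = (h.reshape(B, self._head_in) @ self.W[nh]).ravel() + self.b[nh]
        return out.astype(np.float64)

    # --------------------------------------------------------------- backward
    def _backward(self, dout: np.ndarray, fwd) -> None:
        """Backpropagate the stacked output gradient; parameter gradients
        of both paths accumulate inside the stacked products.  Buffers in
        ``fwd`` are consumed destructively."""
        c = self.config
        inputs, invs, ws, h_head, P, M, B = fwd
        nh = len(c.hidden)
        d = dout.astype(_DT)[:, None]
        np.matmul(h_head.T, d, out=self.gW[nh])
        self.gb[nh][:] = d.sum()
        dh = (d @ self.W[nh].T).reshape(P, M, c.hidden[-1])
        for i in range(nh - 1, -1, -1):
            xhat, act, mask = ws[i]
            inv = invs[i]
            hsz = dh.shape[2]
            ggamma_p = np.empty((P, hsz), dtype=_DT)
            gbeta_p = np.empty((P, hsz), dtype=_DT)
            _bn_bwd_kernel(dh, mask, xhat, self.gamma[i], inv, ggamma_p, gbeta_p)
            np.add.reduce(ggamma_p, axis=0, out=self.ggamma[i])
            np.add.reduce(gbeta_p, axis=0, out=self.gbeta[i])
            flat = dh.reshape(P * M, hsz)
            np.matmul(inputs[i].T, flat, out=self.gW[i])
            # dense bias gradient is exactly 0 through batch norm
            self.gb[i].fill(0.0)
            if i > 0:
                prev = ws[i - 1][1]  # previous activation buffer
                np.matmul(flat, self.W[i].T, out=prev.reshape(P * M, -1))
                dh = prev

    def _step(self, xb: np.ndarray, yb: np.ndarray) -> float:
        """One optimization step: MSE on the dropout path, sd penalty on
        the dropout-free path (vp_mode "clean"), L1 on the kernels."""
        c = self.config
        dual = c.vp_mode == "clean" and any(r > 0 for r in c.dropout)
        out, fwd = self._forward_train(xb, dual)
        B = xb.shape[0]
        out_d = out[:B]
        out_c = out[B:] if dual else out_d
        diff = out_d - yb
        mse = float(np.mean(diff**2))
        dout_mse = 2.0 * diff / B
        sd_t = float(np.std(yb))
        mu_p = out_c.mean()
        sd_p = float(np.sqrt(np.mean((out_c - mu_p) ** 2) + _SD_EPS))
        gap = sd_p - sd_t
        dout_vp = c.lambda_var * 2.0 * gap * (out_c - mu_p) / (B * sd_p)
        loss = mse + c.lambda_var * gap * gap
        if dual:
            dout = np.concatenate([dout_mse, dout_vp])
        else:
            dout = dout_mse + dout_vp
        self._backward(dout, fwd)
        if c.l1 > 0:
            loss += c.l1 * sum(float(np.abs(W).sum()) for W in self.W)
            for W, gW in zip(self.W, self.gW):
                gW += c.l1 * np.sign(W)
        return loss

    def _adam_step(self) -> None:
        c = self.config
        self._t += 1
        b1, b2, eps = _DT(0.9), _DT(0.999), _DT(1e-8)
        self._m *= b1
        self._m += (1 - b1) * self.grad
        self.grad *= self.grad
        self._v *= b2
        self._v += (1 - b2) * self.grad
        lr = c.learning_rate
        if c.lr_schedule == "cosine" and self._total_steps:
            lr *= 0.5 * (1.0 + np.cos(np.pi * min(self._t / self._total_steps, 1.0)))
        lr_t = lr * np.sqrt(1 - float(b2) ** self._t) / (1 - float(b1) ** self._t)
        upd = np.sqrt(self._v)
        upd += eps
        np.divide(self._m, upd, out=upd)
        upd *= _DT(lr_t)
        self.theta -= upd

    # ----------------------------------------------------------------- train
    def fit(self, x: np.ndarray, y: np.ndarray) -> "MLP":
        c = self.config
        x = np.ascontiguousarray(x, dtype=_DT)
        y = np.asarray(y, dtype=np.float64).ravel()
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise ValueError("training data contain non-finite values")
        n = x.shape[0]
        if n < 2:
            raise ValueError("need at least 2 training rows")
        self._total_steps = c.epochs * max(n // c.batch_size, 1)
        for _ in range(c.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, c.batch_size):
                idx = order[start : start + c.batch_size]
                if idx.size < 2:
                    continue  # sd and batch norm need >= 2 rows
                loss = self._step(x[idx], y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss at step {self._t})"
                    )
                self._adam_step()
                epoch_loss += loss
                n_batches += 1
            self.history.append(epoch_loss / max(n_batches, 1))
        return self

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict:
        return {
            "theta": self.theta.copy(),
            "run_mean": [m.copy() for m in self.run_mean],
            "run_var": [v.copy() for v in self.run_var],
            "history": list(self.history),
        }

    def load_state_dict(self, state: dict) -> None:
        self.theta[:] = np.asarray(state["theta"], dtype=_DT)
        for m, s in zip(self.run_mean, state["run_mean"]):
            m[:] = s
        for v, s in zip(self.run_var, state["run_var"]):
            v[:] = s
        self.history = list(state["history"])
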