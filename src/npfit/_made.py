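"""Masked autoregressive conditional density estimator (numpy).

A single-hidden-layer MADE network models q(z | x) for z in R^D,
conditioned on an observation vector x, as a product of Gaussian
conditionals

    q(z | x) = prod_d Normal(z_d; mu_d(z_{<d}, x), exp(s_d(z_{<d}, x))^2)

Autoregressive structure is enforced by binary masks on the weight
matrices (Germain-style connectivity degrees); the conditioning input x
is fully connected.  Training uses hand-written backpropagation with an
Adam optimizer: the only gradient primitive needed by both the maximum-
likelihood and the atomic proposal-corrected losses is the gradient of a
weighted sum of log-densities with respect to the weights.
"""

from __future__ import annotations

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))
_S_CLAMP = 7.0  # bound on log-sigma for numerical stability


class MADE:
    """Masked autoregressive Gaussian conditional density estimator."""

    def __init__(self, dim: int, cond_dim: int, hidden: int, rng: np.random.Generator):
        if dim < 1 or hidden < 1:
            raise ValueError("dim and hidden must be >= 1")
        self.dim = dim
        self.cond_dim = cond_dim
        self.hidden = hidden

        # connectivity degrees: inputs 1..D, hidden cycled in 0..D-1; degree-0
        # hidden units see no z at all and carry purely conditioning
        # information to every output dimension
        d_in = np.arange(1, dim + 1)
        m_hidden = np.arange(hidden) % dim
        # hidden unit j sees z_i iff degree(z_i) <= m_j
        self.mask1 = (d_in[None, :] <= m_hidden[:, None]).astype(float)  # (H, D)
        # output for dimension d sees hidden j iff m_j < d (strict)
        self.mask2 = (m_hidden[None, :] < d_in[:, None]).astype(float)  # (D, H)

        s = 1.0 / np.sqrt(dim + cond_dim)
        self.W1 = rng.normal(0.0, s, size=(hidden, dim))
        self.Wx = rng.normal(0.0, s, size=(hidden, cond_dim)) if cond_dim else np.zeros((hidden, 0))
        self.b1 = np.zeros(hidden)
        sh = 1.0 / np.sqrt(hidden)
        self.Wmu = rng.normal(0.0, sh, size=(dim, hidden))
        self.bmu = np.zeros(dim)
        self.Ws = rng.normal(0.0, sh, size=(dim, hidden))
        self.bs = np.zeros(dim)

    # -- parameter plumbing -------------------------------------------------
    _PARAM_NAMES = ("W1", "Wx", "b1", "Wmu", "bmu", "Ws", "bs")

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k).copy() for k in self._PARAM_NAMES}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self._PARAM_NAMES:
            setattr(self, k, params[k].copy())

    # -- forward ------------------------------------------------------------
    def _forward(self, z: np.ndarray, x: np.ndarray):
        h_pre = z @ (self.W1 * self.mask1).T + self.b1
        if self.cond_dim:
            h_pre = h_pre + x @ self.Wx.T
        h = np.tanh(h_pre)
        mu = h @ (self.Wmu * self.mask2).T + self.bmu
        s = np.clip(h @ (self.Ws * self.mask2).T + self.bs, -_S_CLAMP, _S_CLAMP)
        return h, mu, s

    def conditionals(self, z: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-dimension (mu, log-sigma); row-wise over a batch."""
        _, mu, s = self._forward(np.atleast_2d(z), np.atleast_2d(x))
        return mu, s

    def log_prob(self, z: np.ndarray, x: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        _, mu, s = self._forward(z, np.atleast_2d(x))
        u = (z - mu) * np.exp(-s)
        return np.sum(-0.5 * _LOG_2PI - s - 0.5 * u * u, axis=1)

    # -- backward ------------------------------------------------------------
    def grad_weighted_logprob(self, z: np.ndarray, x: np.ndarray, w: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of sum_r w_r * log q(z_r | x_r) w.r.t. the weights."""
        z = np.atleast_2d(z)
        x = np.atleast_2d(x)
        h, mu, s = self._forward(z, x)
        inv_sig = np.exp(-s)
        u = (z - mu) * inv_sig

        w_col = w[:, None]
        g_mu = w_col * (u * inv_sig)  # d logq / d mu
        g_s = w_col * (u * u - 1.0)  # d logq / d s
        # clamp region has zero gradient through s
        g_s = np.where(np.abs(s) >= _S_CLAMP, 0.0, g_s)

        grads: dict[str, np.ndarray] = {}
        grads["Wmu"] = (g_mu.T @ h) * self.mask2
        grads["bmu"] = g_mu.sum(axis=0)
        grads["Ws"] = (g_s.T @ h) * self.mask2
        grads["bs"] = g_s.sum(axis=0)

        g_h = g_mu @ (self.Wmu * self.mask2) + g_s @ (self.Ws * self.mask2)
        g_pre = g_h * (1.0 - h * h)
        grads["W1"] = (g_pre.T @ z) * self.mask1
        grads["Wx"] = g_pre.T @ x if self.cond_dim else np.zeros_like(self.Wx)
        grads["b1"] = g_pre.sum(axis=0)
        return grads

    # -- sampling -------------------------------------------------------------
    def sample(self, n: int, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Autoregressive sampling of n draws conditioned on a single x."""
        x_rep = np.broadcast_to(np.asarray(x, dtype=float), (n, self.cond_dim))
        z = np.zeros((n, self.dim))
        eps = rng.standard_normal((n, self.dim))
        for d in range(self.dim):
            _, mu, s = self._forward(z, x_rep)
            z[:, d] = mu[:, d] + np.exp(s[:, d]) * eps[:, d]
        return z


class Adam:
    """Adam optimizer over a MADE parameter dict."""

    def __init__(self, net: MADE, lr: float = 5e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(net, k)) for k in MADE._PARAM_NAMES}
        self.v = {k: np.zeros_like(getattr(net, k)) for k in MADE._PARAM_NAMES}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in MADE._PARAM_NAMES:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            update = self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            setattr(self.net, k, getattr(self.net, k) - update)
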