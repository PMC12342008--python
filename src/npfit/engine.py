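"""Sequential neural posterior estimation for one patient.

Likelihood-free inference of p(theta | x_o): in the first round parameters
are drawn from the prior, simulated through the stochastic forward model,
and a masked autoregressive conditional density estimator is trained on
the (theta, x) pairs by maximum likelihood.  In every later round
parameters are drawn from the current posterior estimate conditioned on
x_o (the proposal), and the estimator is retrained on the cumulative
sample set with the atomic proposal correction, which re-weights candidate
parameters by their prior density inside a softmax so the network keeps
estimating the true posterior rather than the proposal posterior.

Inference runs in log-parameter space (z = ln theta), which makes the
lognormal prior Gaussian and guarantees strictly positive samples.
Invalid simulations are dropped, not resampled, keeping per-round cost
bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._made import MADE, Adam
from .features import SummaryVector
from .params import ParamVector
from .priors import PriorSpec, log_density_log_space
from .priors import sample as prior_sample

__all__ = ["EngineError", "EngineConfig", "RoundLog", "PosteriorModel", "fit_patient", "posterior_sample"]


class EngineError(RuntimeError):
    """Inference for a patient failed (all simulations invalid, loss blew up)."""


@dataclass(frozen=True)
class EngineConfig:
    """Sequential training configuration.

    Defaults are the desk-scale setting (10 rounds x 50 simulations); the
    full-scale setting (50 x 100, hidden 100) is available through the
    same fields.
    """

    n_rounds: int = 10
    n_sims_per_round: int = 50
    n_atoms: int = 25
    density_estimator: str = "made"
    hidden_units: int = 50
    seed: int = 0
    learning_rate: float = 5e-4
    max_epochs: int = 100
    patience: int = 10
    train_batch_size: int = 50
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_rounds", "n_sims_per_round", "n_atoms", "hidden_units", "max_epochs", "patience", "train_batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_atoms > self.n_sims_per_round:
            raise ValueError("n_atoms must be <= n_sims_per_round")
        if self.density_estimator != "made":
            raise ValueError("only the 'made' density-estimator family is supported")


@dataclass
class RoundLog:
    round_index: int
    proposal_source: str  # "prior" or "posterior"
    n_invalid: int
    val_losses: list[float] = field(default_factory=list)


@dataclass
class _Standardizer:
    """Frozen z-score transform fitted on the first-round sample set."""

    z_mean: np.ndarray
    z_std: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray

    @classmethod
    def fit(cls, Z: np.ndarray, X: np.ndarray) -> "_Standardizer":
        def stats(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            mean = a.mean(axis=0)
            std = a.std(axis=0)
            return mean, np.where(std <= 1e-12, 1.0, std)

        zm, zs = stats(Z)
        xm, xs = stats(X)
        return cls(zm, zs, xm, xs)

    def z(self, Z: np.ndarray) -> np.ndarray:
        return (Z - self.z_mean) / self.z_std

    def z_inv(self, Zs: np.ndarray) -> np.ndarray:
        return Zs * self.z_std + self.z_mean

    def x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_std


@dataclass
class PosteriorModel:
    """Trained conditional density estimator, conditioned on x_o.

    Samplable and density-evaluable on ParamVector space; samples are
    strictly positive by construction (the estimator lives in log space).
    """

    net: MADE
    standardizer: _Standardizer
    x_o: np.ndarray
    names: tuple[str, ...]
    frozen: dict[str, float]
    rejection_count: int = 0

    def _x_std(self) -> np.ndarray:
        return self.standardizer.x(self.x_o[None, :])[0]

    def sample_arrays(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n positive parameter rows; non-finite draws rejected and redrawn."""
        x = self._x_std()
        rows: list[np.ndarray] = []
        rejected = 0
        attempts = 0
        while sum(len(r) for r in rows) < n:
            want = n - sum(len(r) for r in rows)
            zs = self.net.sample(want, x, rng)
            theta = np.exp(self.standardizer.z_inv(zs))
            ok = np.all(np.isfinite(theta), axis=1) & np.all(theta > 0, axis=1)
            rejected += int((~ok).sum())
            if ok.any():
                rows.append(theta[ok])
            attempts += want
            if attempts >= 100 * n and rejected / attempts > 0.99:
                raise EngineError("posterior mass escaped the positive support")
        self.rejection_count += rejected
        return np.concatenate(rows, axis=0)[:n]

    def sample(self, n: int, seed: int | np.random.Generator) -> list[ParamVector]:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return [ParamVector(self.names, row, self.frozen) for row in self.sample_arrays(n, rng)]

    def log_prob(self, theta: ParamVector | np.ndarray) -> float:
        values = theta.as_array() if isinstance(theta, ParamVector) else np.asarray(theta, dtype=float)
        if np.any(values <= 0) or not np.all(np.isfinite(values)):
            return -np.inf
        z = np.log(values)
        zs = self.standardizer.z(z[None, :])
        logq = self.net.log_prob(zs, self._x_std()[None, :])[0]
        # Jacobians: z-standardization then log-transform
        return float(logq - np.sum(np.log(self.standardizer.z_std)) - np.sum(z))


def posterior_sample(model: PosteriorModel, n: int, seed: int) -> list[ParamVector]:
    """n reproducible posterior draws (strictly positive)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return model.sample(n, seed)


# ---------------------------------------------------------------------------
# training


def _atom_indices(n_rows: int, n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """(n_rows, n_atoms) index matrix: own row first, distinct contrastive rest."""
    atoms = np.empty((n_rows, n_atoms), dtype=int)
    for i in range(n_rows):
        atoms[i, 0] = i
        others = rng.permutation(n_rows - 1)[: n_atoms - 1]
        atoms[i, 1:] = np.where(others >= i, others + 1, others)
    return atoms


def _loss_and_grads(
    net: MADE,
    Z: np.ndarray,
    X: np.ndarray,
    logp: np.ndarray,
    idx: np.ndarray,
    atomic: bool,
    n_atoms: int,
    rng: np.random.Generator,
    want_grads: bool = True,
):
    B = len(idx)
    if not atomic or B < 2:
        logq = net.log_prob(Z[idx], X[idx])
        loss = -float(np.mean(logq))
        if not want_grads:
            return loss, None
        w = np.full(B, -1.0 / B)
        return loss, net.grad_weighted_logprob(Z[idx], X[idx], w)

    M = min(n_atoms, B)
    atoms = idx[_atom_indices(B, M, rng)]  # (B, M) dataset rows
    z_flat = Z[atoms.ravel()]
    x_flat = np.repeat(X[idx], M, axis=0)
    logq = net.log_prob(z_flat, x_flat).reshape(B, M)
    logratio = logq - logp[atoms]
    lse = logsumexp(logratio, axis=1)
    loss = float(np.mean(lse - logratio[:, 0]))
    if not want_grads:
        return loss, None
    soft = np.exp(logratio - lse[:, None])
    w = soft.copy()
    w[:, 0] -= 1.0
    w /= B
    return loss, net.grad_weighted_logprob(z_flat, x_flat, w.ravel())


def _train_round(
    net: MADE,
    Zs: np.ndarray,
    Xs: np.ndarray,
    logp: np.ndarray,
    atomic: bool,
    config: EngineConfig,
    rng: np.random.Generator,
) -> list[float]:
    n = len(Zs)
    n_val = max(1, int(round(config.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx = val_idx
    opt = Adam(net, lr=config.learning_rate)

    best = net.get_params()
    best_val = np.inf
    stall = 0
    val_losses: list[float] = []
    for _epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), config.train_batch_size):
            batch = order[start : start + config.train_batch_size]
            if len(batch) < 2:
                continue
            loss, grads = _loss_and_grads(net, Zs, Xs, logp, batch, atomic, config.n_atoms, rng)
            if not np.isfinite(loss):
                raise EngineError("non-finite training loss")
            opt.step(grads)
        vloss, _ = _loss_and_grads(net, Zs, Xs, logp, val_idx, atomic, config.n_atoms, rng, want_grads=False)
        val_losses.append(vloss)
        if vloss < best_val - 1e-6:
            best_val = vloss
            best = net.get_params()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    net.set_params(best)
    return val_losses


# ---------------------------------------------------------------------------
# the sequential fit


def fit_patient(
    x_o: SummaryVector | np.ndarray,
    prior: PriorSpec,
    forward,
    config: EngineConfig,
) -> tuple[PosteriorModel, list[RoundLog]]:
    """Sequential neural posterior estimation for one observation.

    Parameters
    ----------
    x_o
        The patient's (normalized) summary-vector observation; a
        :class:`~npfit.features.SummaryVector` or a dense array.
    prior
        Lognormal prior over the parametrization (noise scale included).
    forward
        Stochastic-simulator contract: callable ``(ParamVector, rng) ->
        ndarray | None`` returning the summary vector of one simulator
        draw on the patient's observation schedule, or ``None`` for an
        invalid simulation.
    config
        Round/estimator configuration; all randomness derives from
        ``config.seed``.
    """
    x_dense = x_o.imputed_dense(0.0) if isinstance(x_o, SummaryVector) else np.asarray(x_o, dtype=float)
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_prior, rng_sim, rng_train, rng_prop = (np.random.default_rng(s) for s in ss.spawn(5))

    dim = prior.dim
    net = MADE(dim, len(x_dense), config.hidden_units, rng_init)
    standardizer: _Standardizer | None = None
    model: PosteriorModel | None = None

    Z_rows: list[np.ndarray] = []
    X_rows: list[np.ndarray] = []
    logs: list[RoundLog] = []
    for round_index in range(1, config.n_rounds + 1):
        if round_index == 1:
            thetas = [t.as_array() for t in prior_sample(prior, config.n_sims_per_round, rng_prior)]
            source = "prior"
        else:
            assert model is not None
            thetas = list(model.sample_arrays(config.n_sims_per_round, rng_prop))
            source = "posterior"

        n_invalid = 0
        for values in thetas:
            if not np.all(np.isfinite(values)) or np.any(values <= 0):
                n_invalid += 1
                continue
            x = forward(ParamVector(prior.names, values, prior.frozen), rng_sim)
            if x is None or not np.all(np.isfinite(x)):
                n_invalid += 1
                continue
            Z_rows.append(np.log(values))
            X_rows.append(np.asarray(x, dtype=float))
        if n_invalid == len(thetas):
            raise EngineError(f"round {round_index}: all {n_invalid} simulations invalid")

        Z = np.array(Z_rows)
        X = np.array(X_rows)
        if standardizer is None:
            standardizer = _Standardizer.fit(Z, X)
        logp = log_density_log_space(prior, Z)

        val_losses = _train_round(
            net,
            standardizer.z(Z),
            standardizer.x(X),
            logp,
            atomic=round_index > 1,
            config=config,
            rng=rng_train,
        )
        logs.append(RoundLog(round_index, source, n_invalid, val_losses))
        model = PosteriorModel(net, standardizer, x_dense, prior.names, dict(prior.frozen))

    assert model is not None
    return model, logs
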