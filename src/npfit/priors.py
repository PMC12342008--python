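"""Lognormal priors over virtual-patient parametrizations.

Plain fitting centers the prior on the reference parametrization
(``loc = ln theta_ref``, shared ``scale``); nearest-patient fitting centers
it on the learned parametrization of the most similar already-fitted
patient, with the same scale.  Marginals are independent; the lognormal
keeps all parameters positive and gives comparable relative variability
across parameters of different magnitude with a single scale value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParamVector

__all__ = ["PriorSpec", "prior_from_center", "sample", "log_density"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Independent lognormal prior: per-dimension (loc, scale) in log space."""

    names: tuple[str, ...]
    loc: np.ndarray
    scale: np.ndarray
    frozen: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "loc", np.asarray(self.loc, dtype=float))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float))
        object.__setattr__(self, "frozen", dict(self.frozen))
        d = len(self.names)
        if self.loc.shape != (d,) or self.scale.shape != (d,):
            raise ValueError("loc/scale must have one entry per parameter")
        if np.any(self.scale <= 0):
            raise ValueError("prior scales must be > 0")

    @property
    def dim(self) -> int:
        return len(self.names)

    def median(self) -> ParamVector:
        """The marginal-median parametrization (lognormal median = exp(loc))."""
        return ParamVector(self.names, np.exp(self.loc), self.frozen)


def prior_from_center(center: ParamVector, scale: float = 0.25, noise_loc: float = 0.2) -> PriorSpec:
    """Lognormal prior centered on a parametrization.

    Simulator dimensions get ``loc = ln(center)``; the noise dimension is
    centered at ``noise_loc`` regardless of the center's own sigma, so the
    prior belief about measurement noise is not inherited from a
    previously fitted patient.
    """
    if scale <= 0:
        raise ValueError("prior scale must be > 0")
    if noise_loc <= 0:
        raise ValueError("noise_loc must be > 0")
    values = center.as_array()
    if np.any(values <= 0):
        raise ValueError("center must be strictly positive")
    loc = np.log(values)
    loc[-1] = np.log(noise_loc)
    return PriorSpec(center.names, loc, np.full(len(center.names), float(scale)), dict(center.frozen))


def sample(prior: PriorSpec, n: int, seed: int | np.random.Generator) -> list[ParamVector]:
    """``n`` independent reproducible draws, all strictly positive."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.normal(prior.loc, prior.scale, size=(n, prior.dim))
    return [ParamVector(prior.names, np.exp(row), prior.frozen) for row in z]


def log_density(prior: PriorSpec, theta: ParamVector | np.ndarray) -> float:
    """Sum of independent lognormal log-densities; -inf off the support."""
    values = theta.as_array() if isinstance(theta, ParamVector) else np.asarray(theta, dtype=float)
    if values.shape != (prior.dim,):
        raise ValueError("dimension mismatch")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        return -np.inf
    z = np.log(values)
    resid = (z - prior.loc) / prior.scale
    return float(np.sum(-0.5 * _LOG_2PI - np.log(prior.scale) - z - 0.5 * resid**2))


def log_density_log_space(prior: PriorSpec, z: np.ndarray) -> np.ndarray:
    """Log-density of the prior over z = ln(theta), vectorized over rows.

    Used by the engine's atomic proposal correction, which works in log
    space throughout (the log-transform Jacobians cancel inside the
    softmax).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    resid = (z - prior.loc) / prior.scale
    return np.sum(-0.5 * _LOG_2PI - np.log(prior.scale) - 0.5 * resid**2, axis=1)
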