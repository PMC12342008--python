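"""Parameter vectors for virtual patients.

A virtual patient is a named, strictly positive parametrization of the
mechanistic simulator, together with the scale of the multiplicative
lognormal measurement noise.  Only a subset of the simulator parameters is
fitted; the remainder is frozen at the reference parametrization and
carried along so a :class:`ParamVector` is always sufficient to simulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

SIGMA = "sigma"


@dataclass(frozen=True)
class ParamVector:
    """Named positive simulator parameters plus the noise scale.

    Parameters
    ----------
    names
        Fitted simulator parameter names, with ``"sigma"`` (the noise
        scale) as the final entry.  The ordering is fixed and shared with
        priors and posterior models.
    values
        Strictly positive values, one per name.
    frozen
        Non-fitted simulator parameters, taken from the reference
        parametrization.
    """

    names: tuple[str, ...]
    values: np.ndarray
    frozen: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "frozen", dict(self.frozen))
        if len(self.names) != values.shape[0]:
            raise ValueError("names and values length mismatch")
        if not self.names or self.names[-1] != SIGMA:
            raise ValueError("last parameter must be the noise scale 'sigma'")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("all parameter values must be finite and > 0")
        overlap = set(self.names) & set(self.frozen)
        if overlap:
            raise ValueError(f"parameters both fitted and frozen: {sorted(overlap)}")

    # -- accessors ---------------------------------------------------------
    @property
    def sigma(self) -> float:
        """Noise scale of the multiplicative lognormal observation noise."""
        return float(self.values[-1])

    @property
    def fit_names(self) -> tuple[str, ...]:
        """Fitted simulator parameter names (noise scale excluded)."""
        return self.names[:-1]

    def theta(self) -> dict[str, float]:
        """Fitted simulator parameters as a mapping (noise excluded)."""
        return {n: float(v) for n, v in zip(self.names[:-1], self.values[:-1])}

    def full_theta(self) -> dict[str, float]:
        """All simulator parameters: frozen values overridden by fitted ones."""
        out = dict(self.frozen)
        out.update(self.theta())
        return out

    def as_array(self) -> np.ndarray:
        """Values in canonical order (fitted parameters, then sigma)."""
        return self.values.copy()

    def replace_values(self, values: np.ndarray) -> "ParamVector":
        """A new vector with the same names/frozen set but new values."""
        return ParamVector(self.names, np.asarray(values, dtype=float), self.frozen)

    @classmethod
    def from_mapping(
        cls,
        theta: Mapping[str, float],
        sigma: float,
        frozen: Mapping[str, float] | None = None,
        order: tuple[str, ...] | None = None,
    ) -> "ParamVector":
        names = tuple(order) if order is not None else tuple(theta)
        values = np.array([theta[n] for n in names] + [sigma], dtype=float)
        return cls(names + (SIGMA,), values, frozen or {})
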