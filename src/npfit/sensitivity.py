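"""Global sensitivity analysis for fitting-parameter selection.

Total-order Sobol indices are estimated with Saltelli's scheme: two
quasi-random base matrices A and B (Sobol sequence) over uniform
+-range_fraction intervals around the reference parametrization, plus the
k radial matrices AB_i; the total-order index per output uses the Jansen
estimator

    S_T,i = mean_j (f(A_j) - f(AB_i,j))^2 / (2 * Var(f)).

Per-parameter indices are condensed across outputs by variance weighting:

    S_agg,i = sum_j S_{X_j, theta_i} * Var(X_j) / sum_j Var(X_j)

so outputs that actually vary dominate the aggregate.  Parameter
selection combines an expert priority list with the most sensitive of the
remaining parameters by aggregated index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .surrogate import SimulationError, SimulatorSpec, simulate

__all__ = ["SobolResult", "saltelli_sample", "saltelli_indices", "aggregate_index", "select_parameters"]


@dataclass
class SobolResult:
    """Total-order indices per (parameter, output) with output variances."""

    parameters: tuple[str, ...]
    outputs: tuple[str, ...]
    total_order: np.ndarray  # (n_params, n_outputs)
    variances: np.ndarray  # (n_outputs,)
    n_base: int
    range_fraction: float
    seed: int

    def aggregated(self) -> dict[str, float]:
        return {p: aggregate_index(self, p) for p in self.parameters}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        agg = self.aggregated()
        for i, p in enumerate(self.parameters):
            for j, o in enumerate(self.outputs):
                rows.append(
                    {"parameter": p, "output": o, "total_order": self.total_order[i, j], "variance": self.variances[j], "aggregated": agg[p]}
                )
        return pd.DataFrame(rows)


def saltelli_sample(n_base: int, lower: np.ndarray, upper: np.ndarray, seed: int) -> np.ndarray:
    """Saltelli design: rows of A, B, then AB_1..AB_k; shape ((k+2)N, k)."""
    k = len(lower)
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    base = sampler.random(n_base)
    A = lower + base[:, :k] * (upper - lower)
    B = lower + base[:, k:] * (upper - lower)
    blocks = [A, B]
    for i in range(k):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    return np.vstack(blocks)


def total_order_indices(f_values: np.ndarray, n_base: int, k: int) -> tuple[np.ndarray, float]:
    """Jansen total-order estimator from a Saltelli design evaluation.

    ``f_values`` holds the scalar output on the stacked design
    (A, B, AB_1..AB_k); returns (indices per parameter, output variance).
    """
    fA = f_values[:n_base]
    fB = f_values[n_base : 2 * n_base]
    var = float(np.var(np.concatenate([fA, fB])))
    indices = np.zeros(k)
    for i in range(k):
        fAB = f_values[(2 + i) * n_base : (3 + i) * n_base]
        indices[i] = np.mean((fA - fAB) ** 2) / (2.0 * var) if var > 0 else 0.0
    return indices, var


def saltelli_indices(
    spec: SimulatorSpec,
    parameter_subset: Sequence[str] | None = None,
    range_fraction: float = 0.3,
    outputs: Sequence[tuple[str, float]] | None = None,
    N: int = 1024,
    seed: int = 0,
    model: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SobolResult:
    """Total-order Sobol indices of the treated simulation.

    Parameters vary uniformly in ``[ref*(1-f), ref*(1+f)]``.  Outputs
    default to every biomarker at weeks 4, 12 and 24 (snapshots during
    drug treatment).  ``model`` overrides the simulator with an arbitrary
    vectorless function row -> outputs (used for analytic verification).
    """
    if not 0 < range_fraction < 1:
        raise ValueError("range_fraction must lie in (0, 1)")
    params = tuple(parameter_subset) if parameter_subset is not None else spec.parameter_names
    ref = np.array([spec.reference[p] for p in params])
    lower = ref * (1.0 - range_fraction)
    upper = ref * (1.0 + range_fraction)

    if outputs is None:
        weeks = [w for w in (4.0, 12.0, 24.0) if w in spec.observation_grid]
        outputs = [(b, w) for b in spec.biomarker_names for w in weeks]
    outputs = list(outputs)
    out_names = tuple(f"{b}@wk{w:g}" for b, w in outputs)

    design = saltelli_sample(N, lower, upper, seed)
    k = len(params)
    values = np.full((design.shape[0], len(outputs)), np.nan)
    failures = 0
    for r, row in enumerate(design):
        if model is not None:
            values[r] = model(row)
            continue
        theta = dict(zip(params, row))
        try:
            traj = simulate(theta, spec)
        except SimulationError:
            failures += 1
            continue
        for j, (b, w) in enumerate(outputs):
            values[r, j] = traj.values_at(b, np.array([w]))[0]
    if failures > 0.05 * design.shape[0]:
        raise RuntimeError(f"{failures}/{design.shape[0]} simulations failed in the Sobol design")
    if failures:
        col_means = np.nanmean(values, axis=0)
        bad = np.isnan(values[:, 0])
        values[bad] = col_means  # rare failures imputed by the design mean

    total = np.zeros((k, len(outputs)))
    variances = np.zeros(len(outputs))
    for j in range(len(outputs)):
        total[:, j], variances[j] = total_order_indices(values[:, j], N, k)
    return SobolResult(params, out_names, total, variances, N, range_fraction, seed)


def aggregate_index(result: SobolResult, parameter: str) -> float:
    """Variance-weighted mean of a parameter's per-output total-order indices."""
    if parameter not in result.parameters:
        raise KeyError(parameter)
    total_var = float(result.variances.sum())
    if total_var <= 0:
        raise ValueError("all output variances are zero: aggregated index undefined")
    i = result.parameters.index(parameter)
    return float(np.sum(result.total_order[i] * result.variances) / total_var)


def select_parameters(result: SobolResult, expert_list: Sequence[str], k: int) -> list[str]:
    """Expert-priority parameters plus the most sensitive of the rest.

    Returns ``expert_list`` followed by the top ``k - len(expert_list)``
    remaining parameters by aggregated total-order index (ties broken by
    identifier).
    """
    expert = list(expert_list)
    if k < len(expert):
        raise ValueError("k must be >= the number of expert-priority parameters")
    if k > len(result.parameters):
        raise ValueError("k exceeds the number of analyzed parameters")
    unknown = [p for p in expert if p not in result.parameters]
    if unknown:
        raise KeyError(f"expert parameters not analyzed: {unknown}")
    agg = result.aggregated()
    remaining = [p for p in result.parameters if p not in expert]
    remaining.sort(key=lambda p: (-agg[p], p))
    return expert + remaining[: k - len(expert)]
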