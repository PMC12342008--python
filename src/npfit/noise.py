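"""Stochastic simulator: multiplicative lognormal observation noise.

The deterministic surrogate is wrapped into the stochastic simulator used
for inference training: every observed value ``v`` becomes
``v * exp(eps)`` with ``eps ~ Normal(0, sigma^2)``, independently per
biomarker and time point.  The noise scale ``sigma`` is itself part of the
parameter vector, so the appropriate amount of measurement noise is
learned per patient.  Evaluation against data always uses the noise-free
simulator: sigma models measurement error, not biology.
"""

from __future__ import annotations

import numpy as np

from .features import NormalizationModel, SummaryVector, summarize
from .params import ParamVector
from .surrogate import PatientRecord, SimulationError, SimulatorSpec, TrajectorySet, simulate

__all__ = ["apply_noise", "stochastic_forward", "make_forward"]


def apply_noise(traj: TrajectorySet, sigma: float, seed: int | np.random.Generator) -> TrajectorySet:
    """Multiply every value by lognormal noise with the given scale."""
    if sigma < 0:
        raise ValueError("noise scale must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for b, (times, values) in traj.series.items():
        if sigma == 0:
            out[b] = (times.copy(), values.copy())
        else:
            out[b] = (times.copy(), values * np.exp(rng.normal(0.0, sigma, size=values.size)))
    return TrajectorySet(out)


def stochastic_forward(
    theta: ParamVector,
    target: PatientRecord,
    spec: SimulatorSpec,
    seed: int | np.random.Generator,
    normalizer: NormalizationModel | None = None,
) -> SummaryVector | None:
    """One stochastic simulator draw on the target patient's schedule.

    Simulates ``theta``, restricts the trajectories to the biomarkers and
    time points the target patient was actually measured on, applies
    multiplicative lognormal noise with ``theta.sigma`` and summarizes.
    Returns ``None`` on simulation failure (the caller drops the sample).
    """
    try:
        traj = simulate(theta, spec)
    except SimulationError:
        return None
    restricted = traj.restrict(target)
    noisy = apply_noise(restricted, theta.sigma, seed)
    record = PatientRecord(target.patient_id, {b: (t, np.maximum(v, 1e-300)) for b, (t, v) in noisy.series.items()})
    sv = summarize(record, spec.biomarker_names)
    if normalizer is not None:
        sv = normalizer.normalize(sv)
    return sv


def make_forward(
    target: PatientRecord,
    spec: SimulatorSpec,
    normalizer: NormalizationModel,
):
    """Forward-contract closure for the inference engine.

    Returns a callable ``(theta, rng) -> ndarray | None`` producing the
    dense normalized summary vector (masked features imputed to 0) or
    ``None`` for an invalid simulation.
    """

    def forward(theta: ParamVector, rng: np.random.Generator):
        sv = stochastic_forward(theta, target, spec, rng, normalizer)
        return None if sv is None else sv.imputed_dense(0.0)

    return forward
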