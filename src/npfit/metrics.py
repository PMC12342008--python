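"""Evaluation of virtual-patient parametrizations.

The fit quality of a parametrization theta against a patient's clinical
observations c is the max-scaled mean squared deviation

    L(theta, c) = 1 / (sum_b T_b) * sum_b sum_t
                  ( (sim_{b,t}(theta) - c_{b,t}) / max_t' c_{b,t'} )^2

over the patient's observed biomarkers b and measurement times t; the
max-scaling (maximum over that biomarker's observations) weights
biomarkers on different scales equally.  Performance relative to the
reference parametrization is the relative loss reduction

    gap = (L(theta_ref) - L(theta)) / L(theta_ref)

with gap = 1 the best possible case, gap = 0 no improvement and gap < 0 a
worse fit than the reference.  For a learned posterior, the ultimate
parametrization is the best of n (default 100) posterior samples, and the
fraction of samples beating the reference summarizes the quality of the
whole distribution.

Evaluation always uses the noise-free simulator: the fitted noise scale
models measurement error, not biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import PosteriorModel
from .params import ParamVector
from .surrogate import PatientRecord, SimulationError, SimulatorSpec, simulate

__all__ = [
    "loss",
    "gap",
    "best_of_posterior",
    "frac_better",
    "posterior_metrics",
    "EvaluationReport",
    "evaluation_report",
]


def loss(theta: ParamVector, patient: PatientRecord, spec: SimulatorSpec) -> float:
    """Max-scaled mean squared deviation of the noise-free simulation."""
    traj = simulate(theta, spec)
    total = 0.0
    n_obs = 0
    for b, (times, observed) in patient.series.items():
        scale = float(np.max(observed))
        if scale == 0:
            warnings.warn(f"{patient.patient_id}/{b}: observed maximum is 0; biomarker skipped")
            continue
        sim = traj.values_at(b, times)
        total += float(np.sum(((sim - observed) / scale) ** 2))
        n_obs += times.size
    if n_obs == 0:
        raise ValueError("no usable observations for loss computation")
    return total / n_obs


def gap(theta: ParamVector, patient: PatientRecord, spec: SimulatorSpec, reference: ParamVector | None = None) -> float:
    """Relative reduction of the reference loss; <= 1, negative when worse."""
    if reference is None:
        reference = spec.reference_param_vector(theta.fit_names)
    loss_ref = loss(reference, patient, spec)
    if loss_ref == 0:
        raise ValueError("reference loss is 0: gap undefined (reference already perfect)")
    return (loss_ref - loss(theta, patient, spec)) / loss_ref


def posterior_metrics(
    model: PosteriorModel,
    patient: PatientRecord,
    spec: SimulatorSpec,
    reference: ParamVector,
    n: int = 100,
    seed: int = 0,
) -> tuple[ParamVector, float, float]:
    """(best sample, its loss, fraction of samples beating the reference).

    One shared set of ``n`` posterior draws is evaluated noise-free, so
    the best-of-n parametrization and the better-than-reference fraction
    are consistent by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = model.sample(n, seed)
    loss_ref = loss(reference, patient, spec)
    losses = np.full(n, np.inf)
    for k, theta in enumerate(samples):
        try:
            losses[k] = loss(theta, patient, spec)
        except SimulationError:
            continue
    if not np.any(np.isfinite(losses)):
        raise RuntimeError("all posterior-sample simulations failed")
    best_idx = int(np.argmin(losses))  # ties resolved by first occurrence
    frac = float(np.mean(losses < loss_ref))
    return samples[best_idx], float(losses[best_idx]), frac


def best_of_posterior(
    model: PosteriorModel,
    patient: PatientRecord,
    spec: SimulatorSpec,
    n: int = 100,
    seed: int = 0,
) -> tuple[ParamVector, float]:
    """The best of n posterior samples and its noise-free loss."""
    reference = spec.reference_param_vector(model.names[:-1])
    theta, loss_best, _ = posterior_metrics(model, patient, spec, reference, n, seed)
    return theta, loss_best


def frac_better(
    model: PosteriorModel,
    patient: PatientRecord,
    spec: SimulatorSpec,
    n: int = 100,
    seed: int = 0,
) -> float:
    """Fraction of n posterior samples with loss strictly below the reference."""
    reference = spec.reference_param_vector(model.names[:-1])
    _, _, frac = posterior_metrics(model, patient, spec, reference, n, seed)
    return frac


@dataclass
class EvaluationReport:
    """Population-level evaluation tables.

    per_patient
        One row per patient: loss_ref, loss_fit, gap, frac_better.
    pooled_pairs
        One row per (patient, biomarker, time): observed vs simulated
        value at the fitted parametrization (density-correlation input).
    week24
        Observed and simulated biomarker values at the week-24 endpoint.
    """

    per_patient: pd.DataFrame
    pooled_pairs: pd.DataFrame
    week24: pd.DataFrame

    def to_csv(self, prefix: str) -> None:
        self.per_patient.to_csv(f"{prefix}_per_patient.csv", index=False)
        self.pooled_pairs.to_csv(f"{prefix}_pooled_pairs.csv", index=False)
        self.week24.to_csv(f"{prefix}_week24.csv", index=False)


def evaluation_report(results, cohort: list[PatientRecord], spec: SimulatorSpec) -> EvaluationReport:
    """Assemble per-patient metrics and visual-predictive-check tables."""
    by_id = {p.patient_id: p for p in cohort}
    result_ids = {r.patient_id for r in results}
    if result_ids != set(by_id):
        raise ValueError("results and cohort patient ids do not match")

    rows = []
    pairs = []
    week24 = []
    for r in results:
        patient = by_id[r.patient_id]
        rows.append(
            {
                "patient_id": r.patient_id,
                "loss_ref": r.loss_ref,
                "loss_fit": r.loss_best,
                "gap": r.gap,
                "frac_better": r.frac_better,
            }
        )
        if r.theta_best is None:
            continue
        traj = simulate(r.theta_best, spec)
        for b, (times, observed) in patient.series.items():
            sim = traj.values_at(b, times)
            for t, o, s in zip(times, observed, sim):
                pairs.append({"patient_id": r.patient_id, "biomarker": b, "time_weeks": t, "observed": o, "simulated": s})
                if t == times.max() and t >= 24:
                    week24.append({"patient_id": r.patient_id, "biomarker": b, "observed": o, "simulated": s})
    return EvaluationReport(pd.DataFrame(rows), pd.DataFrame(pairs), pd.DataFrame(week24))
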