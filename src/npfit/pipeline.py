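"""Cohort fitting: plain per-patient inference and the nearest-patient-fit
(NPF) pipeline.

NPF treats cohort fitting as a sequential procedure.  A knowledge
container is initialized with the reference patient (the noise-free
reference simulation paired with the reference parametrization).  In each
step the pending patients nearest to the container — under the
missing-data-aware similarity metric on summary features — are selected
as a batch; each batch patient's prior is centered on the learned
parametrization of its nearest container entry; the patients are fitted;
fits whose best posterior sample beats the reference loss pass the
quality gate and extend the container (gate-failing fits remain part of
the learned virtual population but seed no priors).  The container is
frozen within a batch, so same-batch patients never serve as each other's
neighbors.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .engine import EngineConfig, EngineError, PosteriorModel, fit_patient
from .features import NormalizationModel, SummaryVector, distance, fit_normalizer, nearest, summarize
from .noise import make_forward
from .params import ParamVector
from .priors import prior_from_center
from .surrogate import DEFAULT_FIT_PARAMS, PatientRecord, SimulatorSpec, simulate

__all__ = [
    "REFERENCE_ID",
    "ContainerEntry",
    "KnowledgeContainer",
    "FitResult",
    "PipelineConfig",
    "derive_seed",
    "init_container",
    "select_batch",
    "quality_gate",
    "run_pipeline",
]

logger = logging.getLogger("npfit")

REFERENCE_ID = "__reference__"


def derive_seed(master: int, patient_id: str, stage: str) -> int:
    """Stable per-(patient, stage) seed below 2**31, independent of order."""
    digest = hashlib.sha256(f"{master}:{patient_id}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ContainerEntry:
    summary: SummaryVector  # normalized
    theta: ParamVector  # learned parametrization (reference for the seed entry)
    loss: float | None  # achieved loss; None for the reference entry


class KnowledgeContainer:
    """Append-only store of successful patient fits, seeded by the reference."""

    def __init__(self, reference_entry: ContainerEntry):
        self.reference_id = REFERENCE_ID
        self.entries: dict[str, ContainerEntry] = {REFERENCE_ID: reference_entry}

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, patient_id: str, summary: SummaryVector, theta: ParamVector, loss: float, loss_ref: float) -> None:
        if patient_id in self.entries:
            raise ValueError(f"container entry {patient_id!r} already present")
        if not loss < loss_ref:
            raise ValueError("gate condition violated: stored loss must beat the reference loss")
        self.entries[patient_id] = ContainerEntry(summary, theta, loss)


@dataclass
class FitResult:
    """Per-patient outcome of a fitting run."""

    patient_id: str
    posterior: PosteriorModel | None
    theta_best: ParamVector | None
    loss_best: float
    loss_ref: float
    gap: float
    frac_better: float
    prior_source: str
    gate_passed: bool

    @property
    def failed(self) -> bool:
        return self.theta_best is None


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "npf"  # "sbi" (independent fits) or "npf"
    batch_size: int = 4
    engine: EngineConfig = field(default_factory=EngineConfig)
    prior_scale: float = 0.25
    noise_loc: float = 0.2
    n_posterior_samples: int = 100
    fit_names: tuple[str, ...] = DEFAULT_FIT_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("sbi", "npf"):
            raise ValueError("mode must be 'sbi' or 'npf'")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be > 0")


def init_container(
    spec: SimulatorSpec,
    normalizer: NormalizationModel,
    fit_names: tuple[str, ...] = DEFAULT_FIT_PARAMS,
    noise_loc: float = 0.2,
) -> KnowledgeContainer:
    """Container holding only the reference patient.

    The reference patient is the noise-free simulation of the reference
    parametrization on the full observation grid, summarized and
    normalized like every real cohort member.
    """
    reference = spec.reference_param_vector(fit_names, sigma=noise_loc)
    traj = simulate(reference, spec)
    record = PatientRecord(REFERENCE_ID, {b: (t.copy(), v.copy()) for b, (t, v) in traj.series.items()})
    summary = normalizer.normalize(summarize(record, spec.biomarker_names))
    return KnowledgeContainer(ContainerEntry(summary, reference, None))


def select_batch(
    pending: list[tuple[str, SummaryVector]],
    container: KnowledgeContainer,
    batch_size: int,
) -> list[tuple[str, str]]:
    """The batch_size pending patients nearest to their closest container entry.

    Deterministic: distances sorted ascending with lexicographic patient-id
    tie-breaks; each selected patient is paired with its nearest entry.
    """
    if not pending:
        raise ValueError("no pending patients")
    scored = []
    for pid, sv in sorted(pending):
        nid = nearest(sv, container)
        d = distance(sv, container.entries[nid].summary)
        scored.append((d, pid, nid))
    scored.sort(key=lambda item: (item[0], item[1]))
    return [(pid, nid) for _, pid, nid in scored[:batch_size]]


def quality_gate(result: FitResult) -> bool:
    """True iff the learned parametrization strictly beats the reference."""
    return bool(result.loss_best < result.loss_ref)


def _fit_one(
    patient: PatientRecord,
    summary: SummaryVector,
    spec: SimulatorSpec,
    config: PipelineConfig,
    normalizer: NormalizationModel,
    center: ParamVector,
    prior_source: str,
) -> FitResult:
    reference = spec.reference_param_vector(config.fit_names, sigma=config.noise_loc)
    prior = prior_from_center(center, config.prior_scale, config.noise_loc)
    engine_cfg = EngineConfig(
        **{**config.engine.__dict__, "seed": derive_seed(config.seed, patient.patient_id, "fit")}
    )
    forward = make_forward(patient, spec, normalizer)
    loss_ref = metrics.loss(reference, patient, spec)
    try:
        model, _logs = fit_patient(summary, prior, forward, engine_cfg)
        theta_best, loss_best, frac = metrics.posterior_metrics(
            model,
            patient,
            spec,
            reference,
            n=config.n_posterior_samples,
            seed=derive_seed(config.seed, patient.patient_id, "eval"),
        )
    except (EngineError, RuntimeError) as exc:
        logger.warning("fit failed for %s: %s", patient.patient_id, exc)
        return FitResult(patient.patient_id, None, None, np.nan, loss_ref, np.nan, np.nan, prior_source, False)
    gap_value = (loss_ref - loss_best) / loss_ref if loss_ref > 0 else np.nan
    result = FitResult(
        patient.patient_id,
        model,
        theta_best,
        loss_best,
        loss_ref,
        gap_value,
        frac,
        prior_source,
        gate_passed=loss_best < loss_ref,
    )
    logger.info(
        "fitted %s prior=%s loss_ref=%.4g loss_best=%.4g gap=%.3f frac=%.2f gate=%s",
        patient.patient_id,
        prior_source,
        loss_ref,
        loss_best,
        gap_value,
        frac,
        result.gate_passed,
    )
    return result


def run_pipeline(cohort: list[PatientRecord], spec: SimulatorSpec, config: PipelineConfig) -> list[FitResult]:
    """Fit every cohort patient; exactly one FitResult per patient.

    mode="sbi": every patient fitted independently with the
    reference-centered prior.  mode="npf": batches of nearest patients
    fitted with container-derived priors, the container extended with
    gate-passing fits after each batch.  Per-patient seeds derive from the
    master seed and the patient id, so results are order-independent
    within a batch.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    ids = [p.patient_id for p in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in cohort")
    summaries_raw = {p.patient_id: summarize(p, spec.biomarker_names) for p in cohort}
    all_svs = list(summaries_raw.values())
    normalizer = fit_normalizer(all_svs) if len(all_svs) >= 2 else fit_normalizer(all_svs * 2)
    summaries = {pid: normalizer.normalize(sv) for pid, sv in summaries_raw.items()}
    by_id = {p.patient_id: p for p in cohort}
    reference = spec.reference_param_vector(config.fit_names, sigma=config.noise_loc)

    results: dict[str, FitResult] = {}
    if config.mode == "sbi":
        for pid in ids:
            results[pid] = _fit_one(
                by_id[pid], summaries[pid], spec, config, normalizer, reference, prior_source=REFERENCE_ID
            )
    else:
        container = init_container(spec, normalizer, config.fit_names, config.noise_loc)
        pending = set(ids)
        while pending:
            batch = select_batch([(pid, summaries[pid]) for pid in pending], container, config.batch_size)
            batch_results = []
            for pid, nid in batch:
                center = container.entries[nid].theta
                result = _fit_one(by_id[pid], summaries[pid], spec, config, normalizer, center, prior_source=nid)
                batch_results.append(result)
                pending.discard(pid)
            # container frozen during the batch; extended afterwards
            for result in batch_results:
                results[result.patient_id] = result
                if not result.failed and quality_gate(result):
                    container.add(
                        result.patient_id,
                        summaries[result.patient_id],
                        result.theta_best,
                        result.loss_best,
                        result.loss_ref,
                    )
    return [results[pid] for pid in ids]
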