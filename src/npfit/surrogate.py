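"""Surrogate mechanistic simulator and synthetic patient cohorts.

The simulator is a deliberately small treatment-response model with the
shape of a quantitative systems pharmacology problem: strictly positive
parameters, a treatment effect that drives an inflammatory mediator down,
and several coupled observable biomarkers.  Three states (inflammatory
mediator ``P``, acute-phase biomarker ``C``, degradation biomarker ``M``)
start at their pre-treatment steady state; a drug effect
``E(t) = Emax * (1 - exp(-k_on * t))`` suppresses the production of ``P``:

    dP/dt = k_p * (1 - E(t)) - k_dp * P
    dC/dt = k_c * P - k_dc * C
    dM/dt = k_m * P - k_dm * M

Observables: ``CRP_like = C``, ``MMP_like = M``,
``CELL_like = L0 * (1 + a_L * P)`` and the composite disease score
``SCORE_like = d0 + d1 * ln(1 + C) + d2 * P``.

The cohort generator draws per-patient true parametrizations lognormally
around the reference, simulates them, applies multiplicative lognormal
measurement noise and thins biomarkers/time points to emulate sparse
clinical sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import SIGMA, ParamVector

__all__ = [
    "SimulationError",
    "SimulatorSpec",
    "TrajectorySet",
    "PatientRecord",
    "CohortTruth",
    "default_spec",
    "reference_vector",
    "simulate",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_truth_csv",
    "read_truth_csv",
]

#: reference ("typical treated patient") parametrization of the surrogate
DEFAULT_REFERENCE: dict[str, float] = {
    "k_p": 10.0,
    "k_dp": 1.0,
    "k_c": 2.0,
    "k_dc": 0.5,
    "k_m": 1.0,
    "k_dm": 0.4,
    "L0": 2.0,
    "a_L": 0.05,
    "d0": 2.0,
    "d1": 1.5,
    "d2": 0.1,
    "Emax": 0.6,
    "k_on": 0.5,
}

#: default subset of parameters exposed to fitting (plus the noise scale);
#: chosen with the sensitivity module to mirror GSA + expert selection
DEFAULT_FIT_PARAMS: tuple[str, ...] = (
    "k_p",
    "k_dp",
    "k_c",
    "k_dc",
    "k_m",
    "Emax",
    "k_on",
)

DEFAULT_BIOMARKERS: tuple[str, ...] = ("CRP_like", "MMP_like", "CELL_like", "SCORE_like")

#: biomarkers never dropped by the cohort generator (clinical core readouts)
CORE_BIOMARKERS: tuple[str, ...] = ("CRP_like", "SCORE_like")

#: eight measurement weeks from baseline to 24 weeks of treatment
DEFAULT_GRID: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)


class SimulationError(RuntimeError):
    """Raised when the ODE solve fails or produces non-finite state."""


@dataclass(frozen=True)
class SimulatorSpec:
    """Simulator definition: parameters, reference, observables, grid."""

    parameter_names: tuple[str, ...] = tuple(DEFAULT_REFERENCE)
    reference: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_REFERENCE))
    biomarker_names: tuple[str, ...] = DEFAULT_BIOMARKERS
    observation_grid: tuple[float, ...] = DEFAULT_GRID
    solver_abs_tol: float = 1e-6
    solver_rel_tol: float = 1e-6

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameter_names", tuple(self.parameter_names))
        object.__setattr__(self, "reference", dict(self.reference))
        object.__setattr__(self, "biomarker_names", tuple(self.biomarker_names))
        grid = tuple(float(t) for t in self.observation_grid)
        object.__setattr__(self, "observation_grid", grid)
        for name in self.parameter_names:
            v = self.reference.get(name)
            if v is None or not v > 0:
                raise ValueError(f"reference must give a positive value for {name!r}")
        if grid[0] != 0.0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("observation_grid must start at 0 and strictly increase")
        if self.solver_abs_tol <= 0 or self.solver_rel_tol <= 0:
            raise ValueError("solver tolerances must be > 0")

    def reference_param_vector(
        self,
        fit_names: tuple[str, ...] = DEFAULT_FIT_PARAMS,
        sigma: float = 0.2,
    ) -> ParamVector:
        """The reference parametrization restricted to a fitting subset."""
        frozen = {n: self.reference[n] for n in self.parameter_names if n not in fit_names}
        theta = {n: self.reference[n] for n in fit_names}
        return ParamVector.from_mapping(theta, sigma, frozen=frozen, order=fit_names)


def default_spec() -> SimulatorSpec:
    return SimulatorSpec()


def reference_vector(
    spec: SimulatorSpec,
    fit_names: tuple[str, ...] = DEFAULT_FIT_PARAMS,
    sigma: float = 0.2,
) -> ParamVector:
    return spec.reference_param_vector(fit_names, sigma)


@dataclass
class TrajectorySet:
    """Simulated biomarker time courses: biomarker -> (times, values)."""

    series: dict[str, tuple[np.ndarray, np.ndarray]]

    def biomarkers(self) -> tuple[str, ...]:
        return tuple(self.series)

    def restrict(self, patient: "PatientRecord") -> "TrajectorySet":
        """Limit to the biomarkers and times present in a patient record."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for b, (times, _values) in patient.series.items():
            if b not in self.series:
                raise KeyError(f"biomarker {b!r} not simulated")
            out[b] = (times.copy(), self.values_at(b, times))
        return TrajectorySet(out)

    def values_at(self, biomarker: str, times: np.ndarray) -> np.ndarray:
        """Values at the requested times (must lie on the simulated grid)."""
        t_all, v_all = self.series[biomarker]
        idx = np.searchsorted(t_all, times)
        if np.any(idx >= len(t_all)) or not np.allclose(t_all[np.minimum(idx, len(t_all) - 1)], times):
            raise ValueError("requested times are not on the simulated grid")
        return v_all[idx]


@dataclass
class PatientRecord:
    """One patient's observed biomarker time series.

    ``series`` maps biomarker name to ``(times_weeks, values)``; biomarkers
    a patient was never measured on are simply absent from the mapping.
    """

    patient_id: str
    series: dict[str, tuple[np.ndarray, np.ndarray]]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError(f"patient {self.patient_id!r} has no observations")
        for b, (t, v) in self.series.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            self.series[b] = (t, v)
            if t.size == 0:
                raise ValueError(f"{self.patient_id}/{b}: empty series")
            if t.size > 8:
                raise ValueError(f"{self.patient_id}/{b}: more than 8 time points")
            if np.any(t < 0) or np.any(t > 24):
                raise ValueError(f"{self.patient_id}/{b}: times outside [0, 24] weeks")
            if np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"{self.patient_id}/{b}: values must be finite and > 0")

    def biomarkers(self) -> tuple[str, ...]:
        return tuple(self.series)

    def n_observations(self) -> int:
        return sum(t.size for t, _ in self.series.values())


@dataclass
class CohortTruth:
    """Ground-truth generating parametrizations of a synthetic cohort."""

    truth: dict[str, ParamVector]

    def __getitem__(self, patient_id: str) -> ParamVector:
        return self.truth[patient_id]

    def ids(self) -> tuple[str, ...]:
        return tuple(self.truth)


# ---------------------------------------------------------------------------
# simulation


def _full_params(theta: ParamVector | Mapping[str, float], spec: SimulatorSpec) -> dict[str, float]:
    params = dict(spec.reference)
    if isinstance(theta, ParamVector):
        params.update(theta.full_theta())
    else:
        params.update({k: float(v) for k, v in theta.items() if k != SIGMA})
    missing = [n for n in spec.parameter_names if n not in params]
    if missing:
        raise ValueError(f"missing simulator parameters: {missing}")
    return params


def simulate(theta: ParamVector | Mapping[str, float], spec: SimulatorSpec) -> TrajectorySet:
    """Deterministic forward simulation on the observation grid.

    Raises
    ------
    SimulationError
        If the solver fails or any state/observable is non-finite; callers
        running inference treat the draw as invalid rather than crashing.
    """
    p = _full_params(theta, spec)
    for name, v in p.items():
        if not np.isfinite(v) or (v <= 0 and name not in ("d0", "d1", "d2")):
            raise SimulationError(f"non-positive parameter {name}={v}")
    if not 0 <= p["Emax"] < 1:
        raise SimulationError(f"Emax={p['Emax']} outside [0, 1)")

    k_p, k_dp = p["k_p"], p["k_dp"]
    k_c, k_dc = p["k_c"], p["k_dc"]
    k_m, k_dm = p["k_m"], p["k_dm"]
    emax, k_on = p["Emax"], p["k_on"]

    # pre-treatment steady state
    p0 = k_p / k_dp
    y0 = np.array([p0, k_c * p0 / k_dc, k_m * p0 / k_dm])

    def rhs(t: float, y: np.ndarray) -> list[float]:
        effect = emax * (1.0 - np.exp(-k_on * t))
        P, C, M = y
        return [
            k_p * (1.0 - effect) - k_dp * P,
            k_c * P - k_dc * C,
            k_m * P - k_dm * M,
        ]

    grid = np.asarray(spec.observation_grid)
    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        y0,
        t_eval=grid,
        method="LSODA",
        atol=spec.solver_abs_tol,
        rtol=spec.solver_rel_tol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(f"ODE solve failed: {sol.message}")

    P, C, M = sol.y
    observables = {
        "CRP_like": C,
        "MMP_like": M,
        "CELL_like": p["L0"] * (1.0 + p["a_L"] * P),
        "SCORE_like": p["d0"] + p["d1"] * np.log1p(C) + p["d2"] * P,
    }
    series = {}
    for b in spec.biomarker_names:
        v = observables[b]
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise SimulationError(f"non-finite or negative observable {b}")
        series[b] = (grid.copy(), np.asarray(v, dtype=float))
    return TrajectorySet(series)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    n_patients: int,
    spec: SimulatorSpec,
    pop_scale: float = 0.35,
    biomarker_dropout: float = 0.2,
    timepoint_dropout: float = 0.2,
    noise_scale_range: tuple[float, float] = (0.05, 0.2),
    seed: int = 0,
    fit_names: tuple[str, ...] = DEFAULT_FIT_PARAMS,
) -> tuple[list[PatientRecord], CohortTruth]:
    """Generate a synthetic cohort with clinical-data-like sparsity.

    Each patient's true parametrization is drawn per parameter (the fitting
    subset) from ``LogNormal(loc=ln theta_ref, scale=pop_scale)``;
    trajectories are simulated, multiplied by lognormal noise with a
    per-patient scale drawn uniformly from ``noise_scale_range``, and
    thinned: each non-core biomarker is dropped with probability
    ``biomarker_dropout`` and each non-baseline time point independently
    with probability ``timepoint_dropout``.  Fully reproducible from
    ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    for name, prob in (("biomarker_dropout", biomarker_dropout), ("timepoint_dropout", timepoint_dropout)):
        if not 0 <= prob < 1:
            raise ValueError(f"{name} must lie in [0, 1)")
    lo, hi = noise_scale_range
    if lo < 0 or hi < lo:
        raise ValueError("noise_scale_range must be 0 <= lo <= hi")
    if not any(b in CORE_BIOMARKERS for b in spec.biomarker_names):
        raise ValueError("degenerate config: every biomarker could be dropped")

    rng = np.random.default_rng(seed)
    ref = reference_vector(spec, fit_names)
    loc = np.log(ref.values[:-1])

    patients: list[PatientRecord] = []
    truth: dict[str, ParamVector] = {}
    width = max(3, len(str(n_patients)))
    for i in range(n_patients):
        pid = f"P{i:0{width}d}"
        # rejection-sample a simulable true patient (e.g. lognormal draws can
        # push Emax past 1, where the effect model is undefined)
        for _attempt in range(100):
            theta_vals = np.exp(rng.normal(loc, pop_scale)) if pop_scale > 0 else np.exp(loc)
            sigma = rng.uniform(lo, hi) if hi > lo else float(lo)
            true = ParamVector(ref.names, np.append(theta_vals, max(sigma, 1e-12)), ref.frozen)
            try:
                traj = simulate(true, spec)
                break
            except SimulationError:
                continue
        else:
            raise SimulationError("could not draw a simulable patient in 100 attempts")

        series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for b in spec.biomarker_names:
            drop_biomarker = b not in CORE_BIOMARKERS and rng.random() < biomarker_dropout
            times, values = traj.series[b]
            keep = np.ones(times.size, dtype=bool)
            if timepoint_dropout > 0:
                keep[1:] = rng.random(times.size - 1) >= timepoint_dropout
            noisy = values * np.exp(rng.normal(0.0, sigma, size=values.size)) if sigma > 0 else values.copy()
            if drop_biomarker:
                continue  # RNG consumed above so dropout does not shift other draws
            series[b] = (times[keep], noisy[keep])
        patients.append(PatientRecord(pid, series))
        truth[pid] = true
    return patients, CohortTruth(truth)


# ---------------------------------------------------------------------------
# CSV interchange (long format: patient_id, biomarker, time_weeks, value)


def write_cohort_csv(patients: list[PatientRecord], path: str) -> None:
    rows = [
        (p.patient_id, b, t, v)
        for p in patients
        for b, (times, values) in p.series.items()
        for t, v in zip(times, values)
    ]
    pd.DataFrame(rows, columns=["patient_id", "biomarker", "time_weeks", "value"]).to_csv(path, index=False)


def read_cohort_csv(path: str) -> list[PatientRecord]:
    df = pd.read_csv(path)
    expected = ["patient_id", "biomarker", "time_weeks", "value"]
    if list(df.columns) != expected:
        raise ValueError(f"cohort CSV must have columns {expected}, got {list(df.columns)}")
    patients = []
    for pid, group in df.groupby("patient_id", sort=True):
        series = {}
        for b, g in group.groupby("biomarker", sort=True):
            g = g.sort_values("time_weeks")
            series[str(b)] = (g["time_weeks"].to_numpy(float), g["value"].to_numpy(float))
        patients.append(PatientRecord(str(pid), series))
    return patients


def write_truth_csv(truth: CohortTruth, path: str) -> None:
    ids = truth.ids()
    names = truth.truth[ids[0]].names
    rows = [[pid, *truth.truth[pid].values] for pid in ids]
    pd.DataFrame(rows, columns=["patient_id", *names]).to_csv(path, index=False)


def read_truth_csv(path: str, spec: SimulatorSpec) -> CohortTruth:
    df = pd.read_csv(path)
    names = tuple(df.columns[1:])
    fit_names = names[:-1]
    frozen = {n: spec.reference[n] for n in spec.parameter_names if n not in fit_names}
    out = {}
    for _, row in df.iterrows():
        out[str(row["patient_id"])] = ParamVector(names, row[list(names)].to_numpy(float), frozen)
    return CohortTruth(out)
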