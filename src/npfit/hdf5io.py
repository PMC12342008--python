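"""HDF5 interchange of fitting results.

Layout, one group per patient::

    /patients/<id>/samples          (n, dim) posterior draws
    /patients/<id>/parameter_names  string array
    /patients/<id>/theta_best       (dim,) best-of-posterior parametrization
    /patients/<id>/losses           [loss_best, loss_ref]
    /patients/<id>/gap              scalar
    /patients/<id>/frac_better      scalar
    /patients/<id>/prior_source     string
    /patients/<id>/gate_passed      0/1

Numeric payloads round-trip bitwise.  Corrupt or missing patient groups
are reported per patient; intact groups still load.
"""

from __future__ import annotations

import numpy as np

import h5py

from .params import ParamVector
from .pipeline import FitResult

__all__ = ["write_results", "read_results"]


def write_results(results: list[FitResult], path: str, n_samples: int = 100, sample_seed: int = 0) -> None:
    """Write per-patient fit results (posterior draws included when available)."""
    with h5py.File(path, "w") as handle:
        root = handle.create_group("patients")
        for r in results:
            g = root.create_group(r.patient_id)
            if r.theta_best is not None:
                names = r.theta_best.names
                g.create_dataset("parameter_names", data=np.array(names, dtype=h5py.string_dtype()))
                g.create_dataset("theta_best", data=r.theta_best.as_array())
                g.attrs["frozen_names"] = list(r.theta_best.frozen)
                g.attrs["frozen_values"] = [r.theta_best.frozen[k] for k in r.theta_best.frozen]
                if r.posterior is not None:
                    draws = np.array([s.as_array() for s in r.posterior.sample(n_samples, sample_seed)])
                    g.create_dataset("samples", data=draws)
            g.create_dataset("losses", data=np.array([r.loss_best, r.loss_ref]))
            g.create_dataset("gap", data=float(r.gap))
            g.create_dataset("frac_better", data=float(r.frac_better))
            g.create_dataset("prior_source", data=r.prior_source)
            g.create_dataset("gate_passed", data=int(r.gate_passed))


def read_results(path: str) -> tuple[list[FitResult], dict[str, np.ndarray], dict[str, str]]:
    """Load results; returns (results, per-patient samples, per-patient errors).

    The posterior model itself is not reconstructable from disk; results
    carry ``posterior=None`` and the raw draws are returned separately.
    """
    results: list[FitResult] = []
    samples: dict[str, np.ndarray] = {}
    errors: dict[str, str] = {}
    with h5py.File(path, "r") as handle:
        if "patients" not in handle:
            raise ValueError(f"{path}: no /patients group")
        for pid in sorted(handle["patients"]):
            g = handle["patients"][pid]
            try:
                loss_best, loss_ref = (float(v) for v in g["losses"][...])
                theta_best = None
                if "theta_best" in g:
                    names = tuple(n.decode() if isinstance(n, bytes) else str(n) for n in g["parameter_names"][...])
                    frozen_names = list(g.attrs.get("frozen_names", []))
                    frozen_values = list(g.attrs.get("frozen_values", []))
                    frozen = dict(zip(frozen_names, (float(v) for v in frozen_values)))
                    theta_best = ParamVector(names, g["theta_best"][...], frozen)
                if "samples" in g:
                    samples[pid] = g["samples"][...]
                raw_source = g["prior_source"][()]
                results.append(
                    FitResult(
                        patient_id=pid,
                        posterior=None,
                        theta_best=theta_best,
                        loss_best=loss_best,
                        loss_ref=loss_ref,
                        gap=float(g["gap"][()]),
                        frac_better=float(g["frac_better"][()]),
                        prior_source=raw_source.decode() if isinstance(raw_source, bytes) else str(raw_source),
                        gate_passed=bool(int(g["gate_passed"][()])),
                    )
                )
            except (KeyError, OSError, ValueError) as exc:
                errors[pid] = f"{type(exc).__name__}: {exc}"
    return results, samples, errors
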