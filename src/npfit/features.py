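"""Summary-statistic patient features and a missing-data-aware similarity.

Each biomarker time series is reduced to two numbers: its median and its
spread (difference between the 0.9- and 0.1-quantile, linear-interpolation
convention), so K available biomarkers give a 2K-dimensional feature
vector.  Patients are compared by a Euclidean metric over the biomarkers
both have measurements for, rescaled so the distance is stable across
different numbers of common biomarkers:

    d(i, j) = sqrt( 3 / (2 |CB|) * sum_{b in CB}
                    [ (median_i,b - median_j,b)^2 + (spread_i,b - spread_j,b)^2 ] )

computed in a normalized feature space (robust per-feature median/IQR
normalization estimated on the cohort).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .surrogate import PatientRecord

__all__ = [
    "SummaryVector",
    "NormalizationModel",
    "summarize",
    "fit_normalizer",
    "distance",
    "nearest",
    "INCOMPARABLE",
    "summaries_to_csv",
]

#: sentinel distance for patient pairs with no common biomarker; sorts
#: after every finite distance
INCOMPARABLE = math.inf


@dataclass(frozen=True)
class SummaryVector:
    """Per-biomarker (median, spread) features with an availability mask.

    ``median`` and ``spread`` are full-length arrays over
    ``biomarker_names``; entries where ``mask`` is False are NaN.
    """

    biomarker_names: tuple[str, ...]
    median: np.ndarray
    spread: np.ndarray
    mask: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "biomarker_names", tuple(self.biomarker_names))
        object.__setattr__(self, "median", np.asarray(self.median, dtype=float))
        object.__setattr__(self, "spread", np.asarray(self.spread, dtype=float))
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        k = len(self.biomarker_names)
        if not (self.median.shape == self.spread.shape == self.mask.shape == (k,)):
            raise ValueError("median/spread/mask must have one entry per biomarker")
        if not self.normalized and np.any(self.spread[self.mask] < 0):
            raise ValueError("spread must be >= 0 on the raw scale")

    @property
    def n_available(self) -> int:
        return int(self.mask.sum())

    def dense(self) -> np.ndarray:
        """Features of available biomarkers, interleaved; length 2K."""
        out = np.empty(2 * self.n_available)
        out[0::2] = self.median[self.mask]
        out[1::2] = self.spread[self.mask]
        return out

    def imputed_dense(self, fill: float = 0.0) -> np.ndarray:
        """Fixed-length interleaved features with masked entries imputed."""
        med = np.where(self.mask, self.median, fill)
        spr = np.where(self.mask, self.spread, fill)
        out = np.empty(2 * len(self.biomarker_names))
        out[0::2] = med
        out[1::2] = spr
        return out


def summarize(patient: PatientRecord, biomarker_names: Sequence[str] | None = None) -> SummaryVector:
    """Encode a patient as per-biomarker (median, Q0.9 - Q0.1) features."""
    if not patient.series:
        raise ValueError("cannot summarize an empty patient record")
    names = tuple(biomarker_names) if biomarker_names is not None else tuple(patient.series)
    k = len(names)
    median = np.full(k, np.nan)
    spread = np.full(k, np.nan)
    mask = np.zeros(k, dtype=bool)
    for i, b in enumerate(names):
        if b not in patient.series:
            continue
        _, values = patient.series[b]
        median[i] = np.median(values)
        spread[i] = np.quantile(values, 0.9) - np.quantile(values, 0.1)
        mask[i] = True
    if not mask.any():
        raise ValueError("patient has no observations on the requested biomarkers")
    return SummaryVector(names, median, spread, mask)


@dataclass(frozen=True)
class NormalizationModel:
    """Robust per-feature location/scale (median and IQR over the cohort).

    Constant features (IQR zero) fall back to scale 1 so normalization is
    always invertible.
    """

    biomarker_names: tuple[str, ...]
    loc_median: np.ndarray
    scale_median: np.ndarray
    loc_spread: np.ndarray
    scale_spread: np.ndarray

    def normalize(self, sv: SummaryVector) -> SummaryVector:
        if sv.normalized:
            raise ValueError("summary vector already normalized")
        if sv.biomarker_names != self.biomarker_names:
            raise ValueError("biomarker ordering mismatch")
        return SummaryVector(
            sv.biomarker_names,
            (sv.median - self.loc_median) / self.scale_median,
            (sv.spread - self.loc_spread) / self.scale_spread,
            sv.mask,
            normalized=True,
        )

    def denormalize(self, sv: SummaryVector) -> SummaryVector:
        if not sv.normalized:
            raise ValueError("summary vector is not normalized")
        return SummaryVector(
            sv.biomarker_names,
            sv.median * self.scale_median + self.loc_median,
            sv.spread * self.scale_spread + self.loc_spread,
            sv.mask,
            normalized=False,
        )


def fit_normalizer(summaries: Sequence[SummaryVector]) -> NormalizationModel:
    """Estimate robust per-feature statistics over a cohort of summaries."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries to fit a normalizer")
    names = summaries[0].biomarker_names
    if any(s.biomarker_names != names for s in summaries):
        raise ValueError("summaries disagree on biomarker ordering")
    med = np.array([s.median for s in summaries])
    spr = np.array([s.spread for s in summaries])

    def _robust(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        with warnings.catch_warnings():
            # a biomarker no patient carries yields an all-NaN column;
            # it falls back to loc 0 / scale 1 below
            warnings.simplefilter("ignore", RuntimeWarning)
            loc = np.nanmedian(values, axis=0)
            q75 = np.nanquantile(values, 0.75, axis=0)
            q25 = np.nanquantile(values, 0.25, axis=0)
        scale = q75 - q25
        loc = np.where(np.isnan(loc), 0.0, loc)
        scale = np.where(np.isnan(scale) | (scale <= 0), 1.0, scale)
        return loc, scale

    loc_m, scale_m = _robust(med)
    loc_s, scale_s = _robust(spr)
    return NormalizationModel(names, loc_m, scale_m, loc_s, scale_s)


def distance(p_i: SummaryVector, p_j: SummaryVector) -> float:
    """Missing-data-aware Euclidean distance in normalized feature space.

    Returns :data:`INCOMPARABLE` (infinity) when the two patients share no
    biomarker.
    """
    if not (p_i.normalized and p_j.normalized):
        raise ValueError("distance requires normalized summary vectors")
    if p_i.biomarker_names != p_j.biomarker_names:
        raise ValueError("biomarker ordering mismatch")
    common = p_i.mask & p_j.mask
    n_common = int(common.sum())
    if n_common == 0:
        return INCOMPARABLE
    dm = p_i.median[common] - p_j.median[common]
    ds = p_i.spread[common] - p_j.spread[common]
    return math.sqrt(3.0 / (2.0 * n_common) * float(np.sum(dm * dm + ds * ds)))


def nearest(query: SummaryVector, container) -> str:
    """Id of the container entry nearest to ``query``.

    ``container`` is any object with an ``entries`` mapping of
    patient_id -> entry carrying a ``summary`` attribute, and a
    ``reference_id``.  Ties break lexicographically; if every entry is
    incomparable (no common biomarker) the reference entry is returned.
    """
    if not container.entries:
        raise ValueError("container is empty")
    best_id, best_d = None, INCOMPARABLE
    for pid in sorted(container.entries):
        d = distance(query, container.entries[pid].summary)
        if d < best_d:
            best_id, best_d = pid, d
    if best_id is None:
        return container.reference_id
    return best_id


def summaries_to_csv(summaries: Iterable[tuple[str, SummaryVector]], path: str) -> None:
    """Wide CSV export: patient_id, <biomarker>_median, <biomarker>_spread."""
    rows = []
    for pid, sv in summaries:
        row: dict[str, object] = {"patient_id": pid}
        for i, b in enumerate(sv.biomarker_names):
            row[f"{b}_median"] = sv.median[i] if sv.mask[i] else np.nan
            row[f"{b}_spread"] = sv.spread[i] if sv.mask[i] else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
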