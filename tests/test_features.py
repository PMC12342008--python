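"""Summary features, normalization and the missing-data-aware distance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npfit.features import (
    INCOMPARABLE,
    SummaryVector,
    distance,
    fit_normalizer,
    nearest,
    summarize,
)
from npfit.surrogate import PatientRecord


def _record(values_by_biomarker, pid="p"):
    series = {b: (np.arange(len(v), dtype=float), np.asarray(v, dtype=float)) for b, v in values_by_biomarker.items()}
    return PatientRecord(pid, series)


def _sv(names, med, spread, mask=None, normalized=True):
    k = len(names)
    mask = np.ones(k, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    return SummaryVector(names, np.asarray(med, float), np.asarray(spread, float), mask, normalized=normalized)


class TestSummarize:
    def test_median_and_quantile_spread_linear_interpolation(self):
        sv = summarize(_record({"b": [1, 2, 3, 4, 5]}))
        assert sv.median[0] == pytest.approx(3.0)
        # Q0.9 = 4.6, Q0.1 = 1.4 under the linear-interpolation convention
        assert sv.spread[0] == pytest.approx(3.2)

    def test_constant_series_has_zero_spread(self):
        sv = summarize(_record({"b": [7, 7, 7]}))
        assert sv.median[0] == pytest.approx(7.0)
        assert sv.spread[0] == pytest.approx(0.0)

    def test_sixteen_biomarkers_give_32_features(self):
        record = _record({f"b{i:02d}": [1.0, 2.0, 3.0] for i in range(16)})
        sv = summarize(record)
        assert sv.dense().shape == (32,)

    def test_missing_biomarkers_are_masked(self):
        sv = summarize(_record({"a": [1, 2]}), biomarker_names=("a", "b"))
        assert sv.mask.tolist() == [True, False]
        assert sv.dense().shape == (2,)
        assert sv.imputed_dense().shape == (4,)

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            summarize(_record({"a": [1.0]}), biomarker_names=("b",))


class TestNormalizer:
    def test_identical_summaries_fall_back_to_unit_scale(self):
        sv = summarize(_record({"a": [1, 2, 3]}))
        model = fit_normalizer([sv, sv, sv])
        assert np.all(model.scale_median == 1.0)
        assert np.all(model.scale_spread == 1.0)

    def test_location_is_median_over_patients(self):
        a = _sv(("b",), [0.0], [0.0], normalized=False)
        b = _sv(("b",), [10.0], [0.0], normalized=False)
        model = fit_normalizer([a, b])
        assert model.loc_median[0] == pytest.approx(5.0)

    def test_cohort_features_have_median_zero_after_normalization(self, spec, small_cohort):
        patients, _ = small_cohort
        summaries = [summarize(p, spec.biomarker_names) for p in patients]
        model = fit_normalizer(summaries)
        normalized = [model.normalize(s) for s in summaries]
        med = np.nanmedian([s.median for s in normalized], axis=0)
        np.testing.assert_allclose(med, 0.0, atol=1e-12)

    def test_normalize_then_denormalize_is_identity(self, spec, small_cohort, normalizer):
        patients, _ = small_cohort
        sv = summarize(patients[0], spec.biomarker_names)
        back = normalizer.denormalize(normalizer.normalize(sv))
        np.testing.assert_allclose(back.median[back.mask], sv.median[sv.mask], rtol=1e-12)
        np.testing.assert_allclose(back.spread[back.mask], sv.spread[sv.mask], rtol=1e-12)


class TestDistance:
    def test_identical_vectors_have_zero_distance(self):
        a = _sv(("x", "y"), [0.3, -1.0], [0.1, 2.0])
        assert distance(a, a) == 0.0

    def test_single_common_biomarker_hand_value(self):
        a = _sv(("x",), [1.0], [0.0])
        b = _sv(("x",), [0.0], [0.0])
        assert distance(a, b) == pytest.approx(math.sqrt(1.5))

    def test_distance_stable_across_number_of_common_biomarkers(self):
        # each biomarker contributes squared difference 1 -> same distance
        a1 = _sv(("x",), [1.0], [0.0])
        b1 = _sv(("x",), [0.0], [0.0])
        a2 = _sv(("x", "y"), [1.0, 0.0], [0.0, 1.0])
        b2 = _sv(("x", "y"), [0.0, 0.0], [0.0, 0.0])
        assert distance(a1, b1) == pytest.approx(distance(a2, b2))
        assert distance(a2, b2) == pytest.approx(math.sqrt(1.5))

    def test_no_common_biomarker_is_incomparable(self):
        a = _sv(("x", "y"), [1.0, np.nan], [0.0, np.nan], mask=[True, False])
        b = _sv(("x", "y"), [np.nan, 1.0], [np.nan, 0.0], mask=[False, True])
        assert distance(a, b) == INCOMPARABLE
        assert distance(a, b) > 1e12  # sorts after every finite distance

    def test_restriction_property_ignores_uncommon_biomarkers(self, rng):
        names = ("a", "b", "c")
        med = rng.normal(size=3)
        spread = rng.normal(size=3)
        full = _sv(names, med, spread)
        other = _sv(names, rng.normal(size=3), rng.normal(size=3), mask=[True, True, False])
        # changing the uncommon biomarker of `full` must not change d
        med2 = med.copy()
        med2[2] += 100.0
        changed = _sv(names, med2, spread)
        assert distance(full, other) == pytest.approx(distance(changed, other))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 6))
        names = tuple(f"b{i}" for i in range(k))
        mask_a = rng.random(k) < 0.8
        mask_b = rng.random(k) < 0.8
        a = _sv(names, rng.normal(size=k), rng.normal(size=k), mask_a)
        b = _sv(names, rng.normal(size=k), rng.normal(size=k), mask_b)

        common = [i for i in range(k) if mask_a[i] and mask_b[i]]
        if not common:
            assert distance(a, b) == INCOMPARABLE
            return
        acc = 0.0
        for i in common:  # explicit feature loop as independent oracle
            acc += (a.median[i] - b.median[i]) ** 2 + (a.spread[i] - b.spread[i]) ** 2
        expected = math.sqrt(3.0 / (2.0 * len(common)) * acc)
        assert distance(a, b) == pytest.approx(expected)
        assert distance(b, a) == pytest.approx(distance(a, b))
        assert distance(a, b) >= 0.0


class _FakeContainer:
    def __init__(self, entries, reference_id):
        self.entries = entries
        self.reference_id = reference_id


class _Entry:
    def __init__(self, summary):
        self.summary = summary


class TestNearest:
    def test_single_candidate_is_returned(self):
        ref = _Entry(_sv(("x",), [0.0], [0.0]))
        container = _FakeContainer({"ref": ref}, "ref")
        q = _sv(("x",), [5.0], [0.0])
        assert nearest(q, container) == "ref"

    def test_exact_match_wins(self):
        entries = {
            "ref": _Entry(_sv(("x",), [0.0], [0.0])),
            "p1": _Entry(_sv(("x",), [2.0], [1.0])),
        }
        q = _sv(("x",), [2.0], [1.0])
        assert nearest(q, _FakeContainer(entries, "ref")) == "p1"

    def test_minimal_hand_computed_distance_wins(self):
        entries = {
            "a": _Entry(_sv(("x",), [1.2], [0.0])),
            "b": _Entry(_sv(("x",), [0.4], [0.0])),
            "c": _Entry(_sv(("x",), [0.9], [0.0])),
        }
        q = _sv(("x",), [0.0], [0.0])
        assert nearest(q, _FakeContainer(entries, "a")) == "b"

    def test_all_incomparable_falls_back_to_reference(self):
        entries = {"ref": _Entry(_sv(("x", "y"), [0.0, np.nan], [0.0, np.nan], mask=[True, False]))}
        q = _sv(("x", "y"), [np.nan, 1.0], [np.nan, 1.0], mask=[False, True])
        assert nearest(q, _FakeContainer(entries, "ref")) == "ref"
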