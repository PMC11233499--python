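"""Qualifier policy, replicate aggregation, transforms, matrices, splits."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpd_qspr.assay_data import (AssayMeasurement, QualifierPolicy,
                                 aggregate_replicates, apply_qualifier_policy,
                                 build_label_matrix, ingest_measurements,
                                 read_compounds_csv, read_measurements_csv,
                                 temporal_split, write_compounds_csv,
                                 write_measurements_csv)
from tpd_qspr.chemistry import Molecule
from tpd_qspr.tasks import (TaskSpec, default_registry,
                            fraction_unbound_from_percent_bound)


def _spec(task_id):
    return {s.task_id: s for s in default_registry()}[task_id]


def _rec(task, value, qualifier="exact", cid="X1"):
    return AssayMeasurement(compound_id=cid, task_id=task, raw_value=value,
                            qualifier=qualifier)


class TestQualifierPolicy:
    def test_ppb_qualified_records_discarded(self):
        spec = _spec("hPPB")
        records = [_rec("hPPB", 0.1, cid=f"C{i}") for i in range(3)] + [
            _rec("hPPB", 0.01, "less_than", cid="C3"),
            _rec("hPPB", 0.01, "less_than", cid="C4"),
        ]
        kept, dropped = apply_qualifier_policy(records, spec)
        assert len(kept) == 3 and dropped == 2
        assert all(r.qualifier == "exact" for r in kept)

    def test_all_exact_unchanged(self):
        spec = _spec("RLM_CLint")
        records = [_rec("RLM_CLint", v, cid=f"C{i}") for i, v in enumerate([10, 20])]
        kept, dropped = apply_qualifier_policy(records, spec)
        assert kept == records and dropped == 0

    def test_all_qualified_logd_empty_with_audit(self):
        spec = _spec("LogD")
        records = [_rec("LogD", 1.0, "greater_than", cid="A"),
                   _rec("LogD", 2.0, "less_than", cid="B")]
        kept, dropped = apply_qualifier_policy(records, spec)
        assert kept == [] and dropped == 2

    def test_optional_discard_for_clearance(self):
        spec = _spec("RLM_CLint")
        records = [_rec("RLM_CLint", 10.0), _rec("RLM_CLint", 400.0, "greater_than")]
        kept, _ = apply_qualifier_policy(records, spec, QualifierPolicy(discard_everywhere=False))
        assert len(kept) == 2
        kept, _ = apply_qualifier_policy(records, spec, QualifierPolicy(discard_everywhere=True))
        assert len(kept) == 1

    def test_wrong_task_rejected(self):
        with pytest.raises(ValueError):
            apply_qualifier_policy([_rec("LogD", 1.0)], _spec("LogP"))


class TestAggregation:
    def test_geometric_mean(self):
        spec = _spec("RLM_CLint")
        recs = [_rec("RLM_CLint", 1.0), _rec("RLM_CLint", 100.0)]
        assert aggregate_replicates(recs, spec)["X1"] == pytest.approx(10.0)

    def test_singleton_passthrough(self):
        spec = _spec("RLM_CLint")
        assert aggregate_replicates([_rec("RLM_CLint", 7.0)], spec)["X1"] == 7.0

    def test_powers_of_two(self):
        spec = _spec("HLM_CLint")
        recs = [_rec("HLM_CLint", v) for v in (2.0, 4.0, 8.0)]
        assert aggregate_replicates(recs, spec)["X1"] == pytest.approx(4.0)

    def test_identity_task_uses_arithmetic_mean(self):
        spec = _spec("LogD")
        recs = [_rec("LogD", -1.0), _rec("LogD", 3.0)]
        assert aggregate_replicates(recs, spec)["X1"] == pytest.approx(1.0)

    def test_nonpositive_on_log_task_raises(self):
        with pytest.raises(ValueError, match="X1"):
            aggregate_replicates([_rec("RLM_CLint", -1.0)], _spec("RLM_CLint"))

    @given(st.permutations([1.5, 22.0, 7.3, 100.0]))
    @settings(max_examples=20, deadline=None)
    def test_order_invariance(self, values):
        spec = _spec("RLM_CLint")
        recs = [_rec("RLM_CLint", v) for v in values]
        ref = [_rec("RLM_CLint", v) for v in sorted(values)]
        assert aggregate_replicates(recs, spec)["X1"] == pytest.approx(
            aggregate_replicates(ref, spec)["X1"])


class TestTransforms:
    def test_pic50_molar_convention(self):
        assert _spec("CYP3A4_IC50").to_model_scale(1.0) == pytest.approx(6.0)

    def test_clint_log10(self):
        assert _spec("RLM_CLint").to_model_scale(100.0) == pytest.approx(2.0)

    def test_logd_identity(self):
        assert _spec("LogD").to_model_scale(1.9) == 1.9

    def test_percent_bound_conversion(self):
        assert fraction_unbound_from_percent_bound(95.0) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            fraction_unbound_from_percent_bound(101.0)

    def test_log_domain_violation(self):
        with pytest.raises(ValueError):
            _spec("RLM_CLint").to_model_scale(0.0)

    @given(st.floats(min_value=-5, max_value=8))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_all_transforms(self, model_value):
        for tid in ("RLM_CLint", "LogD", "CYP3A4_IC50", "LE-MDCK_v2_Papp", "hPPB"):
            spec = _spec(tid)
            raw = spec.from_model_scale(model_value)
            assert spec.to_model_scale(raw) == pytest.approx(model_value, abs=1e-9)


class TestLabelMatrix:
    def test_mask_counts(self):
        reg = [_spec("LogD"), _spec("LogP")]
        agg = {("A", "LogD"): 1.0, ("B", "LogD"): 2.0,
               ("B", "LogP"): 3.0, ("C", "LogP"): 0.5}
        m = build_label_matrix(agg, reg, compounds=["A", "B", "C"])
        assert m.n_observed == 4
        assert m.compound_ids == ["A", "B", "C"]
        assert m.values[m.row_index()["B"], m.task_ids.index("LogP")] == 3.0

    def test_empty_records_all_false_mask(self):
        m = build_label_matrix({}, [_spec("LogD")], compounds=["A"])
        assert not m.mask.any()

    def test_unknown_task_and_duplicates_rejected(self):
        with pytest.raises(ValueError):
            build_label_matrix({("A", "nope"): 1.0}, [_spec("LogD")])

    def test_generator_density_matches_sparsity(self, small_study):
        matrix, audit = ingest_measurements(small_study.records, small_study.registry)
        p = 0.85  # configured observed fraction
        n_cells = len(small_study.molecules) * len(small_study.registry)
        # qualifier discard removes ~qualifier_rate of observations on top
        p_eff = p * (1 - 0.05)
        se = np.sqrt(p_eff * (1 - p_eff) / n_cells)
        observed = matrix.n_observed / n_cells
        assert abs(observed - p_eff) < 4 * se + 0.01

    def test_density_equals_record_density_exactly(self, clean_study):
        matrix, _ = ingest_measurements(clean_study.records, clean_study.registry)
        assert matrix.n_observed == len(clean_study.records)


class TestTemporalSplit:
    def _mol(self, cid, date):
        return Molecule(cid, "CCO", "other", date)

    def test_cutoff_boundary(self):
        mols = [self._mol("A", dt.date(2021, 12, 31)), self._mol("B", dt.date(2022, 1, 1))]
        split, counts = temporal_split(mols, dt.date(2021, 12, 31))
        assert split.train_ids == ("A",) and split.test_ids == ("B",)
        assert counts["n_train"].sum() == 1 and counts["n_test"].sum() == 1

    def test_all_pre_cutoff_gives_empty_test(self):
        mols = [self._mol("A", dt.date(2020, 1, 1))]
        split, _ = temporal_split(mols, dt.date(2021, 12, 31))
        assert split.test_ids == ()

    def test_partition(self, tiny_library):
        split, _ = temporal_split(tiny_library, dt.date(2021, 12, 31))
        assert len(split.train_ids) + len(split.test_ids) == len(tiny_library)
        assert not set(split.train_ids) & set(split.test_ids)
        by_id = {m.compound_id: m for m in tiny_library}
        assert all(by_id[c].registration_date > dt.date(2021, 12, 31)
                   for c in split.test_ids)

    def test_missing_date_raises(self):
        mol = Molecule("A", "CCO", "other", None)
        with pytest.raises(ValueError, match="A"):
            temporal_split([mol], dt.date(2021, 12, 31))


class TestCsvRoundTrip:
    def test_compounds(self, tmp_path, tiny_library):
        path = tmp_path / "compounds.csv"
        write_compounds_csv(tiny_library, path)
        assert read_compounds_csv(path) == tiny_library

    def test_measurements(self, tmp_path, small_study):
        path = tmp_path / "measurements.csv"
        records = small_study.records[:200]
        write_measurements_csv(records, path)
        back = read_measurements_csv(path)
        assert len(back) == len(records)
        for a, b in zip(back, records):
            assert (a.compound_id, a.task_id, a.qualifier, a.measured_date) == \
                   (b.compound_id, b.task_id, b.qualifier, b.measured_date)
            assert a.raw_value == pytest.approx(b.raw_value, rel=1e-12)
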