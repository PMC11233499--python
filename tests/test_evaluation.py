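"""Baseline predictor, bootstrap, and stratified temporal evaluation."""

import datetime as dt

import numpy as np
import pytest

from tpd_qspr.assay_data import ingest_measurements, temporal_split
from tpd_qspr.evaluation import (baseline_predict, bootstrap_mae,
                                 evaluate_predictions)
from tpd_qspr.model import PredictionTable
from tpd_qspr.assay_data import LabelMatrix
from tpd_qspr.tasks import default_registry

SPECS = {s.task_id: s for s in default_registry()}


def _matrix(values, mask, cids, tids):
    return LabelMatrix(compound_ids=cids, task_ids=tids,
                       values=np.asarray(values, float), mask=np.asarray(mask, bool))


class TestBaseline:
    def test_mean_of_train_labels(self):
        train = _matrix([[1.0], [3.0]], [[True], [True]], ["A", "B"], ["LogD"])
        preds = baseline_predict(train, ["X", "Y", "Z"])
        np.testing.assert_allclose(preds.values, 2.0)

    def test_single_label_constant(self):
        train = _matrix([[7.0]], [[True]], ["A"], ["LogD"])
        preds = baseline_predict(train, ["X"])
        assert preds.values[0, 0] == 7.0

    def test_train_set_baseline_mae_is_mad(self):
        labels = np.array([0.0, 1.0, 5.0])
        train = _matrix(labels[:, None], np.ones((3, 1)), ["A", "B", "C"], ["LogD"])
        preds = baseline_predict(train, ["A", "B", "C"])
        mad = np.abs(labels - labels.mean()).mean()
        assert np.abs(labels - preds.values[:, 0]).mean() == pytest.approx(mad)

    def test_empty_train_task_raises(self):
        train = _matrix([[0.0]], [[False]], ["A"], ["LogD"])
        with pytest.raises(ValueError, match="LogD"):
            baseline_predict(train, ["X"])


class TestBootstrap:
    def test_constant_residuals(self):
        res = bootstrap_mae([1.0] * 10, [1.5] * 10, n_boot=50, seed=0)
        np.testing.assert_allclose(res.mae_samples, 0.5)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        p, y = rng.normal(size=40), rng.normal(size=40)
        a = bootstrap_mae(p, y, n_boot=100, seed=9)
        b = bootstrap_mae(p, y, n_boot=100, seed=9)
        np.testing.assert_array_equal(a.mae_samples, b.mae_samples)

    def test_mean_near_full_sample_mae(self):
        rng = np.random.default_rng(4)
        p, y = rng.normal(size=200), rng.normal(size=200)
        res = bootstrap_mae(p, y, n_boot=1000, seed=1)
        full = np.abs(y - p).mean()
        se = res.mae_samples.std()
        assert abs(res.mae_samples.mean() - full) < 3 * se / np.sqrt(1000) + 1e-3

    def test_quantiles_consistent(self):
        rng = np.random.default_rng(5)
        res = bootstrap_mae(rng.normal(size=30), rng.normal(size=30), n_boot=200, seed=2)
        q = res.quantiles()
        assert q["q1"] <= q["median"] <= q["q3"]
        assert q["whisker_low"] == pytest.approx(q["q1"] - 1.5 * (q["q3"] - q["q1"]))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bootstrap_mae([1.0], [1.0], n_boot=10, seed=0)


class TestEvaluate:
    def _setup(self, clean_study):
        matrix, _ = ingest_measurements(clean_study.records, clean_study.registry)
        modalities = {m.compound_id: m.modality for m in clean_study.molecules}
        return matrix, modalities

    def test_oracle_predictor_scores_zero_error(self, clean_study):
        matrix, modalities = self._setup(clean_study)
        rows = {c: i for i, c in enumerate(clean_study.truth.compound_ids)}
        order = [rows[c] for c in matrix.compound_ids]
        truth_tbl = PredictionTable(
            compound_ids=list(matrix.compound_ids),
            task_ids=list(matrix.task_ids),
            values=clean_study.truth.values[order][:, [
                clean_study.truth.task_ids.index(t) for t in matrix.task_ids]],
            spread=np.zeros_like(matrix.values),
        )
        report = evaluate_predictions(truth_tbl, matrix, matrix,
                                      clean_study.registry, modalities,
                                      n_boot=50, seed=0)
        for res in report.results:
            assert res.regression.mae == pytest.approx(0.0, abs=1e-9)
            if res.classification is not None:
                assert res.classification.error_low == 0.0
                assert res.classification.error_high == 0.0
                # inconclusive percentage equals the truth's medium-band occupancy
                spec = SPECS[res.task_id]
                j = matrix.task_ids.index(res.task_id)
                sub = [i for i, c in enumerate(matrix.compound_ids)
                       if matrix.mask[i, j] and (res.stratum == "all"
                       or modalities[c] == res.stratum)]
                from tpd_qspr.risk import RiskClass, categorize
                med = np.mean([categorize(matrix.values[i, j], spec) is RiskClass.MEDIUM
                               for i in sub]) * 100
                assert res.classification.inconclusive_pct == pytest.approx(med)

    def test_small_strata_skipped_with_audit(self, clean_study):
        matrix, modalities = self._setup(clean_study)
        preds = baseline_predict(matrix, matrix.compound_ids)
        report = evaluate_predictions(preds, matrix, matrix, clean_study.registry,
                                      modalities, min_stratum_size=10**6,
                                      n_boot=10, seed=0)
        assert report.results == []
        assert report.skipped and all(s["n"] < 10**6 for s in report.skipped)

    def test_all_stratum_mae_between_modality_extremes(self, small_study):
        matrix, _ = ingest_measurements(small_study.records, small_study.registry)
        modalities = {m.compound_id: m.modality for m in small_study.molecules}
        preds = baseline_predict(matrix, matrix.compound_ids)
        report = evaluate_predictions(preds, matrix, matrix, small_study.registry,
                                      modalities, n_boot=10, seed=0)
        by_task = {}
        for r in report.results:
            by_task.setdefault(r.task_id, {})[r.stratum] = r.regression.mae
        for task, strata in by_task.items():
            if "all" in strata and len(strata) == 4:
                parts = [v for k, v in strata.items() if k != "all"]
                assert min(parts) - 1e-12 <= strata["all"] <= max(parts) + 1e-12

    def test_report_deterministic(self, clean_study):
        matrix, modalities = self._setup(clean_study)
        preds = baseline_predict(matrix, matrix.compound_ids)
        a = evaluate_predictions(preds, matrix, matrix, clean_study.registry,
                                 modalities, n_boot=25, seed=4).to_json_dict()
        b = evaluate_predictions(preds, matrix, matrix, clean_study.registry,
                                 modalities, n_boot=25, seed=4).to_json_dict()
        assert a == b
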