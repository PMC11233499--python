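"""Ensemble training, prediction, scaffold split, checkpoints."""

import numpy as np
import pytest

from tpd_qspr import model, nn
from tpd_qspr.assay_data import ingest_measurements
from tpd_qspr.chemistry import scaffold_key
from tpd_qspr.model import ModelConfig, scaffold_validation_split


@pytest.fixture(scope="module")
def toy_config():
    # sized to memorize the small noiseless study (see convergence test)
    return ModelConfig(n_tasks=6, hidden_width=64, message_passing_depth=2,
                       ffn_layers=2, ensemble_size=1, max_epochs=400,
                       patience=400, batch_size=20, lr_max=3e-3, lr_final=3e-4,
                       seed=5)


@pytest.fixture(scope="module")
def clean_matrix(clean_study):
    matrix, _ = ingest_measurements(clean_study.records, clean_study.registry)
    return matrix


@pytest.fixture(scope="module")
def trained_toy(clean_study, clean_matrix, toy_config):
    return model.train(clean_matrix, clean_study.molecules, toy_config)


class TestScaffoldSplit:
    def test_no_scaffold_crosses_sides(self, tiny_library):
        rng = np.random.default_rng(0)
        train, val = scaffold_validation_split(tiny_library, 0.2, rng)
        train_keys = {scaffold_key(tiny_library[i]) for i in train}
        val_keys = {scaffold_key(tiny_library[i]) for i in val}
        assert not train_keys & val_keys
        assert len(train) + len(val) == len(tiny_library)

    def test_validation_fraction_respected(self, small_study):
        rng = np.random.default_rng(1)
        train, val = scaffold_validation_split(small_study.molecules, 0.1, rng)
        assert len(val) >= 0.1 * len(small_study.molecules)
        assert len(val) <= 0.5 * len(small_study.molecules)


class TestTrain:
    def test_noiseless_training_drives_loss_down(self, trained_toy):
        epochs = trained_toy.audit["members"][0]["epochs"]
        assert epochs[-1]["train_loss"] < 0.01 * epochs[0]["train_loss"]

    def test_too_little_data_raises(self, clean_study, clean_matrix, toy_config):
        tiny = clean_matrix.subset(clean_matrix.compound_ids[:5])
        with pytest.raises(ValueError, match="too little data"):
            model.train(tiny, clean_study.molecules, toy_config)

    def test_task_count_mismatch(self, clean_study, clean_matrix, toy_config):
        import dataclasses
        bad = dataclasses.replace(toy_config, n_tasks=3)
        with pytest.raises(ValueError, match="tasks"):
            model.train(clean_matrix, clean_study.molecules, bad)

    def test_audit_records_split_sizes(self, trained_toy, clean_study):
        audit = trained_toy.audit
        assert audit["n_train"] + audit["n_validation"] == len(clean_study.molecules)


class TestMultiTaskAdvantage:
    def test_mt_not_worse_than_single_task_on_very_sparse_task(self):
        """With a near-empty task supported by correlated dense tasks, the
        multi-task model's MAE on that task does not exceed the single-task
        model's (within tolerance) — the rationale for joint training."""
        import dataclasses

        from tpd_qspr.assay_data import (LabelMatrix, ingest_measurements,
                                         temporal_split)
        from tpd_qspr.synthetic import (STANDARD_CUTOFF, GeneratorConfig,
                                        generate_study, standard_task_registry)

        registry = standard_task_registry()
        sparsity = {t.task_id: 0.9 for t in registry}
        sparsity["CYP3A4_kobs"] = 0.12
        cfg = GeneratorConfig(
            n_per_modality={"heterobifunctional": 240, "glue": 280, "other": 280},
            noise_sd=0.3, sparsity=sparsity, replicate_rate=0.1,
            qualifier_rate=0.05, seed=31)
        study = generate_study(cfg, registry)
        matrix, _ = ingest_measurements(study.records, registry)
        split, _ = temporal_split(study.molecules, STANDARD_CUTOFF)
        train_m = matrix.subset([c for c in split.train_ids if c in matrix.row_index()])
        test_m = matrix.subset([c for c in split.test_ids if c in matrix.row_index()])

        mc = ModelConfig(n_tasks=6, hidden_width=48, message_passing_depth=2,
                         ffn_layers=2, ensemble_size=1, max_epochs=30,
                         patience=30, seed=5)
        mt = model.train(train_m, study.molecules, mc)
        jt = train_m.task_ids.index("CYP3A4_kobs")
        st_matrix = LabelMatrix(compound_ids=list(train_m.compound_ids),
                                task_ids=["CYP3A4_kobs"],
                                values=train_m.values[:, [jt]],
                                mask=train_m.mask[:, [jt]])
        st = model.train(st_matrix, study.molecules,
                         dataclasses.replace(mc, n_tasks=1))

        by_id = {m.compound_id: m for m in study.molecules}
        test_mols = [by_id[c] for c in test_m.compound_ids]
        pm, ps = model.predict(mt, test_mols), model.predict(st, test_mols)
        j = test_m.task_ids.index("CYP3A4_kobs")
        mask = test_m.mask[:, j]
        y = test_m.values[mask, j]
        mt_mae = np.abs(y - pm.values[mask, pm.task_ids.index("CYP3A4_kobs")]).mean()
        st_mae = np.abs(y - ps.values[mask, 0]).mean()
        assert mt_mae <= st_mae + 0.05


class TestPredict:
    def test_single_member_table_equals_member_output(self, trained_toy, clean_study):
        preds = model.predict(trained_toy, clean_study.molecules[:10])
        assert preds.values.shape == (10, 6)
        assert np.all(preds.spread == 0.0)  # one member: no spread

    def test_duplicated_member_zero_spread(self, trained_toy, clean_study):
        twin = trained_toy.copy()
        twin.members = [twin.members[0], nn.clone_params(twin.members[0])]
        preds = model.predict(twin, clean_study.molecules[:5])
        assert np.allclose(preds.spread, 0.0)
        single = model.predict(trained_toy, clean_study.molecules[:5])
        np.testing.assert_allclose(preds.values, single.values, rtol=1e-6)

    def test_duplicated_molecule_duplicated_rows(self, trained_toy, clean_study):
        mols = [clean_study.molecules[0], clean_study.molecules[0]]
        preds = model.predict(trained_toy, mols)
        np.testing.assert_allclose(preds.values[0], preds.values[1])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, trained_toy, clean_study, tmp_path):
        path = tmp_path / "model.npz"
        model.save_checkpoint(trained_toy, path)
        loaded = model.load_checkpoint(path)
        assert loaded.task_ids == trained_toy.task_ids
        a = model.predict(trained_toy, clean_study.molecules[:8])
        b = model.predict(loaded, clean_study.molecules[:8])
        np.testing.assert_allclose(a.values, b.values)
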