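"""Structure standardization, descriptors, fingerprints, scaffolds, embedding."""

import numpy as np
import pytest
from rdkit import Chem

from tpd_qspr.chemistry import (EMPTY_SCAFFOLD, EmbeddingConfig, Ro5Rule,
                                StandardizationPolicy, StructureParseError,
                                compute_descriptors, embed_chemical_space,
                                maccs_fingerprint, scaffold_key,
                                standardize_structure, tanimoto_distance,
                                tanimoto_distance_matrix)


class TestStandardize:
    def test_kekulized_benzene_canonicalizes(self):
        # independent toolkit canonicalization oracle
        oracle = Chem.MolToSmiles(Chem.MolFromSmiles("C1=CC=CC=C1"))
        assert standardize_structure("C1=CC=CC=C1") == oracle == "c1ccccc1"

    def test_idempotent_on_generator_outputs(self, tiny_library):
        for mol in tiny_library:
            once = standardize_structure(mol.structure)
            assert standardize_structure(once) == once

    def test_salt_kept_unless_desalting(self):
        # frozen output of the default policy on a sodium acetate input
        assert standardize_structure("[Na+].CC(=O)[O-]") == "CC(=O)[O-].[Na+]"
        assert standardize_structure(
            "[Na+].CC(=O)[O-]", StandardizationPolicy(desalt=True)
        ) == "CC(=O)[O-]"

    @pytest.mark.parametrize("bad", ["", "   ", "not_a_smiles((", "C1CC"])
    def test_unparsable_input_raises_with_offender(self, bad):
        with pytest.raises(StructureParseError) as err:
            standardize_structure(bad)
        assert err.value.smiles == bad


class TestDescriptors:
    def test_ethanol(self):
        rec = compute_descriptors("CCO")
        assert (rec.hbd, rec.hba, rec.rotatable_bonds) == (1, 1, 0)
        assert rec.mw == pytest.approx(46.07, abs=0.01)

    def test_benzene_has_no_hbond_partners(self):
        rec = compute_descriptors("c1ccccc1")
        assert rec.hbd == 0 and rec.hba == 0

    def test_same_molecule_different_smiles_equal_records(self):
        assert compute_descriptors("C1=CC=CC=C1") == compute_descriptors("c1ccccc1")
        a, b = compute_descriptors("OCC"), compute_descriptors("CCO")
        assert (a.hba, a.hbd, a.rotatable_bonds, a.beyond_ro5) == \
               (b.hba, b.hbd, b.rotatable_bonds, b.beyond_ro5)
        for field in ("mw", "tpsa", "clogp"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-9)

    def test_heterobifunctionals_larger_than_glues(self, tiny_library):
        mw = {"heterobifunctional": [], "glue": []}
        for mol in tiny_library:
            if mol.modality in mw:
                mw[mol.modality].append(compute_descriptors(mol).mw)
        assert np.mean(mw["heterobifunctional"]) > np.mean(mw["glue"]) > 0
        # every generated heterobifunctional violates at least one Lipinski
        # bound (MW > 500), unlike essentially all glues
        strict = Ro5Rule(min_violations=1)
        het = [m for m in tiny_library if m.modality == "heterobifunctional"]
        glue = [m for m in tiny_library if m.modality == "glue"]
        assert all(compute_descriptors(m, strict).beyond_ro5 for m in het)
        het_frac = np.mean([compute_descriptors(m).beyond_ro5 for m in het])
        glue_frac = np.mean([compute_descriptors(m).beyond_ro5 for m in glue])
        assert het_frac > glue_frac

    def test_configurable_violation_count(self):
        # icosane: cLogP > 5 is the only Lipinski violation
        smi = "C" * 20
        assert not compute_descriptors(smi).beyond_ro5
        assert compute_descriptors(smi, Ro5Rule(min_violations=1)).beyond_ro5


class TestTanimoto:
    def _bits(self, on, n=166):
        v = np.zeros(n, dtype=bool)
        v[list(on)] = True
        return v

    def test_identical_distance_zero(self):
        fp = maccs_fingerprint("CCO")
        assert tanimoto_distance(fp, fp) == 0.0

    def test_disjoint_distance_one(self):
        assert tanimoto_distance(self._bits({0, 1}), self._bits({5, 6})) == 1.0

    def test_half_overlap(self):
        assert tanimoto_distance(self._bits({1, 2, 3}), self._bits({2, 3, 4})) == 0.5

    def test_all_zero_pair_defined_similar(self):
        assert tanimoto_distance(self._bits(set()), self._bits(set())) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto_distance(self._bits({1}, 166), self._bits({1}, 167))

    def test_symmetry_and_self_distance(self, tiny_library):
        fps = [maccs_fingerprint(m) for m in tiny_library[:10]]
        for a in fps:
            assert tanimoto_distance(a, a) == 0.0
        for a, b in zip(fps, fps[1:]):
            assert tanimoto_distance(a, b) == pytest.approx(tanimoto_distance(b, a))

    def test_matrix_matches_pairwise(self, tiny_library):
        fps = np.stack([maccs_fingerprint(m) for m in tiny_library[:8]])
        mat = tanimoto_distance_matrix(fps)
        for i in range(len(fps)):
            for j in range(len(fps)):
                assert mat[i, j] == pytest.approx(tanimoto_distance(fps[i], fps[j]))

    def test_maccs_length(self):
        assert maccs_fingerprint("CCO").shape == (166,)


class TestScaffold:
    def test_toluene_phenol_share_benzene_framework(self):
        assert scaffold_key("Cc1ccccc1") == scaffold_key("Oc1ccccc1")

    def test_acyclic_maps_to_empty_key(self):
        assert scaffold_key("CCCCCC") == EMPTY_SCAFFOLD

    def test_stable_under_atom_reordering(self):
        assert scaffold_key("c1ccccc1CCN") == scaffold_key("NCCc1ccccc1")


class TestEmbedding:
    def test_duplicates_identical_and_deterministic(self, tiny_library):
        fps = [maccs_fingerprint(m) for m in tiny_library[:12]]
        fps.append(fps[0].copy())  # exact duplicate
        cfg = EmbeddingConfig(n_neighbors=5)
        coords = embed_chemical_space(fps, cfg, seed=3)
        assert coords.shape == (13, 2)
        np.testing.assert_allclose(coords[-1], coords[0])
        again = embed_chemical_space(fps, cfg, seed=3)
        np.testing.assert_allclose(coords, again)

    def test_too_few_points(self):
        fps = [maccs_fingerprint("CCO")] * 5
        with pytest.raises(ValueError):
            embed_chemical_space(fps, seed=0)

    def test_modalities_separate_in_embedding(self, tiny_library):
        mols = [m for m in tiny_library if m.modality in ("heterobifunctional", "other")]
        fps = [maccs_fingerprint(m) for m in mols]
        coords = embed_chemical_space(fps, EmbeddingConfig(n_neighbors=8), seed=5)
        labels = np.array([m.modality == "heterobifunctional" for m in mols])
        a, b = coords[labels], coords[~labels]
        intra = np.mean([np.linalg.norm(x - y) for g in (a, b)
                         for x in g for y in g])
        inter = np.mean([np.linalg.norm(x - y) for x in a for y in b])
        assert inter > intra
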