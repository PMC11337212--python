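"""Unit tests for fingerprints, descriptor catalogue, physchem panel and
variance-threshold selection."""

import numpy as np
import pytest

from dilinet.featurization import (
    MACCS_BITS,
    MORGAN_BITS,
    PHYSCHEM15_NAMES,
    STRUCTURAL_BITS,
    ChemFeaturizer,
    FeatureBlock,
    apply_mask,
    descriptor_catalogue,
    fit_variance_mask,
    maccs_bits,
    morgan_bits,
    physchem15,
    structural_bits,
)


class TestFingerprints:
    def test_morgan_length_and_binary(self):
        v = morgan_bits("CCO")
        assert v.shape == (MORGAN_BITS,)
        assert set(np.unique(v)) <= {0, 1}

    def test_maccs_length(self):
        assert maccs_bits("CCO").shape == (MACCS_BITS,)

    def test_concatenated_width_2214(self):
        assert structural_bits("c1ccccc1").shape == (STRUCTURAL_BITS,)
        assert STRUCTURAL_BITS == 2214

    def test_determinism(self):
        assert np.array_equal(morgan_bits("CCO"), morgan_bits("CCO"))

    def test_methane_vs_decane_differ(self):
        # oracle: RDKit's own fingerprinter called independently
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        a = set(gen.GetFingerprint(Chem.MolFromSmiles("C")).GetOnBits())
        b = set(gen.GetFingerprint(Chem.MolFromSmiles("CCCCCCCCCC")).GetOnBits())
        assert a != b
        assert not np.array_equal(morgan_bits("C"), morgan_bits("CCCCCCCCCC"))

    def test_benzene_maccs_aromatic_key(self):
        # oracle: SMARTS match of the published key definition (key 162 =
        # aromatic)
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys

        smarts, _ = MACCSkeys.smartsPatts[162]
        assert Chem.MolFromSmiles("c1ccccc1").HasSubstructMatch(
            Chem.MolFromSmarts(smarts)
        )
        assert maccs_bits("c1ccccc1")[162 - 1] == 1


class TestPhyschem15:
    def test_count_is_15(self):
        assert physchem15("CCO").shape == (15,)
        assert len(PHYSCHEM15_NAMES) == 15

    def test_cyclohexane(self):
        v = dict(zip(PHYSCHEM15_NAMES, physchem15("C1CCCCC1")))
        assert v["rotatable_bonds"] == 0
        assert v["rings"] == 1
        assert v["aromatic_rings"] == 0
        assert v["heteroatoms"] == 0

    def test_benzene(self):
        v = dict(zip(PHYSCHEM15_NAMES, physchem15("c1ccccc1")))
        assert v["aromatic_rings"] == 1
        assert v["fraction_csp3"] == 0

    def test_ethanol_hand_counted(self):
        v = dict(zip(PHYSCHEM15_NAMES, physchem15("CCO")))
        assert v["hbond_donors"] == 1
        assert v["hbond_acceptors"] == 1
        assert v["heteroatoms"] == 1

    def test_naphthalene_assembled_rings(self):
        v = dict(zip(PHYSCHEM15_NAMES, physchem15("c1ccc2ccccc2c1")))
        assert v["rings"] == 2
        assert v["assembled_rings"] == 1  # fused system counts once

    def test_counts_nonnegative_integers(self):
        v = dict(zip(PHYSCHEM15_NAMES, physchem15("CC(=O)Nc1ccc(O)cc1")))
        for name in ("hbond_acceptors", "hbond_donors", "rotatable_bonds",
                     "rings", "aromatic_rings", "heteroatoms", "stereocenters",
                     "nhoh_count", "no_count"):
            assert v[name] >= 0 and v[name] == int(v[name])


class TestDescriptorCatalogue:
    def test_alkanes_all_finite(self):
        block = descriptor_catalogue(["C", "CC", "CCC", "CCCC"])
        block.validate_finite()
        assert block.n_features > 100

    def test_ethanol_mw(self):
        # oracle: atomic-mass summation 2*12.011 + 6*1.008 + 15.999
        block = descriptor_catalogue(["CCO"])
        mw = block.matrix[0, block.feature_names.index("MolWt")]
        assert mw == pytest.approx(2 * 12.011 + 6 * 1.008 + 15.999, abs=0.01)

    def test_nan_column_dropped_for_all(self):
        block = descriptor_catalogue(["CCO", "CCN"])
        m = block.matrix.copy()
        m[0, 3] = np.nan
        poisoned = FeatureBlock("descriptors", m, list(block.feature_names))
        refit = fit_variance_mask  # not used; drop happens in catalogue fit
        keep = np.all(np.isfinite(poisoned.matrix), axis=0)
        assert not keep[3]  # the column would be dropped for every compound


class TestVarianceMask:
    def test_constant_column_dropped(self):
        block = FeatureBlock("morgan", np.ones((10, 3)), ["morgan_0", "morgan_1", "morgan_2"])
        mask = fit_variance_mask(block, 0.01)
        assert not mask.any()

    def test_binary_ten_percent_boundary(self):
        # var = p(1-p) = 0.09: dropped at 0.10, kept at 0.05
        col = np.zeros((10, 1))
        col[0, 0] = 1
        block = FeatureBlock("morgan", col, ["morgan_0"])
        assert not fit_variance_mask(block, 0.10)[0]
        assert fit_variance_mask(block, 0.05)[0]

    def test_variance_equal_threshold_dropped(self):
        # var of [0,1] is exactly 0.25 in binary floating point
        block = FeatureBlock("morgan", np.array([[0.0], [1.0]]), ["morgan_0"])
        assert not fit_variance_mask(block, 0.25)[0]  # strictly greater

    def test_population_variance_used(self):
        col = np.array([[0.0], [1.0]])
        block = FeatureBlock("morgan", col, ["morgan_0"])
        # population var = 0.25 (sample var would be 0.5)
        assert not fit_variance_mask(block, 0.25)[0]
        assert fit_variance_mask(block, 0.24)[0]

    def test_physchem_never_masked(self):
        block = FeatureBlock("physchem15", np.ones((5, 15)), list(PHYSCHEM15_NAMES))
        assert fit_variance_mask(block).all()

    def test_empty_reference_errors(self):
        block = FeatureBlock("morgan", np.zeros((0, 2)), ["morgan_0", "morgan_1"])
        with pytest.raises(ValueError):
            fit_variance_mask(block, 0.05)

    def test_refit_order_invariant(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(50, 20)).astype(float)
        names = [f"morgan_{i}" for i in range(20)]
        a = fit_variance_mask(FeatureBlock("morgan", m, names), 0.1)
        perm = rng.permutation(50)
        b = fit_variance_mask(FeatureBlock("morgan", m[perm], names), 0.1)
        assert np.array_equal(a, b)


class TestApplyMask:
    def test_all_true_identity(self):
        block = FeatureBlock("morgan", np.eye(3), [f"morgan_{i}" for i in range(3)])
        out = apply_mask(block, np.ones(3, dtype=bool))
        assert np.array_equal(out.matrix, block.matrix)

    def test_masked_twice_same_selection(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, (20, 10)).astype(float)
        names = [f"morgan_{i}" for i in range(10)]
        block = FeatureBlock("morgan", m, names)
        mask = fit_variance_mask(block, 0.1)
        once = apply_mask(block, mask)
        again = apply_mask(block, mask)
        assert once.feature_names == again.feature_names

    def test_name_mismatch_errors(self):
        ref = FeatureBlock("maccs", np.ones((5, 2)), ["maccs_1", "maccs_2"])
        fit_variance_mask(ref, 0.0)
        other = FeatureBlock("morgan", np.ones((5, 2)), ["morgan_0", "morgan_1"])
        with pytest.raises(ValueError):
            apply_mask(other, ref)

    def test_length_mismatch_errors(self):
        block = FeatureBlock("morgan", np.ones((5, 3)), [f"morgan_{i}" for i in range(3)])
        with pytest.raises(ValueError):
            apply_mask(block, np.ones(2, dtype=bool))


class TestChemFeaturizer:
    def test_structural_width_identity(self, pipeline):
        fz = pipeline["featurizer"]
        kept_morgan = int(fz.morgan_ref.selection_mask.sum())
        kept_maccs = int(fz.maccs_ref.selection_mask.sum())
        block = fz.structural(pipeline["panel"].gold.compounds[:5])
        assert block.n_features == kept_morgan + kept_maccs == fz.n_structural

    def test_descriptor_block_finite(self, pipeline):
        fz = pipeline["featurizer"]
        block = fz.descriptors(pipeline["panel"].gold.compounds[:5])
        assert np.all(np.isfinite(block.matrix))

    def test_descriptor_width_includes_physchem(self, pipeline):
        fz = pipeline["featurizer"]
        assert fz.n_descriptor_features == int(fz.descriptor_mask.sum()) + 15
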