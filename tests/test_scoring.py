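"""Ligand efficiency, fingerprints, and the random-forest target scorer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polygen.corpus import generate_fixture_corpus
from polygen.scoring import (ActivityRecord, LigandEfficiencyScorer,
                             efficiency_to_pic50, featurize,
                             generate_synthetic_activity, informative_bits,
                             ligand_efficiency, read_activity_csv,
                             train_scorer, write_activity_csv)


class TestLigandEfficiency:
    @pytest.mark.parametrize("affinity, n, expected", [
        (1e-6, 14, 0.6),
        (1.0, 7, 0.0),
        (1e-9, 14, 0.9),
    ])
    def test_formula(self, affinity, n, expected):
        assert ligand_efficiency(affinity, n) == pytest.approx(expected)

    @pytest.mark.parametrize("affinity, n", [(0.0, 5), (-1e-6, 5), (1e-6, 0)])
    def test_invalid_inputs(self, affinity, n):
        with pytest.raises(ValueError):
            ligand_efficiency(affinity, n)

    def test_inverse_worked_example(self):
        assert efficiency_to_pic50(0.6, 14) == pytest.approx(6.0)
        assert efficiency_to_pic50(0.0, 30) == 0.0

    @given(st.floats(-12, -1), st.integers(1, 60))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, log_affinity, n):
        affinity = 10.0**log_affinity
        y = ligand_efficiency(affinity, n)
        assert efficiency_to_pic50(y, n) == pytest.approx(-log_affinity,
                                                          abs=1e-12)


class TestFeaturize:
    def test_shape_and_determinism(self):
        fp1, fp2 = featurize("CCO"), featurize("CCO")
        assert fp1.shape == (2048,)
        assert set(np.unique(fp1)) <= {0, 1}
        assert np.array_equal(fp1, fp2)

    def test_methane_single_environment(self):
        assert featurize("C").sum() <= 1

    def test_spelling_invariance(self):
        from rdkit import Chem
        assert np.array_equal(featurize(Chem.CanonSmiles("OCC")),
                              featurize(Chem.CanonSmiles("CCO")))

    def test_family_members_share_more_bits(self, two_family_corpus):
        fps = np.stack([featurize(m) for m in two_family_corpus])
        fam = np.array([0] * 25 + [1] * 25)
        intra, inter = [], []
        for i in range(50):
            for j in range(i + 1, 50):
                overlap = int((fps[i] & fps[j]).sum())
                (intra if fam[i] == fam[j] else inter).append(overlap)
        assert np.mean(intra) > np.mean(inter)

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError):
            featurize("C(")


class TestActivityRecord:
    def test_build_populates_le_identity(self):
        rec = ActivityRecord.build("CCO", "T", 1e-6)
        assert rec.ligand_efficiency == pytest.approx(
            ligand_efficiency(1e-6, rec.heavy_atom_count))

    @pytest.mark.parametrize("kwargs", [
        {"affinity_value": 0.0}, {"affinity_kind": "EC50"},
    ])
    def test_invalid_records(self, kwargs):
        base = dict(smiles="CCO", target_id="T", affinity_value=1e-6,
                    affinity_kind="IC50")
        with pytest.raises(ValueError):
            ActivityRecord(**{**base, **kwargs})


@pytest.fixture(scope="module")
def sar_setup():
    mols = generate_fixture_corpus(4, 30, seed=3)
    bits = informative_bits(mols, 8, seed=3)
    return mols, bits


class TestSyntheticActivity:
    def test_deterministic(self, sar_setup):
        mols, bits = sar_setup
        a = generate_synthetic_activity(50, "T", bits, seed=3, molecules=mols)
        b = generate_synthetic_activity(50, "T", bits, seed=3, molecules=mols)
        assert a == b

    def test_internal_le_consistency(self, sar_setup):
        mols, bits = sar_setup
        for r in generate_synthetic_activity(50, "T", bits, seed=1,
                                             molecules=mols):
            assert r.ligand_efficiency == pytest.approx(
                ligand_efficiency(r.affinity_value, r.heavy_atom_count),
                rel=1e-9)

    def test_zero_coefficients_constant_up_to_noise(self, sar_setup):
        mols, bits = sar_setup
        recs = generate_synthetic_activity(
            100, "T", bits, seed=2, molecules=mols,
            coefficients=np.zeros(len(bits)), noise_sigma=0.01)
        y = np.array([r.ligand_efficiency for r in recs])
        assert y.std() < 0.05

    def test_bit_bounds_checked(self):
        with pytest.raises(ValueError):
            generate_synthetic_activity(10, "T", [4096], seed=0)


class TestScorer:
    def test_validation_errors(self, sar_setup):
        mols, bits = sar_setup
        recs = generate_synthetic_activity(30, "T1", bits, seed=1,
                                           molecules=mols)
        other = generate_synthetic_activity(30, "T2", bits, seed=1,
                                            molecules=mols)
        with pytest.raises(ValueError, match="mixed"):
            train_scorer(recs + other, n_trees=10)
        with pytest.raises(ValueError, match="20"):
            train_scorer(recs[:5], n_trees=10)
        with pytest.raises(RuntimeError):
            LigandEfficiencyScorer().predict_efficiency("CCO")

    def test_seeded_determinism_and_kd_variant(self, sar_setup):
        mols, bits = sar_setup
        recs = generate_synthetic_activity(60, "T", bits, seed=5,
                                           molecules=mols)
        s1 = train_scorer(recs, n_trees=50, seed=9)
        s2 = train_scorer(list(recs), n_trees=50, seed=9)
        probe = mols[:10]
        assert [s1.predict_efficiency(m) for m in probe] == \
               [s2.predict_efficiency(m) for m in probe]
        # Kd records train through the identical path
        kd = [ActivityRecord(r.smiles, r.target_id, r.affinity_value, "Kd",
                             r.heavy_atom_count, r.ligand_efficiency)
              for r in recs]
        sk = train_scorer(kd, n_trees=50, seed=9)
        assert sk.affinity_kind_ == "Kd"
        assert [sk.predict_efficiency(m) for m in probe] == \
               [s1.predict_efficiency(m) for m in probe]

    def test_noise_free_training_fit_and_pic50_identity(self, sar_setup):
        mols, bits = sar_setup
        recs = generate_synthetic_activity(100, "T", bits, seed=4,
                                           noise_sigma=0.0, molecules=mols)
        scorer = train_scorer(recs, n_trees=100, seed=1)
        for r in recs[:20]:
            pred = scorer.predict_efficiency(r.smiles)
            assert pred == pytest.approx(r.ligand_efficiency, abs=0.05)
            assert scorer.predict_pic50(r.smiles) == pytest.approx(
                efficiency_to_pic50(pred, r.heavy_atom_count))

    def test_feature_length_enforced(self, sar_setup):
        mols, bits = sar_setup
        recs = generate_synthetic_activity(30, "T", bits, seed=1,
                                           molecules=mols)
        scorer = train_scorer(recs, n_trees=10, seed=0)
        with pytest.raises(ValueError):
            scorer.predict(np.zeros((1, 100)))

    def test_cv_metrics_populated(self, sar_setup):
        mols, bits = sar_setup
        recs = generate_synthetic_activity(60, "T", bits, seed=6,
                                           molecules=mols)
        scorer = train_scorer(recs, n_trees=20, seed=0)
        assert len(scorer.cv_metrics_) == 5
        assert all({"fold", "r2", "rmse"} <= set(m) for m in scorer.cv_metrics_)


def test_activity_csv_round_trip_and_units(tmp_path, sar_setup):
    mols, bits = sar_setup
    recs = generate_synthetic_activity(20, "T", bits, seed=8, molecules=mols)
    path = tmp_path / "activity.csv"
    write_activity_csv(recs, path)
    loaded = read_activity_csv(path)
    assert [r.smiles for r in loaded] == [r.smiles for r in recs]
    np.testing.assert_allclose([r.affinity_value for r in loaded],
                               [r.affinity_value for r in recs])
    # unit conversion: 1000 nM == 1 uM == 1e-6 M
    df = pd.DataFrame([{"smiles": "CCO", "target_id": "T",
                        "affinity_value": 1000.0, "affinity_kind": "IC50",
                        "units": "nM"}])
    df.to_csv(tmp_path / "nm.csv", index=False)
    rec = read_activity_csv(tmp_path / "nm.csv")[0]
    assert rec.affinity_value == pytest.approx(1e-6)
    # missing units column assumes molar and warns
    df.drop(columns="units").to_csv(tmp_path / "nounits.csv", index=False)
    with pytest.warns(UserWarning):
        rec = read_activity_csv(tmp_path / "nounits.csv")[0]
    assert rec.affinity_value == pytest.approx(1000.0)
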