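import numpy as np
import pytest

from qsprkit import PipelineConfig, ValidationError
from qsprkit.errors import ContractError
from qsprkit.featurize import (
    FeatureBlocks,
    FeatureSpec,
    assemble,
    build_blocks,
    compute_descriptors,
    compute_druglike_flags,
    compute_fingerprint,
    fit_transform,
    subset_blocks,
)

REF = ("SLogP", "SMR", "naRing", "nHBAcc", "nHBDon", "nRot", "MW", "TopoPSA")


class TestDescriptors:
    def test_benzene_hand_counts(self):
        v = dict(zip(REF, compute_descriptors("c1ccccc1", REF)))
        assert v["naRing"] == 1 and v["nRot"] == 0
        assert v["nHBDon"] == 0 and v["nHBAcc"] == 0

    def test_ethanol_hand_counts(self):
        v = dict(zip(REF, compute_descriptors("CCO", REF)))
        assert v["nHBDon"] == 1 and v["nHBAcc"] == 1 and v["naRing"] == 0

    def test_aspirin_molecular_weight(self):
        # sum of standard atomic weights for C9H8O4
        (mw,) = compute_descriptors("CC(=O)Oc1ccccc1C(=O)O", ["MW"])
        assert mw == pytest.approx(180.16, abs=0.01)

    def test_counts_are_nonnegative_integers(self):
        for smi in ("CCO", "c1ccncc1", "CC(=O)Oc1ccccc1C(=O)O"):
            vec = compute_descriptors(smi, ["naRing", "nHBAcc", "nHBDon", "nRot"])
            assert np.all(vec >= 0) and np.all(vec == np.round(vec))

    def test_unknown_descriptor_and_bad_smiles(self):
        with pytest.raises(ValidationError):
            compute_descriptors("CCO", ["nBogus"])
        with pytest.raises(ValidationError):
            compute_descriptors("xxx", ["MW"])


class TestDruglikeFlags:
    def test_benzene_fails_ghose(self):
        # MW 78 < 160 and 12 atoms (H included) < 20
        flags = compute_druglike_flags("c1ccccc1", ["ghose"])
        assert flags.tolist() == [0.0]

    def test_ethanol_passes_lipinski(self):
        flags = compute_druglike_flags("CCO", ["lipinski"])
        assert flags.tolist() == [1.0]

    def test_c40_alkane_fails_lipinski(self):
        # 40 x 12.011 + 82 x 1.008 = 563 > 500
        smi = "C" * 40
        flags = compute_druglike_flags(smi, ["lipinski"])
        assert flags.tolist() == [0.0]

    def test_flags_binary_over_library_sample(self):
        from qsprkit.fixtures import load_library

        for smi in load_library()["smiles"].head(30):
            flags = compute_druglike_flags(smi, ["lipinski", "ghose"])
            assert set(flags.tolist()) <= {0.0, 1.0}


class TestFingerprints:
    def test_morgan_reference_length(self):
        assert compute_fingerprint("CCO", "morgan", 1024, 2).shape == (1024,)

    @pytest.mark.parametrize(
        "family,bits,expected",
        [
            ("morgan", 512, 512),
            ("maccs", 1024, 167),  # fixed key-set length, bits ignored
            ("atom_pair", 256, 256),
            ("topological_torsion", 256, 256),
            ("path_based", 256, 256),
        ],
    )
    def test_family_lengths(self, family, bits, expected):
        fp = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O", family, bits, 2)
        assert fp.shape == (expected,)
        assert set(np.unique(fp)) <= {0.0, 1.0}

    @pytest.mark.parametrize("family", ["morgan", "maccs", "atom_pair",
                                        "topological_torsion", "path_based"])
    def test_invariant_to_smiles_spelling(self, family):
        a = compute_fingerprint("OCC", family, 512, 2)
        b = compute_fingerprint("CCO", family, 512, 2)
        assert np.array_equal(a, b)

    def test_methane_sets_at_least_one_bit(self):
        assert compute_fingerprint("C", "morgan", 1024, 2).sum() >= 1


def toy_blocks(X):
    n = X.shape[0]
    return FeatureBlocks(
        smiles=[f"m{i}" for i in range(n)],
        descriptors=np.zeros((n, 0)),
        flags=np.zeros((n, 0)),
        fingerprint=np.asarray(X, dtype=float),
    )


def pca_oracle(X, k):
    """Dense eigendecomposition of the sample covariance matrix."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return vals[order], vecs[:, order], Xc @ vecs[:, order]


class TestTransform:
    def test_projection_matches_eigen_oracle_up_to_sign(self):
        rng = np.random.default_rng(0)
        for n, p, k in [(5, 4, 2), (10, 10, 5), (8, 6, 6)]:
            X = rng.normal(size=(n, p))
            cfg = PipelineConfig(descriptors=(), druglike_filters=(),
                                 fingerprint_bits=p, pca_components=k,
                                 scale=False)
            blocks = toy_blocks(X)
            t = fit_transform(blocks, cfg)
            proj = t.transform(blocks)
            vals, _, proj_oracle = pca_oracle(X, k)
            assert np.allclose(np.abs(proj), np.abs(proj_oracle), atol=1e-8)
            assert np.allclose(t.pca_explained_variance, vals, atol=1e-8)

    def test_explained_variance_nonincreasing_and_total_preserved(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 7))
        cfg = PipelineConfig(descriptors=(), druglike_filters=(),
                             fingerprint_bits=7, pca_components=7, scale=False)
        t = fit_transform(toy_blocks(X), cfg)
        ev = t.pca_explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        total_var = np.var(X, axis=0, ddof=1).sum()
        assert ev.sum() == pytest.approx(total_var)

    def test_loadings_column_orthonormal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 10))
        cfg = PipelineConfig(descriptors=(), druglike_filters=(),
                             fingerprint_bits=10, pca_components=4, scale=False)
        t = fit_transform(toy_blocks(X), cfg)
        gram = t.pca_components.T @ t.pca_components
        assert np.allclose(gram, np.eye(4), atol=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 6))
        cfg = PipelineConfig(descriptors=(), druglike_filters=(),
                             fingerprint_bits=6, pca_components=3, scale=False)
        t = fit_transform(toy_blocks(X), cfg)
        for j in range(3):
            col = t.pca_components[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_scaling_gives_zero_mean_unit_variance(self):
        cfg = PipelineConfig(descriptors=REF, druglike_filters=("lipinski",),
                             fingerprint_bits=64, pca_components=0)
        smiles = ["CCO", "CCN", "c1ccccc1", "CC(C)O", "CCCl", "c1ccncc1"]
        blocks = build_blocks(smiles, cfg)
        t = fit_transform(blocks, cfg)
        X = t.transform(blocks)
        desc = X[:, : len(REF)]
        assert np.allclose(desc.mean(axis=0), 0, atol=1e-12)
        stds = desc.std(axis=0)
        # constant columns map to zero, others to unit variance
        assert np.all((np.abs(stds - 1) < 1e-9) | (stds < 1e-12))

    def test_too_many_components_rejected(self):
        cfg = PipelineConfig(descriptors=(), druglike_filters=(),
                             fingerprint_bits=4, pca_components=4, scale=False)
        with pytest.raises(ValidationError):
            fit_transform(toy_blocks(np.eye(4)), cfg)  # n-1 = 3 < 4


@pytest.fixture(scope="module")
def fitted_reference():
    from qsprkit.fixtures import load_library

    cfg = PipelineConfig()  # reference recipe
    smiles = load_library()["smiles"].head(60).tolist()
    blocks = build_blocks(smiles, cfg)
    return cfg, fit_transform(blocks, cfg)


class TestAssemble:
    def test_reference_recipe_yields_60_features(self, fitted_reference):
        cfg, fitted = fitted_reference
        spec = FeatureSpec.from_config(cfg)
        assert spec.n_features == 60
        X, kept, failed = assemble(["CC(=O)Oc1ccccc1C(=O)O"], spec, fitted)
        assert X.shape == (1, 60) and failed == []

    def test_feature_order_contract(self, fitted_reference):
        cfg, _ = fitted_reference
        spec = FeatureSpec.from_config(cfg)
        assert spec.feature_names[:8] == cfg.descriptors
        assert spec.feature_names[8:10] == ("lipinski_flag", "ghose_flag")
        assert spec.feature_names[10] == "pc1" and spec.feature_names[-1] == "pc50"

    def test_no_pca_maccs_width(self):
        cfg = PipelineConfig(fingerprint_family="maccs", pca_components=0)
        spec = FeatureSpec.from_config(cfg)
        assert spec.n_features == 8 + 2 + 167

    def test_featurization_is_deterministic(self, fitted_reference):
        cfg, fitted = fitted_reference
        spec = FeatureSpec.from_config(cfg)
        X1, _, _ = assemble(["c1ccncc1O"], spec, fitted)
        X2, _, _ = assemble(["c1ccncc1O"], spec, fitted)
        assert np.array_equal(X1, X2)

    def test_unfitted_transform_is_contract_error(self):
        from qsprkit.featurize import FittedTransform

        cfg = PipelineConfig()
        with pytest.raises(ContractError):
            assemble(["CCO"], FeatureSpec.from_config(cfg), FittedTransform(config=cfg))

    def test_subset_blocks_slices_rows(self):
        X = np.arange(12.0).reshape(4, 3)
        sub = subset_blocks(toy_blocks(X), [1, 3])
        assert np.array_equal(sub.fingerprint, X[[1, 3]])
        assert sub.smiles == ["m1", "m3"]
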