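"""Molecular featurization: descriptors, drug-likeness flags, fingerprints,
and the fitted scaling + PCA transform.

The feature vector of a molecule is assembled in a fixed order:

    descriptors (as configured) ++ drug-likeness flags ++
    fingerprint principal components (pc1..pck) or raw bits

Under the reference recipe — 8 descriptors, the Lipinski and Ghose flags,
and the 50 leading principal components of a 1024-bit Morgan fingerprint —
every molecule maps to a vector of 60 numbers.

Scaling standardizes each column to zero mean / unit variance on the
training rows (constant columns keep scale 1). PCA is fitted on the
(scaled) fingerprint block only; descriptors and flags pass through scaled
but unprojected. The sign of each principal component is fixed by making
its largest-magnitude loading positive, so fitted transforms are
reproducible across runs and platforms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdFingerprintGenerator
from sklearn.decomposition import PCA

from ._log import log_counts, stage_logger
from .config import PipelineConfig
from .errors import ContractError, ValidationError

RDLogger.DisableLog("rdApp.*")

logger = stage_logger("featurize")

# ---------------------------------------------------------------------------
# Descriptor registry — extensible via register_descriptor().

DESCRIPTOR_REGISTRY: Dict[str, callable] = {
    "SLogP": Crippen.MolLogP,             # computed octanol-water logP
    "SMR": Crippen.MolMR,                 # molar refractivity
    "naRing": lambda m: float(Chem.rdMolDescriptors.CalcNumAromaticRings(m)),
    "nHBAcc": lambda m: float(Lipinski.NumHAcceptors(m)),
    "nHBDon": lambda m: float(Lipinski.NumHDonors(m)),
    "nRot": lambda m: float(Lipinski.NumRotatableBonds(m)),
    "MW": Descriptors.MolWt,
    "TopoPSA": Descriptors.TPSA,
    # A few extra common descriptors beyond the reference panel.
    "nRing": lambda m: float(Chem.rdMolDescriptors.CalcNumRings(m)),
    "nHeavyAtom": lambda m: float(m.GetNumHeavyAtoms()),
    "FractionCSP3": Chem.rdMolDescriptors.CalcFractionCSP3,
}

FILTER_NAMES = ("lipinski", "ghose")

MACCS_BITS = 167  # fixed by the MACCS key dictionary (bit 0 unused)


def register_descriptor(name: str, fn) -> None:
    """Add a descriptor (``mol -> float``) to the registry."""
    DESCRIPTOR_REGISTRY[name] = fn


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"invalid SMILES {smiles!r}")
    return mol


def compute_descriptors(smiles: str, descriptor_names: Sequence[str]) -> np.ndarray:
    """Descriptor vector aligned with ``descriptor_names``."""
    mol = _mol(smiles)
    unknown = [n for n in descriptor_names if n not in DESCRIPTOR_REGISTRY]
    if unknown:
        raise ValidationError(f"unknown descriptors {unknown}")
    return np.array([float(DESCRIPTOR_REGISTRY[n](mol)) for n in descriptor_names])


def lipinski_pass(mol: Chem.Mol) -> int:
    """1 iff zero rule-of-five violations (MW<=500, logP<=5, HBD<=5, HBA<=10)."""
    ok = (
        Descriptors.MolWt(mol) <= 500.0
        and Crippen.MolLogP(mol) <= 5.0
        and Lipinski.NumHDonors(mol) <= 5
        and Lipinski.NumHAcceptors(mol) <= 10
    )
    return int(ok)


def ghose_pass(mol: Chem.Mol) -> int:
    """1 iff inside the Ghose bounds: 160<=MW<=480, -0.4<=logP<=5.6,
    40<=MR<=130 and 20<=total atom count (hydrogens included)<=70."""
    molh = Chem.AddHs(mol)
    ok = (
        160.0 <= Descriptors.MolWt(mol) <= 480.0
        and -0.4 <= Crippen.MolLogP(mol) <= 5.6
        and 40.0 <= Crippen.MolMR(mol) <= 130.0
        and 20 <= molh.GetNumAtoms() <= 70
    )
    return int(ok)


_FILTERS = {"lipinski": lipinski_pass, "ghose": ghose_pass}


def compute_druglike_flags(smiles: str, filters: Sequence[str]) -> np.ndarray:
    """Binary drug-likeness flags, one per configured filter."""
    mol = _mol(smiles)
    unknown = [f for f in filters if f not in _FILTERS]
    if unknown:
        raise ValidationError(f"unknown drug-like filters {unknown}")
    return np.array([float(_FILTERS[f](mol)) for f in filters])


def fingerprint_length(family: str, bits: int) -> int:
    return MACCS_BITS if family == "maccs" else bits


def compute_fingerprint(smiles: str, family: str, bits: int = 1024,
                        radius: int = 2) -> np.ndarray:
    """Binary fingerprint of the configured family and length.

    Hashed families (morgan, atom_pair, topological_torsion, path_based)
    honor ``bits``; MACCS keys have a fixed length. Identical for any two
    SMILES spellings of one structure.
    """
    mol = _mol(smiles)
    if family == "maccs":
        fp = MACCSkeys.GenMACCSKeys(mol)
    elif family == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=bits)
        fp = gen.GetFingerprint(mol)
    elif family == "atom_pair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=bits)
        fp = gen.GetFingerprint(mol)
    elif family == "topological_torsion":
        gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=bits)
        fp = gen.GetFingerprint(mol)
    elif family == "path_based":
        # Hashed path enumeration (Daylight-style), paths of 1-7 bonds.
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(minPath=1, maxPath=7, fpSize=bits)
        fp = gen.GetFingerprint(mol)
    else:
        raise ValidationError(f"unknown fingerprint family {family!r}")
    arr = np.zeros(fp.GetNumBits(), dtype=np.float64)
    for b in fp.GetOnBits():
        arr[b] = 1.0
    return arr


# ---------------------------------------------------------------------------
# Feature blocks, spec and fitted transform.


@dataclass
class FeatureBlocks:
    """Raw per-molecule feature blocks prior to scaling/PCA."""

    smiles: List[str]
    descriptors: np.ndarray  # n x d
    flags: np.ndarray        # n x f
    fingerprint: np.ndarray  # n x bits
    failed: List[str] = field(default_factory=list)


def build_blocks(smiles_list: Sequence[str], config: PipelineConfig) -> FeatureBlocks:
    """Compute all raw blocks; molecules failing any computation are
    excluded from the blocks and listed in ``failed``."""
    ok, desc_rows, flag_rows, fp_rows, failed = [], [], [], [], []
    for smi in smiles_list:
        try:
            d = compute_descriptors(smi, config.descriptors)
            f = compute_druglike_flags(smi, config.druglike_filters)
            fp = compute_fingerprint(
                smi, config.fingerprint_family, config.fingerprint_bits,
                config.morgan_radius,
            )
        except ValidationError:
            failed.append(smi)
            continue
        ok.append(smi)
        desc_rows.append(d)
        flag_rows.append(f)
        fp_rows.append(fp)
    if failed:
        log_counts(logger, "featurization failures", failed=len(failed))
    n_d, n_f = len(config.descriptors), len(config.druglike_filters)
    n_b = fingerprint_length(config.fingerprint_family, config.fingerprint_bits)
    return FeatureBlocks(
        smiles=ok,
        descriptors=np.array(desc_rows).reshape(len(ok), n_d),
        flags=np.array(flag_rows).reshape(len(ok), n_f),
        fingerprint=np.array(fp_rows).reshape(len(ok), n_b),
        failed=failed,
    )


def subset_blocks(blocks: FeatureBlocks, idx) -> FeatureBlocks:
    """Row-subset of the blocks (failed list is not carried over)."""
    idx = np.asarray(idx)
    return FeatureBlocks(
        smiles=[blocks.smiles[i] for i in idx],
        descriptors=blocks.descriptors[idx],
        flags=blocks.flags[idx],
        fingerprint=blocks.fingerprint[idx],
    )


@dataclass
class FeatureSpec:
    """Resolved, ordered output-feature names for a pipeline configuration."""

    config: PipelineConfig
    feature_names: Tuple[str, ...]

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "FeatureSpec":
        config.validate()
        names = list(config.descriptors) + [f"{f}_flag" for f in config.druglike_filters]
        n_bits = fingerprint_length(config.fingerprint_family, config.fingerprint_bits)
        if config.pca_components > 0:
            names += [f"pc{i + 1}" for i in range(config.pca_components)]
        else:
            names += [f"fp{i}" for i in range(n_bits)]
        return cls(config=config, feature_names=tuple(names))

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _fit_scaler(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column center/scale for standardization; constant columns get
    scale 1 so they map to exactly zero."""
    center = X.mean(axis=0) if X.shape[0] else np.zeros(X.shape[1])
    scale = X.std(axis=0) if X.shape[0] else np.ones(X.shape[1])
    scale = np.where(scale == 0.0, 1.0, scale)
    return center, scale


@dataclass
class FittedTransform:
    """Fitted scaling + PCA state for one pipeline configuration."""

    config: PipelineConfig
    desc_center: np.ndarray = None
    desc_scale: np.ndarray = None
    flag_center: np.ndarray = None
    flag_scale: np.ndarray = None
    fp_center: np.ndarray = None
    fp_scale: np.ndarray = None
    pca_mean: Optional[np.ndarray] = None
    pca_components: Optional[np.ndarray] = None  # n_bits x k loading matrix
    pca_explained_variance: Optional[np.ndarray] = None
    fitted: bool = False

    def transform(self, blocks: FeatureBlocks) -> np.ndarray:
        """Apply the fitted state; returns the assembled n x p matrix."""
        if not self.fitted:
            raise ContractError("transform has not been fitted")
        cfg = self.config
        if cfg.scale:
            desc = (blocks.descriptors - self.desc_center) / self.desc_scale
            flags = (blocks.flags - self.flag_center) / self.flag_scale
        else:
            desc, flags = blocks.descriptors, blocks.flags
        fp = blocks.fingerprint
        if cfg.pca_components > 0:
            if cfg.scale and cfg.scale_fingerprint_before_pca:
                fp = (fp - self.fp_center) / self.fp_scale
            fp = (fp - self.pca_mean) @ self.pca_components
        elif cfg.scale:
            fp = (fp - self.fp_center) / self.fp_scale
        return np.hstack([desc, flags, fp])


def fit_transform(blocks: FeatureBlocks, config: PipelineConfig) -> FittedTransform:
    """Fit scaling on every block and PCA on the (scaled) fingerprint block.

    Requires at least ``pca_components + 1`` training rows; each principal
    component's sign is fixed via its largest-magnitude loading.
    """
    config.validate()
    n = blocks.fingerprint.shape[0]
    k = config.pca_components
    if k > 0 and k > min(n - 1, blocks.fingerprint.shape[1]):
        raise ValidationError(
            f"pca_components={k} exceeds min(n_rows-1={n - 1}, "
            f"n_bits={blocks.fingerprint.shape[1]})"
        )
    t = FittedTransform(config=config)
    t.desc_center, t.desc_scale = _fit_scaler(blocks.descriptors)
    t.flag_center, t.flag_scale = _fit_scaler(blocks.flags)
    t.fp_center, t.fp_scale = _fit_scaler(blocks.fingerprint)
    if not config.scale:
        t.desc_center = np.zeros_like(t.desc_center)
        t.desc_scale = np.ones_like(t.desc_scale)
        t.flag_center = np.zeros_like(t.flag_center)
        t.flag_scale = np.ones_like(t.flag_scale)
    if k > 0:
        fp = blocks.fingerprint
        if config.scale and config.scale_fingerprint_before_pca:
            fp = (fp - t.fp_center) / t.fp_scale
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(fp)
        components = pca.components_.T.copy()  # n_bits x k
        # Deterministic sign: largest-|loading| entry of each component > 0.
        for j in range(components.shape[1]):
            i = np.argmax(np.abs(components[:, j]))
            if components[i, j] < 0:
                components[:, j] *= -1.0
        t.pca_mean = pca.mean_.copy()
        t.pca_components = components
        t.pca_explained_variance = pca.explained_variance_.copy()
    t.fitted = True
    return t


def assemble(smiles_list: Sequence[str], spec: FeatureSpec,
             fitted: FittedTransform) -> Tuple[np.ndarray, List[str], List[str]]:
    """Featurize molecules into the spec's fixed column order.

    Returns ``(matrix, row_smiles, failed_smiles)``; the matrix has one row
    per successfully featurized molecule and ``spec.n_features`` columns.
    """
    if not fitted.fitted:
        raise ContractError("transform has not been fitted")
    blocks = build_blocks(smiles_list, spec.config)
    X = fitted.transform(blocks)
    if X.shape[1] != spec.n_features:
        raise ContractError(
            f"assembled width {X.shape[1]} != spec width {spec.n_features}"
        )
    return X, blocks.smiles, blocks.failed
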