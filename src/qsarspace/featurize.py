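"""Vector-space molecular representations.

Six representation families are registered behind one interface: a 2D
descriptor matrix and five fingerprint bit-matrices (circular/ECFP, hashed
path, hashed atom-pair, MACCS keys, and a PubChem-style structural key set).
Each featurizer is a pure function of the canonical structure and its
parameters, so feature columns mean the same thing across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .curation import CuratedDataset

__all__ = [
    "FeatureMatrix",
    "FeatureSpec",
    "featurize",
    "registered_representations",
    "enumerate_representations",
    "count_model_tasks",
    "standardize_columns",
    "DEFAULT_CONFIG",
]

FINGERPRINT_TAGS = ("maccs", "pubchem_like", "path_fp", "atom_pair", "ecfp")


@dataclass
class FeatureMatrix:
    """Molecules x dimensions matrix with a representation tag.

    Fingerprint matrices hold only {0,1}; descriptor matrices are real-valued
    with no missing entries (columns undefined for any molecule are removed).
    """

    matrix: np.ndarray
    dim_names: list[str]
    representation: str
    mol_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[0] != len(self.mol_ids):
            raise ValueError("rows do not align with mol_ids")
        if self.matrix.shape[1] != len(self.dim_names):
            raise ValueError("columns do not align with dim_names")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.is_binary and not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError(f"{self.representation} fingerprint must be 0/1")

    @property
    def is_binary(self) -> bool:
        return self.representation in FINGERPRINT_TAGS or self.representation.startswith("bits")

    @property
    def n_dims(self) -> int:
        return self.matrix.shape[1]

    def rows(self, mol_ids: list[str]) -> "FeatureMatrix":
        """Row subset in the requested mol_id order."""
        index = {m: i for i, m in enumerate(self.mol_ids)}
        missing = [m for m in mol_ids if m not in index]
        if missing:
            raise KeyError(f"mol_ids not present in feature matrix: {missing[:5]}")
        sel = [index[m] for m in mol_ids]
        return FeatureMatrix(self.matrix[sel], list(self.dim_names),
                             self.representation, list(mol_ids))


@dataclass(frozen=True)
class FeatureSpec:
    representation: str
    params: dict = field(default_factory=dict)


def _mols(dataset: CuratedDataset) -> list[Chem.Mol]:
    mols = []
    for rec in dataset.records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise ValueError(f"unparseable structure for {rec.mol_id}: {rec.smiles}")
        mols.append(mol)
    return mols


def _bits_from_generator(gen, mols) -> np.ndarray:
    out = np.zeros((len(mols), gen.GetOptions().fpSize), dtype=float)
    for i, mol in enumerate(mols):
        fp = gen.GetFingerprint(mol)
        out[i, list(fp.GetOnBits())] = 1.0
    return out


def _ecfp(mols, radius: int = 3, n_bits: int = 2048):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    names = [f"ecfp{2 * radius}_{i}" for i in range(n_bits)]
    return _bits_from_generator(gen, mols), names


def _path_fp(mols, min_path: int = 1, max_path: int = 7, n_bits: int = 2048):
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        minPath=min_path, maxPath=max_path, fpSize=n_bits)
    names = [f"path_{i}" for i in range(n_bits)]
    return _bits_from_generator(gen, mols), names


def _atom_pair(mols, n_bits: int = 2048):
    gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
    names = [f"ap_{i}" for i in range(n_bits)]
    return _bits_from_generator(gen, mols), names


def _maccs(mols):
    out = np.zeros((len(mols), 167), dtype=float)
    for i, mol in enumerate(mols):
        fp = MACCSkeys.GenMACCSKeys(mol)
        out[i, list(fp.GetOnBits())] = 1.0
    return out, [f"maccs_{i}" for i in range(167)]


# Substitute structural key set standing in for the CDK PubChem 881-bit keys:
# 56 element/ring/feature count keys plus an RDKit substructure-pattern
# fingerprint folded into the remaining 825 positions (881 bits total).
_COUNT_KEYS: list[tuple[str, int]] = [
    (sym, thr)
    for sym in ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
    for thr in (1, 2, 4, 8)
]
_RING_KEYS = [(size, thr) for size in (3, 4, 5, 6, 7, 8) for thr in (1, 2)]


def _pubchem_like(mols, n_bits: int = 881):
    n_keys = len(_COUNT_KEYS) + len(_RING_KEYS) + 2  # + aromatic-ring thresholds
    n_hashed = n_bits - n_keys
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=5, fpSize=n_hashed)
    out = np.zeros((len(mols), n_bits), dtype=float)
    names = (
        [f"pc_count_{sym}>={thr}" for sym, thr in _COUNT_KEYS]
        + [f"pc_ring{size}>={thr}" for size, thr in _RING_KEYS]
        + ["pc_aromatic>=1", "pc_aromatic>=2"]
        + [f"pc_hashed_{i}" for i in range(n_hashed)]
    )
    for i, mol in enumerate(mols):
        counts = {}
        for atom in mol.GetAtoms():
            counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        col = 0
        for sym, thr in _COUNT_KEYS:
            out[i, col] = 1.0 if counts.get(sym, 0) >= thr else 0.0
            col += 1
        ring_info = mol.GetRingInfo()
        ring_sizes = [len(r) for r in ring_info.AtomRings()]
        for size, thr in _RING_KEYS:
            out[i, col] = 1.0 if sum(1 for s in ring_sizes if s == size) >= thr else 0.0
            col += 1
        n_aromatic = sum(
            1 for ring in ring_info.BondRings()
            if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring))
        out[i, col] = 1.0 if n_aromatic >= 1 else 0.0
        out[i, col + 1] = 1.0 if n_aromatic >= 2 else 0.0
        on_bits = list(gen.GetFingerprint(mol).GetOnBits())
        if on_bits:
            out[i, n_keys + np.array(on_bits, dtype=int)] = 1.0
    return out, names


def _descriptors(mols):
    """All RDKit 2D descriptors; drops undefined and constant columns."""
    names = [name for name, _ in Descriptors._descList]
    funcs = dict(Descriptors._descList)
    raw = np.empty((len(mols), len(names)))
    for i, mol in enumerate(mols):
        for j, name in enumerate(names):
            try:
                raw[i, j] = funcs[name](mol)
            except Exception:
                raw[i, j] = np.nan
    defined = np.isfinite(raw).all(axis=0)
    raw, names = raw[:, defined], [n for n, ok in zip(names, defined) if ok]
    varying = raw.std(axis=0) > 0
    return raw[:, varying], [n for n, ok in zip(names, varying) if ok]


_REGISTRY = {
    "descriptors": _descriptors,
    "maccs": _maccs,
    "pubchem_like": _pubchem_like,
    "path_fp": _path_fp,
    "atom_pair": _atom_pair,
    "ecfp": _ecfp,
}


def registered_representations() -> list[str]:
    return sorted(_REGISTRY)


def featurize(dataset: CuratedDataset, spec: FeatureSpec | str) -> FeatureMatrix:
    """Compute one representation for every molecule of a curated dataset."""
    if isinstance(spec, str):
        spec = FeatureSpec(spec)
    if spec.representation not in _REGISTRY:
        raise ValueError(
            f"unknown representation {spec.representation!r}; "
            f"registered: {registered_representations()}")
    matrix, names = _REGISTRY[spec.representation](_mols(dataset), **spec.params)
    return FeatureMatrix(matrix, names, spec.representation, dataset.mol_ids)


def standardize_columns(fm: FeatureMatrix, train_mask: np.ndarray) -> FeatureMatrix:
    """Zero-mean/unit-variance columns using training-set statistics only.

    Applied to descriptor matrices (heterogeneous units) before PCA or SVM;
    fingerprints are left as raw bits.
    """
    mean = fm.matrix[train_mask].mean(axis=0)
    sd = fm.matrix[train_mask].std(axis=0)
    sd[sd == 0] = 1.0
    return FeatureMatrix((fm.matrix - mean) / sd, list(fm.dim_names),
                         fm.representation + "_std", list(fm.mol_ids))


# 18 representations: 6 vector-space families under feature selection, the same
# 6 under PCA, and 6 similarity sources (5 fingerprint Tanimoto + 1 graph-based)
# under metric-space PCA.
DEFAULT_CONFIG: dict[str, list[str]] = {
    "vector_fs": ["descriptors", *FINGERPRINT_TAGS],
    "vector_pca": ["descriptors", *FINGERPRINT_TAGS],
    "metric_pca": [*FINGERPRINT_TAGS, "graph"],
}


def enumerate_representations(config: dict[str, list[str]] | None = None
                              ) -> list[tuple[str, str]]:
    """(approach, representation) pairs of an experiment configuration."""
    if config is None:
        config = DEFAULT_CONFIG
    known = {"vector_fs", "vector_pca", "metric_pca"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown approaches: {sorted(unknown)}")
    return [(app, rep) for app in ("vector_fs", "vector_pca", "metric_pca")
            for rep in config.get(app, [])]


def count_model_tasks(config=None, n_datasets: int = 1) -> int:
    return len(enumerate_representations(config)) * n_datasets
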