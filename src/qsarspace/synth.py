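"""Synthetic structure-activity benchmark generator.

Emulates the statistical structure of a curated binding-affinity dataset so
the whole pipeline runs offline: molecules form clustered chemical series
(cluster centroid bit-vectors with per-bit mutation), activity is driven by a
handful of informative substructure bits plus a per-cluster effect and noise,
and the latent activity is inverted to Ki through Ki = 10^(4 (1 - y*)) nM so
that values beyond [0, 1] exercise both clamp clauses of the spKi transform.
Duplicate measurements (differing years), salt-like records (appended small
fragment) and activity cliffs (anti-correlated activity draws) are injected
at configurable rates.

The fingerprint matrix is emitted directly (no toolkit parsing needed), and a
parallel set of simple valid SMILES strings is generated for toolkit smoke
tests and for exercising the curation rules.  Six representation "families"
are derived from the bit matrix by deterministic, information-preserving
re-encodings, standing in for the descriptor and fingerprint families of real
chemistry runs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import MoleculeRecord
from .featurize import FeatureMatrix
from .similarity import SimilarityMatrix

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate",
           "emulate_representation", "oracle_pve"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults describe a mid-sized clustered series."""

    n_molecules: int = 400
    n_bits: int = 256
    n_clusters: int = 8
    bit_density: float = 0.3        # centroid P(bit on)
    mutation_rate: float = 0.05     # per-bit flip probability within a series
    n_informative_bits: int = 5
    effect_sizes: tuple[float, ...] | None = None  # default: 0.15..0.35 evenly
    baseline: float = 0.05          # latent activity intercept
    cluster_effect_sd: float = 0.15
    noise_sd: float = 0.05
    cliff_fraction: float = 0.0
    duplicate_fraction: float = 0.05
    salt_fraction: float = 0.05
    seed: int = 1234

    def __post_init__(self) -> None:
        for name in ("bit_density", "mutation_rate", "cliff_fraction",
                     "duplicate_fraction", "salt_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_informative_bits > self.n_bits:
            raise ValueError("n_informative_bits exceeds n_bits")
        if self.n_clusters > self.n_molecules:
            raise ValueError("more clusters than molecules")

    @property
    def betas(self) -> np.ndarray:
        if self.effect_sizes is not None:
            if len(self.effect_sizes) != self.n_informative_bits:
                raise ValueError("effect_sizes length != n_informative_bits")
            return np.asarray(self.effect_sizes, dtype=float)
        return np.linspace(0.15, 0.35, self.n_informative_bits)


@dataclass
class SyntheticDataset:
    records: list[MoleculeRecord]       # raw table, pre-curation
    bits: pd.DataFrame                  # mol_id-indexed fingerprint matrix
    truth: pd.DataFrame                 # mol_id, cluster, y_star, informative bits
    informative_bits: np.ndarray        # bit indices carrying the signal
    spec: SyntheticSpec = field(repr=False, default=None)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mol_id": [r.mol_id for r in self.records],
             "smiles": [r.smiles for r in self.records],
             "ki_nM": [r.ki_nM for r in self.records],
             "year": [r.year for r in self.records]})

    def bit_matrix(self, mol_ids: list[str]) -> FeatureMatrix:
        sub = self.bits.loc[mol_ids]
        return FeatureMatrix(sub.to_numpy(dtype=float), list(self.bits.columns),
                             "bits", list(mol_ids))

    def graph_similarity(self, mol_ids: list[str]) -> SimilarityMatrix:
        """Stand-in graph-based similarity: simple matching coefficient.

        Counts agreeing bits (both on or both off), unlike Tanimoto which
        ignores shared absences — a distinct, file-loadable score in [0, 1].
        """
        B = self.bits.loc[mol_ids].to_numpy(dtype=float)
        agree = B @ B.T + (1 - B) @ (1 - B).T
        return SimilarityMatrix(agree / B.shape[1], list(mol_ids), list(mol_ids),
                                "graph_smc")


def _index_smiles(i: int, width: int) -> str:
    """Unique, valid SMILES per index: t-Bu cap + C/O chain encoding i in binary."""
    body = "".join("O" if (i >> b) & 1 else "C" for b in range(width))
    return "CC(C)(C)" + body


def generate(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Draw one synthetic dataset; fully reproducible under spec.seed."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_molecules, spec.n_bits

    centroids = rng.random((spec.n_clusters, d)) < spec.bit_density
    cluster = rng.integers(0, spec.n_clusters, size=n)
    flips = rng.random((n, d)) < spec.mutation_rate
    bits = centroids[cluster] ^ flips

    info = rng.choice(d, size=spec.n_informative_bits, replace=False)
    info.sort()
    betas = spec.betas
    cluster_effect = rng.normal(0.0, spec.cluster_effect_sd, spec.n_clusters)
    y_star = (spec.baseline + bits[:, info] @ betas + cluster_effect[cluster]
              + rng.normal(0.0, spec.noise_sd, n))

    if spec.cliff_fraction > 0:
        n_cliff = int(round(spec.cliff_fraction * n))
        cliff_idx = rng.choice(n, size=n_cliff, replace=False)
        y_star[cliff_idx] = 2 * y_star.mean() - y_star[cliff_idx]

    ki = 10.0 ** (4.0 * (1.0 - y_star))  # inverts the spKi mapping
    years = rng.integers(1995, 2016, size=n)

    width = max(1, int(np.ceil(np.log2(max(n, 2)))))
    mol_ids = [f"M{i:05d}" for i in range(n)]
    smiles = [_index_smiles(i, width) for i in range(n)]

    salted = rng.random(n) < spec.salt_fraction
    records = [
        MoleculeRecord(mol_id=mol_ids[i],
                       smiles=smiles[i] + (".O" if salted[i] else ""),
                       ki_nM=float(ki[i]), year=int(years[i]))
        for i in range(n)]

    # duplicates: older re-measurements with perturbed Ki, so curation keeps
    # the original (most recent) record and the ground truth stays aligned
    n_dup = int(round(spec.duplicate_fraction * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False)
    for j, i in enumerate(dup_idx):
        records.append(MoleculeRecord(
            mol_id=f"D{j:05d}", smiles=smiles[i],
            ki_nM=float(ki[i] * 10 ** rng.normal(0.0, 0.1)),
            year=int(years[i]) - int(rng.integers(1, 6))))

    bits_df = pd.DataFrame(bits.astype(float), index=mol_ids,
                           columns=[f"bit_{j}" for j in range(d)])
    truth = pd.DataFrame({"mol_id": mol_ids, "cluster": cluster,
                          "y_star": y_star})
    for b, j in enumerate(info):
        truth[f"info_bit_{j}"] = bits[:, j].astype(int)
    return SyntheticDataset(records=records, bits=bits_df, truth=truth,
                            informative_bits=info, spec=spec)


# deterministic re-encodings of the bit matrix standing in for the six
# representation families when no real chemistry is available
def _tag_rng(tag: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(tag.encode()) % (2 ** 31))


def emulate_representation(bits: FeatureMatrix, representation: str,
                           ) -> FeatureMatrix:
    """Map the ground-truth bit matrix to a named representation family.

    descriptors: sums over blocks of 4 bits (small-integer "counts");
    maccs / pubchem_like: fold or scatter to the family's key width;
    ecfp / path_fp / atom_pair: fixed tag-seeded bit permutations.
    All transforms are deterministic and preserve the recoverable signal.
    """
    B = bits.matrix
    n, d = B.shape
    ids = list(bits.mol_ids)
    if representation == "descriptors":
        width = 4
        pad = (-d) % width
        M = np.pad(B, ((0, 0), (0, pad))).reshape(n, -1, width).sum(axis=2)
        names = [f"desc_{j}" for j in range(M.shape[1])]
        return FeatureMatrix(M, names, "descriptors", ids)
    if representation == "maccs":
        M = np.zeros((n, 167))
        for j in range(d):
            M[:, j % 167] = np.maximum(M[:, j % 167], B[:, j])
        return FeatureMatrix(M, [f"maccs_{j}" for j in range(167)], "maccs", ids)
    if representation == "pubchem_like":
        M = np.zeros((n, 881))
        for j in range(d):
            M[:, (j * 7) % 881] = np.maximum(M[:, (j * 7) % 881], B[:, j])
        return FeatureMatrix(M, [f"pc_{j}" for j in range(881)],
                             "pubchem_like", ids)
    if representation in ("ecfp", "path_fp", "atom_pair"):
        perm = _tag_rng(representation).permutation(d)
        return FeatureMatrix(B[:, perm], [f"{representation}_{j}" for j in range(d)],
                             representation, ids)
    raise ValueError(f"no synthetic emulation for representation {representation!r}")


def oracle_pve(dataset: SyntheticDataset, activities: pd.Series) -> float:
    """PVE of a least-squares fit of activity on the true informative bits.

    Certifies the generator: with cliffs off, small noise and no cluster
    effect, the informative bits alone must explain nearly all the variance.
    """
    ids = list(activities.index)
    X = dataset.bits.loc[ids].iloc[:, dataset.informative_bits].to_numpy()
    X = np.column_stack([np.ones(len(ids)), X])
    y = activities.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return 1.0 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum())
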