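"""Activity-data curation: cleaning, deduplication, spKi transform, train/IVS split.

Raw bioactivity tables (one row per measurement: identifier, SMILES, Ki in nM,
publication year) are cleaned the way medicinal-chemistry QSAR sets usually are:
unparseable structures and missing affinities are dropped, salt/mixture records
are reduced to their largest fragment, and duplicate measurements of the same
compound are collapsed to the most recent one.  Ki is then mapped to spKi, a
scaled and clamped pKi in [0, 1]::

    spKi = 0                      if Ki >= 10,000 nM
         = (4 - log10(Ki)) / 4    if 1 nM < Ki < 10,000 nM
         = 1                      if Ki <= 1 nM

so that very weak binders all score 0 and sub-nanomolar binders all score 1.
Finally the curated set is split once into a training set and an independent
validation set (IVS); the IVS is never seen by any downstream fitting or
selection step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

KI_UPPER_NM = 10_000.0
KI_LOWER_NM = 1.0

__all__ = [
    "MoleculeRecord",
    "CuratedDataset",
    "spki",
    "curate",
    "split",
    "read_records_csv",
    "read_curated_csv",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """One bioactivity measurement: identifier, structure, Ki (nM), year."""

    mol_id: str
    smiles: str
    ki_nM: float | None = None
    year: int | None = None


@dataclass
class CuratedDataset:
    """Curated molecule set with spKi activities and an optional train/IVS split."""

    records: list[MoleculeRecord]
    spki: np.ndarray
    split: np.ndarray | None = None  # per-record labels in {"train", "ivs"}
    provenance_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.mol_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mol_id in curated dataset")
        self.spki = np.asarray(self.spki, dtype=float)
        if self.spki.shape != (len(self.records),):
            raise ValueError("spki length does not match records")
        if len(self.records) and (self.spki.min() < 0 or self.spki.max() > 1):
            raise ValueError("spki values must lie in [0, 1]")

    @property
    def mol_ids(self) -> list[str]:
        return [r.mol_id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def _mask(self, label: str) -> np.ndarray:
        if self.split is None:
            raise ValueError("dataset has not been split")
        return np.asarray(self.split) == label

    @property
    def train_mask(self) -> np.ndarray:
        return self._mask("train")

    @property
    def ivs_mask(self) -> np.ndarray:
        return self._mask("ivs")

    @property
    def train_ids(self) -> list[str]:
        m = self.train_mask
        return [r.mol_id for r, keep in zip(self.records, m) if keep]

    @property
    def ivs_ids(self) -> list[str]:
        m = self.ivs_mask
        return [r.mol_id for r, keep in zip(self.records, m) if keep]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "mol_id": self.mol_ids,
                "smiles": self.smiles,
                "ki_nM": [r.ki_nM for r in self.records],
                "year": [r.year for r in self.records],
                "spki": self.spki,
            }
        )
        if self.split is not None:
            df["split"] = self.split
        return df

    def write_csv(self, path, provenance_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                json.dump(self.provenance_log, fh, indent=1)


def spki(ki_nM: float) -> float:
    """Scaled, clamped pKi in [0, 1] from a Ki in nanomolar.

    Raises ``ValueError`` for non-positive input (Ki is a concentration).
    """
    ki = float(ki_nM)
    if not ki > 0 or math.isnan(ki):
        raise ValueError(f"Ki must be a positive concentration in nM, got {ki_nM!r}")
    if ki >= KI_UPPER_NM:
        return 0.0
    if ki <= KI_LOWER_NM:
        return 1.0
    return (4.0 - math.log10(ki)) / 4.0


def _canonical_largest_fragment(smiles: str) -> tuple[str | None, bool]:
    """Canonical SMILES of the largest fragment; flag is True when fragments dropped.

    Largest by heavy-atom count, ties broken by total atom count then by
    canonical SMILES (lexicographically smallest) for determinism.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None, False
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    multi = len(frags) > 1
    best = max(
        frags,
        key=lambda m: (m.GetNumHeavyAtoms(), m.GetNumAtoms(), Chem.MolToSmiles(m)),
    )
    return Chem.MolToSmiles(best), multi


def curate(raw_records: list[MoleculeRecord]) -> CuratedDataset:
    """Clean a raw measurement table into a curated, deduplicated dataset.

    Rules, in order: drop records with missing Ki; drop unparseable structures;
    reduce multi-fragment structures (salts, mixtures) to the largest fragment;
    canonicalize; among records sharing a canonical structure keep the most
    recent year (records without a year lose ties; remaining ties keep the
    record latest in input order).  Every action is appended to the provenance
    log.  Raises ``ValueError`` if nothing usable remains.
    """
    if not raw_records:
        raise ValueError("no input records")
    log: list[dict] = []
    cleaned: list[MoleculeRecord] = []
    for rec in raw_records:
        if rec.ki_nM is None or math.isnan(rec.ki_nM):
            log.append({"action": "drop_missing_ki", "mol_id": rec.mol_id})
            continue
        if rec.ki_nM <= 0:
            log.append({"action": "drop_nonpositive_ki", "mol_id": rec.mol_id})
            continue
        if not rec.smiles:
            log.append({"action": "drop_empty_smiles", "mol_id": rec.mol_id})
            continue
        canon, had_fragments = _canonical_largest_fragment(rec.smiles)
        if canon is None:
            log.append({"action": "drop_unparseable", "mol_id": rec.mol_id,
                        "smiles": rec.smiles})
            continue
        if had_fragments:
            log.append({"action": "keep_largest_fragment", "mol_id": rec.mol_id,
                        "from": rec.smiles, "to": canon})
        cleaned.append(replace(rec, smiles=canon))

    # deduplicate on canonical structure, keeping the most recent measurement
    by_structure: dict[str, tuple[int, MoleculeRecord]] = {}
    for pos, rec in enumerate(cleaned):
        prev = by_structure.get(rec.smiles)
        if prev is None:
            by_structure[rec.smiles] = (pos, rec)
            continue
        _, kept = prev
        kept_year = -1 if kept.year is None else kept.year
        new_year = -1 if rec.year is None else rec.year
        if new_year >= kept_year:  # ties: later input order wins
            loser = kept
            by_structure[rec.smiles] = (pos, rec)
        else:
            loser = rec
        log.append({"action": "drop_duplicate", "mol_id": loser.mol_id,
                    "kept": by_structure[rec.smiles][1].mol_id,
                    "structure": rec.smiles})

    kept_records = [rec for _, rec in sorted(by_structure.values())]
    if not kept_records:
        raise ValueError("no usable records after curation")
    activities = np.array([spki(r.ki_nM) for r in kept_records])
    return CuratedDataset(records=kept_records, spki=activities, provenance_log=log)


def split(dataset: CuratedDataset, ivs_fraction: float = 0.2,
          seed: int = 17) -> CuratedDataset:
    """Random train/IVS partition of a curated dataset.

    The partition is drawn after a canonical pre-sort by ``mol_id``, so the
    same seed yields the same partition regardless of input row order.
    """
    if not 0 < ivs_fraction < 1:
        raise ValueError("ivs_fraction must lie strictly between 0 and 1")
    n = len(dataset.records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    n_ivs = int(round(n * ivs_fraction))
    if n_ivs < 2 or n - n_ivs < 2:
        raise ValueError(
            f"ivs_fraction={ivs_fraction} leaves fewer than 2 records on one side")
    order = sorted(range(n), key=lambda i: dataset.records[i].mol_id)
    rng = np.random.default_rng(seed)
    ivs_positions = {order[i] for i in rng.permutation(n)[:n_ivs]}
    labels = np.array(["ivs" if i in ivs_positions else "train" for i in range(n)])
    log = dataset.provenance_log + [
        {"action": "split", "ivs_fraction": ivs_fraction, "seed": seed,
         "n_train": int(n - n_ivs), "n_ivs": int(n_ivs)}]
    return CuratedDataset(records=list(dataset.records), spki=dataset.spki.copy(),
                          split=labels, provenance_log=log)


def read_curated_csv(path) -> CuratedDataset:
    """Read back a curated CSV written by :meth:`CuratedDataset.write_csv`."""
    df = pd.read_csv(path)
    records = [MoleculeRecord(mol_id=str(r.mol_id), smiles=str(r.smiles),
                              ki_nM=None if pd.isna(r.ki_nM) else float(r.ki_nM),
                              year=None if pd.isna(r.year) else int(r.year))
               for r in df.itertuples(index=False)]
    split_col = df["split"].to_numpy() if "split" in df.columns else None
    return CuratedDataset(records=records, spki=df["spki"].to_numpy(float),
                          split=split_col)


def read_records_csv(path) -> list[MoleculeRecord]:
    """Read a raw measurement table (columns mol_id, smiles, ki_nM, year)."""
    df = pd.read_csv(path)
    required = {"mol_id", "smiles", "ki_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"input CSV missing required columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        year = getattr(row, "year", None)
        if year is not None and not pd.isna(year):
            year = int(year)
        else:
            year = None
        ki = None if pd.isna(row.ki_nM) else float(row.ki_nM)
        records.append(MoleculeRecord(mol_id=str(row.mol_id), smiles=str(row.smiles),
                                      ki_nM=ki, year=year))
    return records
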