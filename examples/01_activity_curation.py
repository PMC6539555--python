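"""Curate a small affinity table: salts, duplicates, and the spKi transform.

Builds a toy measurement table with a salt record and a duplicated compound,
runs the curation rules, and prints the spKi activities.
"""

from qsarspace import MoleculeRecord, curate, spki, split

records = [
    MoleculeRecord("chembl_1", "CCOc1ccccc1", ki_nM=12.0, year=2011),
    MoleculeRecord("chembl_2", "CCOc1ccccc1", ki_nM=45.0, year=2016),  # newer duplicate
    MoleculeRecord("chembl_3", "CCN(CC)CC.Cl", ki_nM=850.0, year=2009),  # HCl salt
    MoleculeRecord("chembl_4", "c1ccc2ccccc2c1", ki_nM=25_000.0, year=2014),  # inactive
    MoleculeRecord("chembl_5", "CC(C)Cc1ccc(C)cc1", ki_nM=0.4, year=2013),  # sub-nM
]

dataset = curate(records)
print("kept records:")
for rec, activity in zip(dataset.records, dataset.spki):
    print(f"  {rec.mol_id:10s} {rec.smiles:22s} Ki={rec.ki_nM:>8.1f} nM "
          f"spKi={activity:.3f}")
print()
print("curation log actions:", [e["action"] for e in dataset.provenance_log])
print()
# spKi maps Ki in nM onto [0, 1]: 0 at/above 10 uM (inactive), 1 at/below 1 nM
for ki in (10_000.0, 100.0, 1.0):
    print(f"spKi({ki:>8.0f} nM) = {spki(ki):.2f}")

# the duplicate kept is the 2016 measurement; the salt lost its Cl fragment;
# naphthalene's weak Ki clamps to spKi 0 and the sub-nM compound to 1
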