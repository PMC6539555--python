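"""Fingerprint a few molecules and build a Tanimoto similarity matrix.

Shows the vector-space representations registered for real structures and
the metric-space view (each molecule as its similarity profile).
"""

import numpy as np

from qsarspace import MoleculeRecord, curate, featurize, similarity_matrix
from qsarspace.featurize import FeatureSpec, registered_representations

records = [
    MoleculeRecord("benzene", "c1ccccc1", 500.0, 2010),
    MoleculeRecord("toluene", "Cc1ccccc1", 300.0, 2010),
    MoleculeRecord("phenol", "Oc1ccccc1", 200.0, 2010),
    MoleculeRecord("hexane", "CCCCCC", 9000.0, 2010),
]
dataset = curate(records)

print("registered representations:", registered_representations())
for rep in ("ecfp", "maccs", "pubchem_like"):
    fm = featurize(dataset, FeatureSpec(rep))
    print(f"{rep:13s} matrix {fm.matrix.shape}, "
          f"mean popcount {fm.matrix.sum(axis=1).mean():.1f}")

S = similarity_matrix(featurize(dataset, "ecfp"))
print("\nTanimoto similarity (ECFP):")
with np.printoptions(precision=2, suppress=True):
    print("  ", S.row_ids)
    print(S.values)
# the three aromatics are mutually more similar than any of them is to
# hexane; the diagonal is exactly 1
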