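"""Feedforward dimension selection and final IVS evaluation for one cell.

Runs the metric-space pipeline (Tanimoto matrix -> fold-wise PCA -> SVR)
on a synthetic benchmark, printing the CV selection curve and the one-shot
independent-validation score.
"""

from qsarspace import curate, split
from qsarspace.pipeline import DatasetSource, RunConfig, run_cell
from qsarspace.synth import SyntheticSpec, generate

data = generate(SyntheticSpec(seed=1))
dataset = split(curate(data.records), ivs_fraction=0.2, seed=17)

config = RunConfig(datasets=[], seed=17, k_max=20, k_dense=20, cv_folds=5)
source = DatasetSource("demo", synthetic=data.spec)
ev, curve = run_cell(dataset, "metric_pca", "ecfp", config, source, data)

print("k   mean CV PVE   mean CV RMSE")
for k, pve, rmse in zip(curve.k_values, curve.mean_cv_pve, curve.mean_cv_rmse):
    marker = "  <- chosen" if k == curve.chosen_k else ""
    print(f"{k:<4d}{pve:>10.3f}{rmse:>14.3f}{marker}")
print(f"\nchosen k = {ev.chosen_k} principal components")
print(f"IVS PVE  = {ev.ivs_pve:.3f}   (variance explained on molecules never "
      "seen during selection or fitting)")
print(f"IVS RMSE = {ev.ivs_rmse:.3f}  (on the spKi scale, 0..1)")
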