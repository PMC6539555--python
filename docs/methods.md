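# Methods

This note documents the modeling choices, defaults and known limitations of
`qsarspace`, in the spirit of a model-description appendix.

## Activity model and curation

Bioactivity is a binding affinity Ki in nanomolar. Modeling uses spKi, a
scaled and clamped pKi: 0 at or above 10 000 nM, 1 at or below 1 nM, and
(4 − log₁₀ Ki)/4 in between. The transform is continuous and non-increasing
in Ki; the clamps encode the judgment that discriminating among very weak
(> 10 µM) or very potent (< 1 nM) compounds is not useful for regression.

Curation rules, in order: records with missing or non-positive Ki are
dropped; unparseable structures are dropped (logged, not fatal);
multi-fragment SMILES are reduced to the largest fragment (heavy-atom count,
ties by total atoms then canonical SMILES); structures are canonicalized
with RDKit; duplicates — detected on the canonical structure *after*
fragment reduction, not on identifiers — keep the record with the greatest
publication year. Records without a year lose ties ("most recent" is only
assessable with a year); remaining exact ties keep the record latest in
input order, which makes deduplication order-auditable. Every action is
appended to a provenance log.

The train/IVS split is uniform random without stratification. Default IVS
fraction 0.2, default seed 17; the partition is drawn after a canonical sort
by `mol_id`, so it is invariant to input row order. The IVS is scored
exactly once per model and is never visible to ranking, PCA, selection, or
fitting.

## Representations

Vector space (all via RDKit, deterministic given the canonical structure):

| tag            | family                      | default width |
|----------------|-----------------------------|---------------|
| `descriptors`  | all RDKit 2D descriptors    | toolkit-dependent; undefined and constant columns removed |
| `maccs`        | MACCS structural keys       | 167 |
| `pubchem_like` | substitute structural keys  | 881 |
| `path_fp`      | hashed paths, lengths 1–7   | 2048 |
| `atom_pair`    | hashed atom pairs           | 2048 |
| `ecfp`         | Morgan circular, radius 3   | 2048 |

The `pubchem_like` set is *not* the CDK PubChem implementation: it is 56
element/ring/aromaticity count keys plus an RDKit substructure-pattern
fingerprint folded into the remaining 825 positions. It fills the
"substructure key" slot of the six-family design without a second toolkit
dependency. The ECFP radius defaults to 3 (ECFP6-style) and is configurable;
radius 2 gives ECFP4-style keys. Descriptor columns are standardized to zero
mean and unit variance with training-set statistics only (heterogeneous
units); fingerprints stay raw bits. 3D descriptors are omitted — no
conformers are generated.

Metric space: the Tanimoto coefficient c/(a + b − c) over each fingerprint
family, used directly as a similarity (not converted to distance). Two
all-zero fingerprints score 1 by convention (identical absence of features),
avoiding 0/0 while preserving symmetry. Graph-based similarity (e.g.,
atom-matching scores) is consumed only as a precomputed labeled CSV matrix:
rows/columns are reordered to the requested molecules, values optionally
max-normalized into [0, 1], and square matrices asymmetric beyond 1e-8 are
symmetrized by averaging with a warning. The full default grid is 18
treatments: 3 approaches × 6 representations (metric space swaps descriptors
for the graph similarity).

## Dimension reduction and model building

PCA stores column means, orthonormal loadings and the explained-variance
spectrum explicitly; out-of-sample rows are projected as
(x − mean)·loadings. In metric space a training molecule's "feature vector"
is its similarity profile to all training molecules, and a query's is its
cross-similarity row to the same training molecules in the same order.
Similarity matrices and fingerprint bit matrices are centered but not
scaled (shared scale); descriptors are standardized upstream. Loadings carry
a deterministic sign convention (largest-magnitude element positive).
Components run up to min(n − 1, n_dims); constant matrices are an error.

Feature ranking uses a random-forest regressor (500 trees, one third of the
dimensions tried per split) with permutation importance — the mean increase
in squared error over 5 permutations of each column — computed on the
training data, ties broken by dimension index.

The feedforward selection adds dimensions one at a time (ranked order for
SF-models, variance order for OPC-models) and evaluates each count k with
five-fold cross-validation of an RBF-kernel ε-SVR (C = 1, γ = 1/d,
ε = 0.1 — the e1071/libsvm defaults). The selected k minimizes the mean CV
RMSE, ties to the smallest k; mean CV PVE is recorded alongside. The default
k-schedule is dense (step 1) up to 30 and step 5 beyond, capped at
min(100, n − 1, n_dims); this is a compute concession relative to a pure
step-1 sweep and is configurable (`k_dense`, `k_step`, `k_max`).

Within each CV fold of a PCA approach the reduction is *refit from the
fold's training molecules only* — in metric space this means the fold-train
square similarity block and cross-similarity projection of the held-out
fold. Refitting once on the full training set is the laxer, cheaper variant
and is exposed as `refit_per_fold=False`; the strict default exists because
fold-test molecules would otherwise shape the components. A pure-noise
control (CV PVE stays ≤ 0.1 for all k) guards this path in the tests.

After selection the SVR is refit on the entire training set and the IVS is
scored once: RMSE and PVE = 1 − SSres/SStot. PVE is reported as missing when
the evaluation activities are constant. SVR fitting is a deterministic
optimization; identical inputs give identical models.

## Representation comparison

Treatments are ranked within each dataset by IVS PVE, rank 1 best, ties
averaged. The Friedman statistic uses the standard tie-corrected form
(k − 1)·Σ(Rⱼ − n(k+1)/2)² / (A − C), with A the sum of squared ranks and
C = nk(k+1)²/4, which reduces to 12/(nk(k+1))·ΣRⱼ² − 3n(k+1) without ties;
the p-value is the chi-square upper tail on k − 1 df. Post hoc grouping uses
the Conover rank-sum least significant difference,
t₁₋α/2,(n−1)(k−1) · √(2n(A − C)(1 − T₁/(n(k−1)))/((n−1)(k−1))), at
α = 0.05 by default. Because significance depends only on the rank-sum gap,
letter groups are maximal runs of rank-sum-sorted treatments whose extremes
do not differ; two treatments share a letter exactly when their difference
is non-significant, and a treatment can belong to several groups. Letter
labels may differ from other software even when the significance relation
agrees; equivalence is established against an all-pairs oracle, not against
any published figure.

## Nearest-neighbor pruning

Removal is greedy max-degree elimination on the graph of pairs with
similarity ≥ threshold: repeatedly delete the molecule with the most
violating neighbors (ties: larger maximum similarity, then smaller id), then
restore any removed molecule with no kept neighbor, so the kept set is
maximal and deterministic. An exact maximum independent set is intractable
and not required — the goal is a threshold-respecting subset of near-maximal
size. Threshold calibration bisects on (0, 1] (prune size is non-decreasing
in the threshold) and returns the threshold whose size lands closest to the
target, ties to the larger threshold. Pruning is applied before the
train/IVS split.

## Synthetic benchmark

The generator emulates the structure the analysis assumes, not real
medicinal chemistry. Cluster centroids are Bernoulli(p_on = 0.3) bit vectors
of length 256 (8 clusters by default); members copy their centroid with
per-bit flip probability ε = 0.05, giving within-series Tanimoto similarity
well above between-series similarity. Latent activity is
y* = 0.05 + Σβⱼ·bitⱼ + cluster effect + noise, with 5 informative bits,
effect sizes evenly spaced on [0.15, 0.35], cluster effects N(0, 0.15²) and
noise N(0, 0.05²). Ki = 10^(4(1 − y*)) nM inverts the spKi transform, and
the intercept is set low enough that default draws land beyond *both*
clamps (sub-nM actives and ≥ 10 µM inactives). An optional cliff fraction
replaces y* with an anti-correlated reflection about the mean, emulating
activity cliffs. Five percent of records are re-emitted as older duplicate
measurements with perturbed Ki (curation keeps the original, so the ground
truth stays aligned), and five percent of structure strings carry a small
disconnected fragment to exercise salt stripping.

Each molecule also gets a unique, valid SMILES (a tert-butyl cap plus a C/O
chain encoding its index) so the RDKit featurizers can run on synthetic
data; these strings carry no activity signal — on synthetic runs the six
representation families are deterministic, signal-preserving re-encodings
of the ground-truth bit matrix (block sums for "descriptors", folds/scatters
to the key widths, fixed permutations for the hashed families), and the
graph-similarity stand-in is the simple matching coefficient (fraction of
agreeing bits), a distinct score from Tanimoto. Consequently the synthetic
benchmark certifies the *pipeline machinery* — leakage control, selection,
projection, ranking — and the relative behavior of approaches under a known
signal; it does not certify performance on real chemical matter, where
feature relevance, similarity scales and activity landscapes are far less
benign. A sufficiency check (least-squares on the informative bits reaches
PVE ≥ 0.9 with cluster effects and noise switched off) certifies the
generator before the generator certifies anything else.

## Problem sizes and numerical choices

Tests and examples run the pipeline at the default benchmark size (400
molecules, 320 train / 80 IVS) with the k-schedule capped at 20 dense
steps, and the pruning experiment at 5 seeds with the target size one third
of the original; these sizes keep the suite quick while leaving the
selection curves well past their minima. Tolerances: PCA orthonormality and
projection round-trips at 1e-8–1e-9; similarity symmetry at 1e-8; chi-square
upper tail delegated to scipy (relative accuracy far below 1e-6). Degenerate
inputs fail loudly rather than silently: constant activity vectors, constant
feature matrices, folds with fewer than two distinct activities, similarity
files with missing molecules, and infeasible pruning targets all raise.

## Known limitations

- The `pubchem_like` keys are a substitute set, not bit-compatible with CDK
  PubChem fingerprints; absolute per-bit comparisons with other software are
  not meaningful.
- The descriptor set is whatever the installed RDKit exposes; its size is
  toolkit-version dependent and deliberately not a contract.
- Graph-based similarity is consumed as data; no graph-matching algorithm is
  implemented here.
- The SVM and RF hyperparameters are fixed library defaults by design; the
  pipeline compares representations, it does not tune learners.
- Friedman-based comparison needs several datasets to have power; with two
  or three blocks the post hoc letters will usually merge all treatments.
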