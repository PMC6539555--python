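"""Nearest-neighbor removal: harden a dataset by deleting similar molecules.

Similarity-based QSAR scores are inflated when near-duplicates of training
molecules sit in the validation set.  To probe robustness, molecules are
removed until no pair in the dataset reaches a given similarity threshold;
because different similarity methods live on different scales, the threshold
can be calibrated per method so the pruned sets have comparable sizes.
Pruning is applied before the train/IVS split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["PruneResult", "prune", "calibrate_threshold"]


@dataclass
class PruneResult:
    method: str
    threshold: float
    kept_ids: list[str]
    n_before: int
    n_after: int
    max_pairwise_similarity: float


def prune(S: SimilarityMatrix, threshold: float) -> PruneResult:
    """Greedy nearest-neighbor removal at a similarity threshold.

    A pair "violates" when its similarity is >= threshold.  The molecule with
    the most violating neighbors is removed repeatedly (ties: larger maximum
    similarity to the others, then lexicographically smaller id) until no
    violating pair remains; removed molecules that ended up with no kept
    violating neighbor are restored, so the kept set is maximal.
    """
    if not S.is_square:
        raise ValueError("prune requires a square similarity matrix")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    ids = list(S.row_ids)
    n = len(ids)
    sim = S.values.copy()
    np.fill_diagonal(sim, -np.inf)
    adj = sim >= threshold

    alive = np.ones(n, dtype=bool)
    removed: list[int] = []
    while True:
        deg = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = -1
        if deg.max() <= 0:
            break
        worst = np.flatnonzero(deg == deg.max())
        if len(worst) > 1:
            masked = np.where(alive[None, :], sim[worst], -np.inf)
            max_sim = masked.max(axis=1)
            worst = worst[max_sim == max_sim.max()]
            if len(worst) > 1:
                worst = [min(worst, key=lambda i: ids[i])]
        victim = int(worst[0])
        alive[victim] = False
        removed.append(victim)
    # restore pass: a removed molecule with no kept neighbor can come back
    for i in sorted(removed, key=lambda i: ids[i]):
        if not (adj[i] & alive).any():
            alive[i] = True
    kept = np.flatnonzero(alive)
    max_sim = float(sim[np.ix_(kept, kept)].max()) if len(kept) > 1 else 0.0
    return PruneResult(method=S.method, threshold=float(threshold),
                       kept_ids=[ids[i] for i in kept], n_before=n,
                       n_after=int(len(kept)), max_pairwise_similarity=max_sim)


def calibrate_threshold(S: SimilarityMatrix, target_n: int,
                        iterations: int = 40) -> tuple[float, PruneResult]:
    """Bisect the threshold so the pruned set size lands closest to target_n.

    Prune size is non-decreasing in the threshold.  Returns the threshold and
    the corresponding prune result; among equally close thresholds the larger
    one wins.
    """
    n = len(S.row_ids)
    if not 1 <= target_n <= n:
        raise ValueError(f"target_n must lie in [1, {n}]")
    lo, hi = 1e-9, 1.0
    best: tuple[int, float, PruneResult] | None = None

    def consider(thr: float) -> PruneResult:
        nonlocal best
        res = prune(S, thr)
        key = (abs(res.n_after - target_n), thr)
        if best is None or key[0] < best[0] or (key[0] == best[0] and thr > best[1]):
            best = (key[0], thr, res)
        return res

    consider(hi)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        res = consider(mid)
        if res.n_after < target_n:
            lo = mid
        else:
            hi = mid
    assert best is not None
    return best[1], best[2]
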