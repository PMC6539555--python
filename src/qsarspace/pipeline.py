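"""Configuration-driven orchestration of the full representation comparison.

For every (dataset, approach, representation) cell the pipeline runs
curate -> split -> featurize/similarity -> rank or reduce -> feedforward CV
selection -> final SVR fit -> one-shot IVS evaluation, then aggregates the
per-cell IVS PVEs into a rank table and a Friedman test with post hoc letter
groups.  Datasets are either raw CSV tables of real molecules (RDKit
featurization) or synthetic specifications (bit-matrix re-encodings); a
failed cell is recorded and the run continues.
"""

from __future__ import annotations

import hashlib
import json
import sys
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curation import CuratedDataset, curate, read_records_csv, split
from .featurize import (DEFAULT_CONFIG, FeatureMatrix, enumerate_representations,
                        featurize, standardize_columns)
from .modeling import (MetricPCASpace, ModelEvaluation, SVMSpec,
                       SelectedFeatureSpace, SelectionCurve, VectorPCASpace,
                       default_k_schedule, evaluate, feedforward_select,
                       fit_final, rf_rank)
from .pruning import calibrate_threshold
from .similarity import SimilarityMatrix, load_external_similarity, similarity_matrix
from .stats import FriedmanResult, RankTable, friedman, posthoc_groups, rank_table
from .synth import SyntheticDataset, SyntheticSpec, emulate_representation, generate

__all__ = ["DatasetSource", "RunConfig", "RunResult", "run", "run_cell",
           "prepare_dataset", "load_config"]


@dataclass
class DatasetSource:
    name: str
    path: str | None = None                  # raw records CSV
    synthetic: SyntheticSpec | None = None
    graph_similarity_path: str | None = None


@dataclass
class PruneSettings:
    representation: str = "ecfp"   # similarity method used for removal
    target_fraction: float | None = None
    threshold: float | None = None


@dataclass
class RunConfig:
    datasets: list[DatasetSource]
    representations: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CONFIG.items()})
    seed: int = 17
    ivs_fraction: float = 0.2
    cv_folds: int = 5
    k_max: int | None = 100
    k_dense: int = 30
    k_step: int = 5
    alpha: float = 0.05
    refit_per_fold: bool = True
    rf_trees: int = 500
    rf_repeats: int = 5
    svm: SVMSpec = field(default_factory=SVMSpec)
    prune: PruneSettings | None = None
    output_dir: str | None = None


@dataclass
class RunResult:
    evaluations: pd.DataFrame
    curves: dict[tuple[str, str, str], SelectionCurve]
    ranks: RankTable | None
    friedman: FriedmanResult | None
    manifest: dict
    errors: list[dict]

    @property
    def ok(self) -> bool:
        return not self.errors


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    datasets = []
    for entry in raw.get("datasets", []):
        synth = entry.get("synthetic")
        datasets.append(DatasetSource(
            name=entry["name"], path=entry.get("path"),
            synthetic=SyntheticSpec(**synth) if synth is not None else None,
            graph_similarity_path=entry.get("graph_similarity_path")))
    prune_raw = raw.get("prune")
    kwargs = {k: raw[k] for k in ("seed", "ivs_fraction", "cv_folds", "k_max",
                                  "k_dense", "k_step", "alpha", "refit_per_fold",
                                  "rf_trees", "rf_repeats", "output_dir")
              if k in raw}
    return RunConfig(datasets=datasets,
                     representations=raw.get("representations",
                                             {k: list(v) for k, v in
                                              DEFAULT_CONFIG.items()}),
                     svm=SVMSpec(**raw.get("svm", {})),
                     prune=PruneSettings(**prune_raw) if prune_raw else None,
                     **kwargs)


def prepare_dataset(source: DatasetSource, config: RunConfig,
                    ) -> tuple[CuratedDataset, SyntheticDataset | None]:
    """Load or generate, curate, optionally prune, and split one dataset."""
    if (source.path is None) == (source.synthetic is None):
        raise ValueError(f"dataset {source.name}: give exactly one of path/synthetic")
    sdata = None
    if source.synthetic is not None:
        sdata = generate(source.synthetic)
        raw = sdata.records
    else:
        raw = read_records_csv(source.path)
    dataset = curate(raw)
    if config.prune is not None:
        dataset = _prune_dataset(dataset, source, sdata, config)
    return split(dataset, config.ivs_fraction, config.seed), sdata


def _prune_dataset(dataset: CuratedDataset, source: DatasetSource,
                   sdata: SyntheticDataset | None, config: RunConfig,
                   ) -> CuratedDataset:
    from .pruning import prune as prune_op
    rep = config.prune.representation
    S = _similarity_source(dataset, dataset.mol_ids, rep, source, sdata)
    if isinstance(S, FeatureMatrix):
        S = similarity_matrix(S.rows(dataset.mol_ids))
    if config.prune.threshold is not None:
        result = prune_op(S, config.prune.threshold)
    else:
        frac = config.prune.target_fraction or 1.0 / 3.0
        target = max(10, int(round(frac * len(dataset.records))))
        _, result = calibrate_threshold(S, target)
    keep = set(result.kept_ids)
    idx = [i for i, r in enumerate(dataset.records) if r.mol_id in keep]
    log = dataset.provenance_log + [
        {"action": "prune", "method": result.method,
         "threshold": result.threshold, "n_before": result.n_before,
         "n_after": result.n_after}]
    return CuratedDataset(records=[dataset.records[i] for i in idx],
                          spki=dataset.spki[idx], provenance_log=log)


def _similarity_source(dataset: CuratedDataset, train_ids: list[str], rep: str,
                       source: DatasetSource, sdata: SyntheticDataset | None):
    """Fingerprint matrix or square similarity backing a metric-space cell."""
    if rep == "graph":
        if sdata is not None:
            return sdata.graph_similarity(dataset.mol_ids)
        if source.graph_similarity_path is None:
            raise ValueError(
                f"dataset {source.name}: graph similarity requires a "
                "precomputed matrix (graph_similarity_path)")
        return load_external_similarity(source.graph_similarity_path,
                                        dataset.mol_ids)
    return _feature_matrix(dataset, rep, sdata)


def _feature_matrix(dataset: CuratedDataset, rep: str,
                    sdata: SyntheticDataset | None) -> FeatureMatrix:
    if sdata is not None:
        return emulate_representation(sdata.bit_matrix(dataset.mol_ids), rep)
    return featurize(dataset, rep)


def run_cell(dataset: CuratedDataset, approach: str, representation: str,
             config: RunConfig, source: DatasetSource,
             sdata: SyntheticDataset | None,
             ) -> tuple[ModelEvaluation, SelectionCurve]:
    """Train and evaluate one (dataset, approach, representation) model."""
    train_ids, ivs_ids = dataset.train_ids, dataset.ivs_ids
    tmask, imask = dataset.train_mask, dataset.ivs_mask
    y_train, y_ivs = dataset.spki[tmask], dataset.spki[imask]
    seed = config.seed

    if approach == "metric_pca":
        src = _similarity_source(dataset, train_ids, representation, source, sdata)
        space = MetricPCASpace(src, train_ids,
                               refit_per_fold=config.refit_per_fold)
        query = ivs_ids
    else:
        fm = _feature_matrix(dataset, representation, sdata)
        fm = fm.rows(dataset.mol_ids)
        if representation == "descriptors":
            fm = standardize_columns(fm, tmask)
        X = fm.matrix
        if approach == "vector_pca":
            space = VectorPCASpace(X[tmask], refit_per_fold=config.refit_per_fold)
        elif approach == "vector_fs":
            ranked = rf_rank(X[tmask], y_train, seed=seed,
                             n_estimators=config.rf_trees,
                             n_repeats=config.rf_repeats)
            space = SelectedFeatureSpace(X[tmask], ranked.order)
        else:
            raise ValueError(f"unknown approach {approach!r}")
        query = X[imask]

    k_cap = space.k_cap if config.k_max is None else min(space.k_cap, config.k_max)
    schedule = default_k_schedule(k_cap, config.k_dense, config.k_step)
    curve = feedforward_select(space, y_train, schedule, folds=config.cv_folds,
                               seed=seed, model_spec=config.svm)
    model = fit_final(space, y_train, curve.chosen_k, model_spec=config.svm)
    ivs_pve, ivs_rmse = evaluate(y_ivs, model.predict(query))
    cv_pve = float(curve.mean_cv_pve[curve.k_values.index(curve.chosen_k)])
    return (ModelEvaluation(dataset="", representation=representation,
                            approach=approach, chosen_k=curve.chosen_k,
                            cv_pve=cv_pve, ivs_pve=ivs_pve, ivs_rmse=ivs_rmse),
            curve)


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig, log=sys.stderr) -> RunResult:
    """Execute the full grid, aggregate ranks, and write results if asked."""
    pairs = enumerate_representations(config.representations)
    rows, curves, errors = [], {}, []
    for source in config.datasets:
        try:
            dataset, sdata = prepare_dataset(source, config)
        except Exception as exc:
            errors.append({"dataset": source.name, "stage": "prepare",
                           "error": repr(exc)})
            print(f"[{source.name}] preparation failed: {exc}", file=log)
            continue
        for approach, rep in pairs:
            try:
                ev, curve = run_cell(dataset, approach, rep, config, source, sdata)
                ev.dataset = source.name
                rows.append(ev)
                curves[(source.name, approach, rep)] = curve
                print(f"[{source.name}] {approach}/{rep}: k={ev.chosen_k} "
                      f"ivs_pve={ev.ivs_pve:.3f} rmse={ev.ivs_rmse:.3f}",
                      file=log)
            except Exception as exc:
                errors.append({"dataset": source.name, "approach": approach,
                               "representation": rep, "error": repr(exc),
                               "traceback": traceback.format_exc()})
                print(f"[{source.name}] {approach}/{rep} FAILED: {exc}", file=log)

    evaluations = pd.DataFrame([vars(e) for e in rows])
    ranks = fr = None
    if not evaluations.empty:
        wide = evaluations.pivot_table(index="dataset",
                                       columns=["approach", "representation"],
                                       values="ivs_pve")
        wide.columns = [f"{a}:{r}" for a, r in wide.columns]
        if wide.shape[0] >= 2 and wide.shape[1] >= 2 and not wide.isna().any().any():
            ranks = rank_table(wide)
            fr = friedman(ranks)
            posthoc_groups(fr, ranks, alpha=config.alpha)

    manifest = {
        "qsarspace_version": __version__,
        "seed": config.seed,
        "cv_folds": config.cv_folds,
        "ivs_fraction": config.ivs_fraction,
        "n_cells": len(pairs) * len(config.datasets),
        "n_completed": len(rows),
        "datasets": [
            {"name": s.name,
             "path": s.path,
             "sha256": _file_sha256(s.path) if s.path else None,
             "synthetic": asdict(s.synthetic) if s.synthetic else None}
            for s in config.datasets],
        "versions": _library_versions(),
    }
    result = RunResult(evaluations=evaluations, curves=curves, ranks=ranks,
                       friedman=fr, manifest=manifest, errors=errors)
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _library_versions() -> dict[str, str]:
    import rdkit
    import scipy
    import sklearn
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__,
            "rdkit": rdkit.__version__}


def _write_outputs(result: RunResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.evaluations.to_csv(out / "evaluations.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    if result.errors:
        (out / "errors.json").write_text(json.dumps(result.errors, indent=1))
    curves_dir = out / "curves"
    curves_dir.mkdir(exist_ok=True)
    for (ds, app, rep), curve in result.curves.items():
        pd.DataFrame({"k": curve.k_values, "mean_cv_pve": curve.mean_cv_pve,
                      "mean_cv_rmse": curve.mean_cv_rmse}).to_csv(
            curves_dir / f"{ds}__{app}__{rep}.csv", index=False)
    if result.friedman is not None:
        fr = result.friedman
        (out / "friedman.json").write_text(json.dumps(
            {"statistic": fr.statistic, "df": fr.df, "p_value": fr.p_value,
             "rank_sums": fr.rank_sums.to_dict(), "groups": fr.groups},
            indent=1))
        result.ranks.ranks.to_csv(out / "ranks.csv")


def report_text(result: RunResult) -> str:
    """Plain-text comparison report: median ranks, IQRs and letter groups."""
    lines = ["Representation comparison report", "=" * 32]
    if result.ranks is None or result.friedman is None:
        lines.append("Not enough complete cells for a cross-dataset comparison.")
        return "\n".join(lines)
    fr = result.friedman
    lines.append(f"Friedman chi-squared = {fr.statistic:.2f}, df = {fr.df}, "
                 f"p = {fr.p_value:.3g}")
    lines.append("")
    lines.append(f"{'treatment':<28}{'rank_sum':>9}{'median':>8}{'IQR':>12}  groups")
    R = result.ranks.ranks
    for name in fr.rank_sums.sort_values().index:
        med = R[name].median()
        q1, q3 = R[name].quantile([0.25, 0.75])
        grp = (fr.groups or {}).get(name, "")
        lines.append(f"{name:<28}{fr.rank_sums[name]:>9.1f}{med:>8.1f}"
                     f"{f'[{q1:.1f},{q3:.1f}]':>12}  {grp}")
    return "\n".join(lines)
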