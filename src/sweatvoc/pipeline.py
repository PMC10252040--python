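"""End-to-end orchestration: log → split → rank → PCA → grid search → holdout
→ SHAP → probe relevance, with per-batch execution and provenance.

Because a GC-column replacement mid-study shifts the whole measurement space,
pooling column batches lets the batch dominate the leading principal
components and corrupts the class signal; the pipeline therefore refuses to
pool batches by default and analyzes each column's measurements separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset, RunConfig, ValidationError, validate_dataset
from .io import (
    log_run_header,
    read_library,
    read_measurement_table,
    read_run_config,
    setup_logging,
)
from .modeling import evaluate_holdout, grid_search, split_train_test
from .preprocess import (
    apply_scaler,
    fit_scaler,
    log_transform,
    mannwhitney_rank,
    pca_project,
    select_significant,
)
from .relevance import (
    jaccard,
    jaccard_curve,
    linear_shap,
    probe_relevance,
    relevance_report,
)


@dataclass
class BatchReport:
    """Stage outputs for one GC-column batch."""

    batch: str
    n_measurements: int
    ranked: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_explained: tuple[float, ...]
    grid_surface: pd.DataFrame
    best_C: float
    best_N: int
    best_cv_score: float
    f1: float
    sensitivity: float | None
    specificity: float | None
    coefficients: pd.DataFrame
    probe_cdf: pd.DataFrame
    probe_min_rank: int
    probe_max_rank: int
    retained: dict[float, tuple[str, ...]]
    relevance_table: pd.DataFrame
    shap_ranking: tuple[str, ...]


@dataclass
class RunReport:
    """Full-run provenance: config hash, seed and per-batch outputs."""

    seed: int
    config_hash: str
    batches: dict[str, BatchReport] = field(default_factory=dict)

    def metrics(self) -> dict:
        return {
            batch: {
                "best_C": rep.best_C,
                "best_N": rep.best_N,
                "best_cv_score": rep.best_cv_score,
                "f1_weighted": rep.f1,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "retained_counts": {
                    str(d): len(v) for d, v in sorted(rep.retained.items())
                },
                "probe_min_rank": rep.probe_min_rank,
                "probe_max_rank": rep.probe_max_rank,
            }
            for batch, rep in self.batches.items()
        }


def run_pipeline(
    dataset: Dataset | None = None,
    config: RunConfig | None = None,
    measurements_path=None,
    library_path=None,
    config_path=None,
    out_dir=None,
) -> RunReport:
    """Execute the full workflow on a dataset (or on CSV inputs).

    Validates inputs up front, then per batch: log-transform, group-aware
    train/test split, Mann-Whitney ranking, PCA artifacts, (C, N) grid search
    with SMOTE inside each fold, holdout evaluation, linear SHAP on the final
    fit, and probe-variable relevance at the configured δ grid.
    """
    if config is None:
        config = read_run_config(config_path) if config_path else RunConfig()
    if dataset is None:
        if measurements_path is None or library_path is None:
            raise ValidationError("provide a dataset or measurement+library paths")
        library = read_library(library_path)
        dataset = read_measurement_table(measurements_path, library)
    config.validate(library_size=dataset.library.size)
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    logger = setup_logging(out / "run.log" if out else None)
    log_run_header(logger, config)

    report = RunReport(seed=config.seed, config_hash=config.config_hash())
    structure = validate_dataset(dataset, config.max_replicates)
    for flag in structure.flags:
        logger.info("structure: %s", flag)

    batches = sorted(dataset.meta["batch"].unique())
    if len(batches) > 1 and not config.pool_batches:
        logger.info("multiple column batches present; analyzing separately: %s", batches)
        batch_sets = {b: np.flatnonzero((dataset.meta["batch"] == b).to_numpy()) for b in batches}
    else:
        if len(batches) > 1:
            logger.info("pool_batches=True: pooling %s (batch confound not removed)", batches)
        batch_sets = {"+".join(batches): np.arange(dataset.n)}

    for batch, rows in batch_sets.items():
        logger.info("batch %s: %d measurements", batch, rows.size)
        report.batches[batch] = _run_batch(dataset, rows, config, logger, out, batch)

    if out:
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report.metrics(), fh, indent=2)
    return report


def _run_batch(dataset, rows, config, logger, out, batch) -> BatchReport:
    sub = dataset.select_rows(rows)
    if sub.meta["status"].nunique() < 2:
        raise ValidationError(f"batch {batch}: both statuses required")
    logged = log_transform(sub)
    train_rows, test_rows = split_train_test(
        logged, np.arange(logged.n), config.test_fraction, config.seed
    )
    logger.info(
        "batch %s: %d train rows, %d test rows (group-aware split)",
        batch, train_rows.size, test_rows.size,
    )

    # ranking + PCA artifacts from the learning rows only (leakage-safe default)
    ranked = mannwhitney_rank(logged, train_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        significant = select_significant(ranked, config.alpha)
    scaler = fit_scaler(logged, train_rows)
    standardized = apply_scaler(logged, scaler)
    if len(significant) >= 2:
        scores, explained = pca_project(standardized, significant, k=2)
        pca_frame = pd.DataFrame(
            {
                "subject_id": logged.meta["subject_id"],
                "status": logged.meta["status"],
                "pc1": scores[:, 0],
                "pc2": scores[:, 1],
            }
        )
    else:
        logger.info("batch %s: <2 significant descriptors, PCA skipped", batch)
        pca_frame, explained = pd.DataFrame(), ()

    n_grid = [n for n in config.n_grid if n <= dataset.library.size]
    grid = grid_search(
        logged,
        train_rows,
        config.c_grid,
        n_grid,
        scheme=config.cv_scheme,
        k=config.k_folds,
        seed=config.seed,
        smote_k=config.smote_k,
    )
    logger.info(
        "batch %s: grid best C=%g N=%d cv=%.3f (%d tied cells)",
        batch, grid.best_C, grid.best_N, grid.best_score, len(grid.tied),
    )
    holdout = evaluate_holdout(
        logged, train_rows, test_rows, grid.best_C, grid.best_N,
        seed=config.seed, smote_k=config.smote_k,
    )
    logger.info(
        "batch %s: holdout f1=%.3f sensitivity=%s specificity=%s",
        batch, holdout.f1, holdout.sensitivity, holdout.specificity,
    )

    # SHAP + probe relevance in the final model's standardized feature space
    idx = logged.library.indices(holdout.subset)
    X_train = standardized.areas[train_rows][:, idx]
    shap = linear_shap(holdout.fit, X_train, X_train)
    probe = probe_relevance(
        X_train,
        logged.labels()[train_rows],
        C=grid.best_C,
        R=config.probe_realizations,
        seed=config.seed,
        deltas=config.delta_grid,
        descriptor_ids=holdout.subset,
    )
    logger.info(
        "batch %s: probe ranks [%d, %d]; retained %s",
        batch, probe.min_rank, probe.max_rank,
        {d: len(v) for d, v in sorted(probe.retained.items())},
    )
    table = relevance_report(
        probe, shap, logged, rows=train_rows, delta=min(config.delta_grid)
    )

    surface = pd.DataFrame(
        [(c, n, s) for (c, n), s in sorted(grid.surface.items())],
        columns=["C", "N", "cv_score"],
    )
    coef = pd.DataFrame(
        {"descriptor_id": holdout.subset, "weight": holdout.fit.weights}
    )
    rep = BatchReport(
        batch=batch,
        n_measurements=int(np.asarray(rows).size),
        ranked=ranked.frame,
        pca_scores=pca_frame,
        pca_explained=tuple(float(e) for e in explained),
        grid_surface=surface,
        best_C=grid.best_C,
        best_N=grid.best_N,
        best_cv_score=grid.best_score,
        f1=holdout.f1,
        sensitivity=holdout.sensitivity,
        specificity=holdout.specificity,
        coefficients=coef,
        probe_cdf=pd.DataFrame(
            {
                "rank": np.arange(1, probe.n_features + 2),
                "count": probe.rank_counts,
                "cdf": probe.cdf,
            }
        ),
        probe_min_rank=probe.min_rank,
        probe_max_rank=probe.max_rank,
        retained=probe.retained,
        relevance_table=table,
        shap_ranking=tuple(shap.ranking()),
    )
    if out:
        prefix = out / f"batch_{batch}"
        rep.ranked.to_csv(f"{prefix}_ranked.csv", index=False)
        if not rep.pca_scores.empty:
            rep.pca_scores.to_csv(f"{prefix}_pca_scores.csv", index=False)
        rep.grid_surface.to_csv(f"{prefix}_grid_surface.csv", index=False)
        rep.coefficients.to_csv(f"{prefix}_coefficients.csv", index=False)
        rep.probe_cdf.to_csv(f"{prefix}_probe_cdf.csv", index=False)
        rep.relevance_table.to_csv(f"{prefix}_relevance.csv", index=False)
        for d, ids in rep.retained.items():
            pd.DataFrame({"descriptor_id": list(ids)}).to_csv(
                f"{prefix}_retained_delta{int(round(d * 100)):02d}.csv", index=False
            )
    return rep


def run_two_dataset_comparison(run1: RunReport, run2: RunReport) -> dict:
    """Jaccard similarity of retained sets (and ranking curves) of two runs.

    Batches and δ values are matched by name; a mismatch restricts the
    comparison to the intersection with a warning.
    """
    out: dict = {"per_delta": {}, "curves": {}}
    common_batches = sorted(set(run1.batches) & set(run2.batches))
    if not common_batches:
        b1 = next(iter(run1.batches.values()), None)
        b2 = next(iter(run2.batches.values()), None)
        if b1 is None or b2 is None:
            raise ValidationError("both runs must contain at least one batch report")
        pairs = [("*", b1, b2)]
    else:
        pairs = [(b, run1.batches[b], run2.batches[b]) for b in common_batches]
    for name, r1, r2 in pairs:
        if not r1.retained or not r2.retained:
            raise ValidationError("runs are missing retained sets")
        d1, d2 = set(r1.retained), set(r2.retained)
        if d1 != d2:
            warnings.warn(
                f"delta grids differ; comparing common deltas {sorted(d1 & d2)}",
                stacklevel=2,
            )
        per_delta = {
            d: jaccard(r1.retained[d], r2.retained[d]) for d in sorted(d1 & d2)
        }
        max_m = min(len(r1.shap_ranking), len(r2.shap_ranking))
        sizes = [m for m in range(5, max_m + 1, 5)] or [max_m]
        curve = jaccard_curve(r1.shap_ranking, r2.shap_ranking, sizes)
        out["per_delta"][name] = per_delta
        out["curves"][name] = curve
    return out
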