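"""End-to-end diagnostic pipeline: cohort -> cleaning -> scaling -> PCA ->
stratified split -> TSDPSO-tuned SVM -> test-set evaluation.

Artifacts (metrics JSON, ROC/PR CSVs, tuning convergence curve, run log)
are written to an output directory; every artifact embeds the seed and a
hash of the resolved configuration for provenance.  Default problem
sizes are desk-scale (a few hundred samples per class, a small tuning
swarm); all are configurable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import evaluation, preprocess, svm_objective, synthetic
from .optimizer import DelayPolicy, TractionConfig
from .swarm import SwarmConfig

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("tsdpso.pipeline")


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    # synthetic cohort (ignored when input_csv is given)
    input_csv: str | None = None
    n_per_class: int = 300
    delta: float = 3.0
    # preprocessing
    z_threshold: float = 3.0
    norm_range: tuple[float, float] = (-1.0, 1.0)
    pca_threshold: float = 0.95
    # split / cross-validation
    test_fraction: float = 0.2
    folds: int = 5
    # tuning swarm (desk-scale defaults)
    swarm_size: int = 8
    tune_iterations: int = 10
    label_col: str = "FRI"

    def config_hash(self) -> str:
        # Hash covers the scientific settings only, not where output lands.
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _age_bin(age: pd.Series) -> pd.Series:
    return pd.cut(age, bins=[-np.inf, 34, 65, np.inf], labels=[0, 1, 2]).astype(int)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the metrics payload."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    logger.info("seed=%d config_hash=%s", config.seed, config.config_hash())

    if config.input_csv is not None:
        raw = pd.read_csv(config.input_csv)
        logger.info("loaded %d rows from %s", len(raw), config.input_csv)
    else:
        spec = synthetic.CohortSpec(
            n_per_class=config.n_per_class, delta=config.delta, seed=config.seed
        )
        raw = synthetic.generate_cohort(spec)
        logger.info("generated cohort: %d rows, delta=%.2f", len(raw), config.delta)

    table, report = preprocess.clean_table(
        raw, z_threshold=config.z_threshold, label_col=config.label_col
    )
    logger.info(
        "cleaning: %d missing, %d duplicate, %d outlier rows dropped",
        report.rows_dropped_missing,
        report.rows_dropped_duplicate,
        report.rows_dropped_outlier,
    )
    if table.labels is None:
        raise preprocess.DataError(f"label column {config.label_col!r} not found")

    table, _ = preprocess.normalize_table(table, config.norm_range)
    proj = preprocess.fit_pca(table)
    m = preprocess.select_components(proj, config.pca_threshold)
    reduced = preprocess.project(proj, table, m)
    logger.info("PCA: retained %d of %d components", m, proj.n_features)

    y = reduced.labels.to_numpy().astype(int)
    x = reduced.features.to_numpy()
    strata = y
    if "age" in table.features.columns:
        strata = y * 10 + _age_bin(table.features["age"]).to_numpy()
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=config.test_fraction,
        stratify=strata,
        random_state=config.seed,
    )

    swarm = SwarmConfig(
        swarm_size=config.swarm_size,
        max_iterations=config.tune_iterations,
        seed=config.seed,
    )
    best, result, model = svm_objective.tune_svm_tsdpso(
        x[train_idx],
        y[train_idx],
        swarm_config=swarm,
        cv=svm_objective.CVSpec(folds=config.folds, seed=config.seed),
        delay_policy=DelayPolicy(),
        traction=TractionConfig(),
    )
    logger.info(
        "tuned C=%.4g gamma=%.4g cv_error=%.4f", best.C, best.gamma, result.gbest_fitness
    )

    scores = model.decision_function(x[test_idx])
    predicted = model.predict(x[test_idx])
    cm = evaluation.confusion_from_predictions(y[test_idx], predicted)
    metrics = evaluation.metrics_from_confusion(cm)
    roc, auc = evaluation.roc_auc(y[test_idx], scores)
    pr = evaluation.pr_curve(y[test_idx], scores)

    payload = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "cleaning": dataclasses.asdict(report),
        "pca_components": m,
        "hyperparameters": {"C": best.C, "gamma": best.gamma},
        "cv_error": result.gbest_fitness,
        "confusion": dataclasses.asdict(cm),
        "metrics": dataclasses.asdict(metrics),
        "auc": auc,
    }
    (out / "metrics.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    pd.DataFrame({"fpr": roc.x, "tpr": roc.y}).to_csv(out / "roc.csv", index=False)
    pd.DataFrame({"recall": pr.x, "precision": pr.y}).to_csv(out / "pr.csv", index=False)
    pd.DataFrame(
        {
            "iteration": np.arange(len(result.convergence_curve)),
            "best_fitness": result.convergence_curve,
        }
    ).to_csv(out / "curve.csv", index=False)
    logger.info("test AUC=%.4f accuracy=%.2f%%", auc, metrics.accuracy)
    return payload
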