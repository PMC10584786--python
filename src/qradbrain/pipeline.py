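"""End-to-end orchestration of the classification pipeline.

Stage order mirrors the method: stratified split -> standardization (fitted
on training rows) -> SMOTE + undersampling of the training rows ->
Spearman correlation pruning (|rho| > 0.8) -> L1-hinge linear selection ->
MI top-m ranking -> QUBO selection of k features -> variational quantum
classifier -> Kernel-SHAP attribution of the test scores -> metrics.
Every stage is seeded; rerunning a config reproduces all artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import classification_report
from .preprocessing import (
    MutualInfoRanker,
    L1MarginSelector,
    SmoteUnderSampler,
    SpearmanPruner,
    standardize,
    stratified_split,
)
from .quantum import VariationalQuantumClassifier
from .qubo import QuboFeatureSelector
from .shapley import KernelShapExplainer, shap_summary
from .synthetic import SyntheticTableSpec, gen_feature_table
from .tables import FeatureTable

__all__ = ["RunConfig", "run_pipeline", "PipelineStageError"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serializable configuration of a full run (version-stamped)."""

    seed: int = 0
    table_csv: str | None = None  # input table; None -> synthetic
    table_spec: SyntheticTableSpec = field(
        default_factory=lambda: SyntheticTableSpec(n_redundant=3))
    split_fraction: float = 0.7
    smote_k_neighbors: int = 5
    smote_target_ratio: float = 1.0
    prune_threshold: float = 0.8
    linear_penalty: float = 0.01
    mi_top_m: int = 17
    qubo_k: int = 10
    qubo_bins: int = 4
    qubo_alpha: float | str = "auto"
    qubo_reads: int = 5000
    qnn_layers: int = 6
    qnn_lr: float = 0.01
    qnn_epochs: int = 100
    qnn_batch_size: int | None = None
    shap_background: int = 50
    shap_coalitions: int = 2048
    shap_max_samples: int = 64  # explain at most this many test rows
    version: str = "1"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "table_spec" in d and isinstance(d["table_spec"], dict):
            d["table_spec"] = SyntheticTableSpec(**d["table_spec"])
        return cls(**d)


def _log(handle, stage: str, **payload):
    handle.write(json.dumps({"stage": stage, "time": time.time(), **payload},
                            default=str) + "\n")
    handle.flush()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; write artifacts into ``out_dir``; return the
    report dict (selected features, train/test metrics, metric gap)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    log = open(out / "log.jsonl", "w")

    def _stage(name, fn, **kw):
        try:
            res = fn()
            _log(log, name, status="ok", **kw)
            return res
        except Exception as exc:  # surface the failing stage by name
            _log(log, name, status="error", error=str(exc))
            log.close()
            raise PipelineStageError(name, exc) from exc

    # --- data
    def _load():
        if config.table_csv:
            return FeatureTable.from_csv(config.table_csv)
        spec_dict = asdict(config.table_spec)
        spec_dict["seed"] = config.seed
        return gen_feature_table(SyntheticTableSpec(**spec_dict))
    table = _stage("load_table", _load)
    table.to_csv(out / "table.csv")

    train_idx, test_idx = _stage(
        "split",
        lambda: stratified_split(table.labels, config.split_fraction,
                                 seed=config.seed),
        fraction=config.split_fraction)

    def _std():
        vals, keep, mean, std = standardize(table.values, train_idx)
        return table.select(keep.tolist()), vals
    table_k, values = _stage("standardize", _std)

    Xtr, ytr = values[train_idx], table_k.labels[train_idx]
    Xte, yte = values[test_idx], table_k.labels[test_idx]

    def _resample():
        return SmoteUnderSampler(
            k_neighbors=config.smote_k_neighbors,
            target_ratio=config.smote_target_ratio,
            random_state=config.seed,
        ).fit_resample(Xtr, ytr)
    Xtr_b, ytr_b = _stage("resample", _resample,
                          before={"n": len(ytr)})

    pruner = SpearmanPruner(threshold=config.prune_threshold,
                            bins=config.qubo_bins)
    _stage("prune", lambda: pruner.fit(Xtr_b, ytr_b))
    cols_pruned = np.flatnonzero(pruner.support_)

    linear = L1MarginSelector(penalty=config.linear_penalty)
    _stage("linear_select",
           lambda: linear.fit(Xtr_b[:, cols_pruned], ytr_b))
    cols_linear = cols_pruned[linear.support_]
    if len(cols_linear) < config.qubo_k:
        # keep the largest-|coefficient| candidates alive when the penalty
        # over-sparsifies below the QUBO cardinality
        order = np.argsort(-np.abs(linear.coef_))[:config.qubo_k]
        cols_linear = cols_pruned[np.sort(order)]

    ranker = MutualInfoRanker(top_m=config.mi_top_m, bins=config.qubo_bins)
    _stage("mi_rank", lambda: ranker.fit(Xtr_b[:, cols_linear], ytr_b))
    cols_mi = cols_linear[ranker.support_]

    selector = QuboFeatureSelector(
        k=config.qubo_k, bins=config.qubo_bins, alpha=config.qubo_alpha,
        reads=config.qubo_reads, random_state=config.seed)
    _stage("qubo_select", lambda: selector.fit(Xtr_b[:, cols_mi], ytr_b))
    cols_final = cols_mi[selector.support_]
    selected_names = [table_k.names[int(c)] for c in cols_final]
    (out / "selected_features.json").write_text(json.dumps({
        "pruned_to": [table_k.names[int(c)] for c in cols_pruned],
        "linear_kept": [table_k.names[int(c)] for c in cols_linear],
        "mi_top": [table_k.names[int(c)] for c in cols_mi],
        "selected": selected_names,
        "qubo_energy": selector.solution_.energy,
        "solver": selector.solution_.solver,
    }, indent=2))

    clf = VariationalQuantumClassifier(
        n_layers=config.qnn_layers, lr=config.qnn_lr,
        epochs=config.qnn_epochs, batch_size=config.qnn_batch_size,
        random_state=config.seed)
    _stage("train_qnn",
           lambda: clf.fit(Xtr_b[:, cols_final], ytr_b))
    clf.history_.to_csv(out / "training_history.csv", index=False)
    (out / "qnn_params.json").write_text(json.dumps(
        clf.params_.to_dict(), indent=2))

    scores_tr = clf.decision_function(Xtr_b[:, cols_final])
    scores_te = clf.decision_function(Xte[:, cols_final])
    rep_tr = _stage("metrics_train",
                    lambda: classification_report(ytr_b, scores_tr))
    rep_te = _stage("metrics_test",
                    lambda: classification_report(yte, scores_te))

    def _explain():
        model = lambda Z: clf.decision_function(Z)
        explainer = KernelShapExplainer(
            model, Xtr_b[:, cols_final],
            n_coalitions=config.shap_coalitions,
            max_background=config.shap_background, seed=config.seed)
        m = min(config.shap_max_samples, len(test_idx))
        atts = explainer.explain(Xte[:m, cols_final])
        pred = np.where(scores_te[:m] < 0, -1, 1)
        summaries = shap_summary(atts, Xte[:m, cols_final], yte[:m], pred,
                                 feature_names=selected_names)
        rows = pd.DataFrame(
            np.vstack([a.phi for a in atts]), columns=selected_names)
        rows["base_value"] = [a.base_value for a in atts]
        rows["fx"] = [a.fx for a in atts]
        rows.to_csv(out / "attributions.csv", index=False)
        for name, df in summaries.items():
            df.to_csv(out / f"shap_{name}.csv", index=False)
        return summaries
    summaries = _stage("explain", _explain)

    report = {
        "selected_features": selected_names,
        "train": rep_tr.to_dict(),
        "test": rep_te.to_dict(),
        "gap": {
            "bacc": rep_tr.bacc - rep_te.bacc,
            "roc_auc": rep_tr.roc_auc - rep_te.roc_auc,
        },
        "top_feature_by_mean_abs_shap":
            summaries["importance"]["feature"].iloc[0],
    }
    if table.relevant is not None:
        relevant = set(table.relevant)
        hits = relevant & set(selected_names)
        report["planted_recovery"] = len(hits) / max(len(relevant), 1)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    _log(log, "done", report=report)
    log.close()
    return report
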