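"""Cross-validated multimodal experiment orchestration.

For each endpoint: patients are split into ``n_folds`` random folds; per fold,
every tabular modality is preprocessed (fit on the training fold only) and
modelled with univariate screening plus forward selection, and the bag
modality (if present) is trained with the deep MIL Cox model; test-fold risks
are predicted, fused with validation-performance weights (computed from
training-side validation only, per fold) and with uniform weights; pooled
test predictions across folds are evaluated with the full metric suite.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort_io import (MultimodalBundle, RiskVector, SurvivalOutcome,
                        write_risk_vectors)
from .cox_forward_selection import (FittedCoxModel, forward_select,
                                    make_subpartitions, predict_risk,
                                    univariate_screen)
from .deep_cph import (DeepRiskModel, MILNetConfig, TrainConfig,
                       predict_bag_risk, train_deep_cph)
from .ensemble_fusion import compute_weights, fuse, fuse_uniform
from .survival_metrics import (bootstrap_cindex, label_at_horizon,
                               auroc_delong, median_split)
from .tabular_preprocess import apply_preprocess, fit_preprocess

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    endpoints: tuple[str, ...] = ("OS", "DFS")
    n_folds: int = 5
    seed: int = 0
    categorical: dict[str, list[str]] = field(default_factory=dict)  # per modality
    max_features: int = 20
    n_subpartitions: int = 10
    subpartition_val_fraction: float = 0.2
    l2: float = 1e-6
    stratify_folds: bool = False
    # deep model settings (used when the bundle carries bags)
    deep_proj_dim: int = 256
    deep_heads: int = 8
    deep_landmarks: int = 256
    deep_epochs: int = 100
    deep_lr: float = 1e-3
    deep_accumulation: int = 32
    deep_dropout: float = 0.25
    bootstrap_B: int = 1000
    auroc_horizons_months: tuple[float, ...] = (12.0, 36.0, 60.0)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


def assign_folds(ids: list[str], n_folds: int = 5, seed: int = 0,
                 events: np.ndarray | None = None) -> dict[str, int]:
    """Random permutation chunked into near-equal folds (sizes differ by at
    most 1); optionally stratified by event status."""
    if len(ids) < n_folds:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    if events is not None:
        events = np.asarray(events).astype(bool)
        groups = [np.asarray(ids)[events], np.asarray(ids)[~events]]
    else:
        groups = [np.asarray(ids)]
    offset = 0
    for grp in groups:
        perm = rng.permutation(grp)
        for i, pid in enumerate(perm):
            assignment[str(pid)] = (i + offset) % n_folds
        offset += len(grp)
    return assignment


@dataclass
class FoldModels:
    """Everything fitted on one training fold for one endpoint."""

    tabular: dict[str, tuple[object, FittedCoxModel]] = field(default_factory=dict)
    deep: DeepRiskModel | None = None
    p_val: dict[str, float] = field(default_factory=dict)


def fit_fold(bundle: MultimodalBundle, endpoint: str, train_ids: list[str],
             cfg: ExperimentConfig, fold_seed: int) -> FoldModels:
    """Fit every modality on a training fold; no test-fold data enters."""
    out_train = bundle.outcomes[endpoint].subset(train_ids)
    models = FoldModels()
    for name, table in bundle.tables.items():
        t_train = table.subset(train_ids)
        proc, spec = fit_preprocess(t_train, cfg.categorical.get(name),
                                    rho_max=0.8, ddof=1)
        parts = make_subpartitions(train_ids, cfg.n_subpartitions,
                                   cfg.subpartition_val_fraction, seed=fold_seed)
        screen = univariate_screen(proc, out_train, parts, l2=cfg.l2)
        model, trace = forward_select(proc, out_train, screen, parts,
                                      cfg.max_features, l2=cfg.l2)
        models.tabular[name] = (spec, model)
        models.p_val[name] = trace.p_val
        logger.info("fold seed %d %s/%s: selected %s (p_val=%.3f)",
                    fold_seed, endpoint, name, model.feature_names, trace.p_val)
    if bundle.bags:
        d = next(iter(bundle.bags.values())).dim
        net_cfg = MILNetConfig(d, cfg.deep_proj_dim, cfg.deep_dropout,
                               cfg.deep_heads, cfg.deep_landmarks)
        train_cfg = TrainConfig(lr=cfg.deep_lr, epochs=cfg.deep_epochs,
                                accumulation_size=cfg.deep_accumulation,
                                seed=fold_seed)
        train_bags = {p: bundle.bags[p] for p in train_ids}
        models.deep = train_deep_cph(train_bags, out_train, net_cfg, train_cfg)
        # validation performance = C-index on the model's internal val split
        models.p_val["wsi"] = max(models.deep.history["val_cindex"][0], 1e-6)
    return models


def predict_fold(bundle: MultimodalBundle, endpoint: str, test_ids: list[str],
                 models: FoldModels) -> dict[str, RiskVector]:
    risks: dict[str, RiskVector] = {}
    for name, (spec, model) in models.tabular.items():
        t_test = apply_preprocess(bundle.tables[name].subset(test_ids), spec)
        risks[name] = predict_risk(model, t_test, endpoint=endpoint, modality=name)
    if models.deep is not None:
        test_bags = {p: bundle.bags[p] for p in test_ids}
        rv = predict_bag_risk(models.deep, test_bags, endpoint=endpoint)
        order = {p: i for i, p in enumerate(rv.patient_ids)}
        idx = [order[p] for p in test_ids]
        risks["wsi"] = RiskVector(list(test_ids), rv.scores[idx], "wsi", endpoint)
    return risks


def _evaluate(risks: RiskVector, outcome: SurvivalOutcome, cfg: ExperimentConfig,
              seed: int) -> dict:
    out = outcome.subset(risks.patient_ids)
    res = bootstrap_cindex(risks.scores, out.time, out.event, B=cfg.bootstrap_B, seed=seed)
    entry = {"cindex": res.point, "cindex_ci": list(res.ci),
             "n_comparable_pairs": res.n_comparable_pairs}
    strat = median_split(risks.scores, out.time, out.event)
    entry["logrank_chi2"] = strat.chi2
    entry["logrank_p"] = strat.p_value
    entry["auroc"] = {}
    for t in cfg.auroc_horizons_months:
        labels = label_at_horizon(out.time, out.event, t)
        try:
            a = auroc_delong(risks.scores, labels)
            entry["auroc"][f"{t:g}mo"] = {"auc": a.auc, "ci": list(a.ci),
                                          "n_pos": a.n_pos, "n_neg": a.n_neg}
        except ValueError as exc:
            entry["auroc"][f"{t:g}mo"] = {"error": str(exc)}
    return entry


def run_experiment(bundle: MultimodalBundle, cfg: ExperimentConfig,
                   outdir: str | Path | None = None) -> dict:
    """Full cross-validated experiment; returns (and optionally writes) the report."""
    report: dict = {"config": dataclasses.asdict(cfg), "version": __version__,
                    "n_patients": len(bundle), "endpoints": {}}
    all_risk_rows: list[RiskVector] = []
    for endpoint in cfg.endpoints:
        outcome = bundle.outcomes[endpoint]
        folds = assign_folds(
            bundle.patients, cfg.n_folds, cfg.seed,
            events=outcome.event if cfg.stratify_folds else None)
        pooled: dict[str, list[RiskVector]] = {}
        fold_weights = []
        for k in range(cfg.n_folds):
            train_ids = [p for p in bundle.patients if folds[p] != k]
            test_ids = [p for p in bundle.patients if folds[p] == k]
            fold_seed = cfg.seed * 1000 + k
            models = fit_fold(bundle, endpoint, train_ids, cfg, fold_seed)
            risks = predict_fold(bundle, endpoint, test_ids, models)
            weights = compute_weights(models.p_val, endpoint)
            fused = fuse(risks, weights)
            uniform = fuse_uniform(risks, endpoint)
            fold_weights.append(weights.weights)
            for name, rv in {**risks, "fused": fused.fused,
                             "fused_uniform": uniform.fused}.items():
                pooled.setdefault(name, []).append(rv)
        ep_report: dict = {"fold_weights": fold_weights, "models": {}}
        for name, pieces in pooled.items():
            ids = [p for rv in pieces for p in rv.patient_ids]
            scores = np.concatenate([rv.scores for rv in pieces])
            order = np.argsort(ids)
            rv = RiskVector([ids[i] for i in order], scores[order], name, endpoint)
            all_risk_rows.append(rv)
            ep_report["models"][name] = _evaluate(rv, outcome, cfg, seed=cfg.seed)
        report["endpoints"][endpoint] = ep_report
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        write_risk_vectors(all_risk_rows, outdir / "risks.csv")
    return report
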