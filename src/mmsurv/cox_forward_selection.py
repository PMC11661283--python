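"""Cox model construction by univariate screening and iterative forward selection.

The training cohort is split 10 times into random sub-training / sub-validation
partitions. Each candidate feature (or feature set) is scored by fitting a Cox
proportional-hazards model on every sub-training split and averaging Harrell's
C-index on the matching sub-validation splits. Screening keeps features whose
mean validation C-index exceeds 0.5 and ranks them; forward selection starts
from the top-ranked feature and greedily adds the candidate with the best mean
validation C-index, accepting only strict improvements, up to ``max_features``.
The final model is refit on the full training cohort with the selected set;
the best mean validation C-index is retained as the modality's validation
performance p_val for ensemble weighting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._coxnewton import cox_newton
from .cohort_io import FeatureTable, RiskVector, SurvivalOutcome
from .survival_metrics import harrell_cindex

logger = logging.getLogger(__name__)


@dataclass
class SubPartitionSet:
    """Random sub-train / sub-validation splits of a training cohort."""

    partitions: list[tuple[list[str], list[str]]]
    val_fraction: float
    seed: int

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)


def make_subpartitions(ids: list[str], n: int = 10, val_fraction: float = 0.2,
                       seed: int = 0) -> SubPartitionSet:
    """n independent random splits; each validation part holds
    round(val_fraction * len(ids)) patients, at least one per side."""
    if n < 1 or not 0 < val_fraction < 1:
        raise ValueError("need n >= 1 and 0 < val_fraction < 1")
    if len(ids) < 5:
        raise ValueError("training cohort too small to sub-partition (need >= 5)")
    rng = np.random.default_rng(seed)
    ids = list(ids)
    n_val = min(max(1, round(val_fraction * len(ids))), len(ids) - 1)
    parts = []
    for _ in range(n):
        perm = rng.permutation(len(ids))
        val = [ids[i] for i in perm[:n_val]]
        train = [ids[i] for i in perm[n_val:]]
        parts.append((train, val))
    return SubPartitionSet(parts, val_fraction, seed)


@dataclass
class FittedCoxModel:
    """Linear Cox risk model: risk(x) = sum_j beta_j * x_j."""

    feature_names: list[str]
    beta: np.ndarray
    converged: bool = True
    ties: str = "efron"
    l2: float = 1e-6

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("coefficients must be finite")

    def to_json(self, path: str | Path | None = None) -> str:
        d = {"feature_names": self.feature_names, "beta": self.beta.tolist(),
             "converged": self.converged, "ties": self.ties, "l2": self.l2}
        s = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedCoxModel":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        return cls(**json.loads(text))


@dataclass
class UnivariateScreenResult:
    table: pd.DataFrame  # feature, mean_cindex, passed, rank (NaN if failed)

    @property
    def passed(self) -> list[str]:
        t = self.table[self.table["passed"]]
        return t.sort_values("rank")["feature"].tolist()


@dataclass
class ForwardSelectionTrace:
    steps: list[dict] = field(default_factory=list)  # candidate, mean_cindex, accepted
    selected: list[str] = field(default_factory=list)
    p_val: float = float("nan")
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s


def _aligned(table: FeatureTable, outcome: SurvivalOutcome):
    df = table.data
    out = outcome.subset(table.patient_ids)
    return df, out.time, out.event


def _mean_val_cindex(df: pd.DataFrame, time: np.ndarray, event: np.ndarray,
                     pos: dict[str, int], features: list[str],
                     parts: SubPartitionSet, l2: float) -> float:
    """Mean sub-validation C-index of a Cox fit on ``features`` over the
    partitions; non-convergent or degenerate fits count as 0.5."""
    x = df[features].to_numpy(dtype=float)
    scores = []
    for train_ids, val_ids in parts.partitions:
        itr = [pos[p] for p in train_ids]
        iva = [pos[p] for p in val_ids]
        fit = cox_newton(x[itr], time[itr], event[itr], l2=l2)
        if not fit.converged:
            scores.append(0.5)
            continue
        risk = x[iva] @ fit.beta
        try:
            scores.append(harrell_cindex(risk, time[iva], event[iva]).point)
        except ValueError:  # no comparable pairs in this sub-validation draw
            scores.append(0.5)
    return float(np.mean(scores))


def univariate_screen(table: FeatureTable, outcome: SurvivalOutcome,
                      parts: SubPartitionSet, l2: float = 1e-6) -> UnivariateScreenResult:
    """Score each feature alone; keep those with mean validation C-index > 0.5,
    ranked descending (rank 1 = best)."""
    df, time, event = _aligned(table, outcome)
    pos = {p: i for i, p in enumerate(table.patient_ids)}
    rows = []
    for feat in table.feature_names:
        if df[feat].nunique() <= 1:
            mean_c = 0.5  # zero-variance feature: degenerate fit, uninformative
        else:
            mean_c = _mean_val_cindex(df, time, event, pos, [feat], parts, l2)
        rows.append({"feature": feat, "mean_cindex": mean_c, "passed": mean_c > 0.5})
    res = pd.DataFrame(rows)
    res["rank"] = np.nan
    passed = res[res["passed"]].sort_values("mean_cindex", ascending=False, kind="stable")
    res.loc[passed.index, "rank"] = np.arange(1, len(passed) + 1)
    return UnivariateScreenResult(res)


def forward_select(table: FeatureTable, outcome: SurvivalOutcome,
                   screen: UnivariateScreenResult, parts: SubPartitionSet,
                   max_features: int = 20, l2: float = 1e-6):
    """Iterative forward selection while fitting.

    Returns (FittedCoxModel refit on the full training cohort,
    ForwardSelectionTrace). Raises if no feature passed screening.
    """
    candidates = screen.passed
    if not candidates:
        raise ValueError("no feature passed the univariate screen")
    df, time, event = _aligned(table, outcome)
    pos = {p: i for i, p in enumerate(table.patient_ids)}
    trace = ForwardSelectionTrace(seed=parts.seed)

    selected = [candidates[0]]
    best = _mean_val_cindex(df, time, event, pos, selected, parts, l2)
    trace.steps.append({"candidate": candidates[0], "mean_cindex": best, "accepted": True})
    remaining = candidates[1:]

    while remaining and len(selected) < max_features:
        scores = [
            _mean_val_cindex(df, time, event, pos, selected + [c], parts, l2)
            for c in remaining
        ]
        # best candidate; ties broken by screening rank (remaining is rank-ordered)
        j = int(np.argmax(scores))
        cand, score = remaining[j], scores[j]
        accepted = score > best
        trace.steps.append({"candidate": cand, "mean_cindex": float(score), "accepted": accepted})
        if not accepted:
            break
        selected.append(cand)
        best = score
        remaining.pop(j)

    trace.selected = list(selected)
    trace.p_val = float(best)
    fit = cox_newton(df[selected].to_numpy(dtype=float), time, event, l2=l2)
    if not fit.converged:
        logger.warning("full-cohort refit did not converge for %s", selected)
    model = FittedCoxModel(selected, fit.beta, fit.converged, l2=l2)
    return model, trace


def predict_risk(model: FittedCoxModel, table: FeatureTable,
                 endpoint: str = "", modality: str | None = None) -> RiskVector:
    """Deterministic linear risk scores ``x @ beta`` for every patient."""
    missing = [f for f in model.feature_names if f not in table.data.columns]
    if missing:
        raise ValueError(f"table lacks model features: {missing}")
    x = table.data[model.feature_names].to_numpy(dtype=float)
    return RiskVector(table.patient_ids, x @ model.beta,
                      modality if modality is not None else table.modality, endpoint)
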