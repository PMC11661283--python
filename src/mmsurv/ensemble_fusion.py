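"""Validation-performance-weighted late fusion of per-modality risk scores.

Each modality m contributes a risk score r_{i,m} per patient i and a
validation performance p_m (a C-index). Fusion weights are the normalized
validation performances,

    w_m = p_m / sum_m' p_m',

and the ensemble risk is the weighted sum r_i = sum_m w_m r_{i,m}. Risk
scores are combined raw (models trained on the same cohort share a baseline
hazard); an optional per-modality z-scoring switch exists for scale-sensitive
settings but is off by default. A uniform-weight variant (w_m = 1/M) is
provided for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .cohort_io import RiskVector


@dataclass
class ModalityWeightSet:
    p_val: dict[str, float]
    weights: dict[str, float]
    endpoint: str = ""

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({"endpoint": self.endpoint, "p_val": self.p_val,
                        "weights": self.weights}, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s


@dataclass
class FusedRisk:
    fused: RiskVector
    components: dict[str, RiskVector] = field(default_factory=dict)
    weight_set: ModalityWeightSet | None = None


def compute_weights(p_val: Mapping[str, float], endpoint: str = "") -> ModalityWeightSet:
    """w_m = p_m / sum p_m; every validation performance must be positive."""
    if not p_val:
        raise ValueError("need at least one modality")
    bad = {m: p for m, p in p_val.items() if not (np.isfinite(p) and p > 0)}
    if bad:
        raise ValueError(f"validation performances must be positive: {bad}")
    total = float(sum(p_val.values()))
    return ModalityWeightSet(dict(p_val), {m: float(p) / total for m, p in p_val.items()},
                             endpoint)


def _check_aligned(risks: Mapping[str, RiskVector]) -> list[str]:
    its = iter(risks.values())
    ref = next(its).patient_ids
    for rv in its:
        if rv.patient_ids != ref:
            raise ValueError("risk vectors are not aligned on identical patient lists")
    return ref


def fuse(risks: Mapping[str, RiskVector], weights: ModalityWeightSet,
         standardize: bool = False, label: str = "fused") -> FusedRisk:
    """Per-patient weighted sum of modality risk scores."""
    if set(risks) != set(weights.weights):
        raise ValueError(
            f"modalities {sorted(risks)} do not match weight set {sorted(weights.weights)}")
    ids = _check_aligned(risks)
    total = np.zeros(len(ids))
    for m, rv in risks.items():
        s = rv.scores
        if standardize:
            sd = s.std()
            s = (s - s.mean()) / sd if sd > 0 else s - s.mean()
        total = total + weights.weights[m] * s
    fused = RiskVector(ids, total, label, weights.endpoint)
    return FusedRisk(fused, dict(risks), weights)


def fuse_uniform(risks: Mapping[str, RiskVector], endpoint: str = "",
                 standardize: bool = False) -> FusedRisk:
    """Equal-weight fusion: w_m = 1/M for every modality."""
    M = len(risks)
    if M == 0:
        raise ValueError("need at least one modality")
    ws = ModalityWeightSet({m: float("nan") for m in risks},
                           {m: 1.0 / M for m in risks}, endpoint)
    return fuse(risks, ws, standardize=standardize, label="fused_uniform")
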