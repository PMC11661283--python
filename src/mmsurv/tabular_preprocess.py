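"""Fitted, replayable preprocessing for clinical and omics tables.

Pipeline (fit on a training cohort, replayed verbatim on test cohorts):

1. drop features missing in more than ``max_missing_frac`` of patients
   (strict inequality: exactly at the threshold is kept);
2. impute remaining missing numeric values with the training median
   (categoricals with the training modal level);
3. one-hot code declared categorical features with k-1 indicators
   (reference = most frequent training level; unseen test levels map to
   all-zero indicators);
4. z-score numeric features with training mean/sd (constant features
   dropped); indicator columns are left on their 0/1 scale;
5. greedy Spearman deduplication in column order: a column is dropped iff
   its |rho| with any previously kept column exceeds ``rho_max``.

All fitted state lives in a JSON-serializable :class:`PreprocessSpec`, so the
transform is a pure function of the spec.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import FeatureTable


@dataclass
class PreprocessSpec:
    modality: str = ""
    categorical: list[str] = field(default_factory=list)
    max_missing_frac: float = 0.20
    rho_max: float = 0.8
    ddof: int = 1
    signed_rho: bool = False
    kept_after_missingness: list[str] = field(default_factory=list)
    medians: dict[str, float] = field(default_factory=dict)
    modal_levels: dict[str, str] = field(default_factory=dict)
    level_maps: dict[str, list[str]] = field(default_factory=dict)  # non-reference levels
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    constant_dropped: list[str] = field(default_factory=list)
    dedup_dropped: list[tuple[str, str, float]] = field(default_factory=list)
    final_features: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "PreprocessSpec":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        d = json.loads(text)
        d["dedup_dropped"] = [tuple(t) for t in d["dedup_dropped"]]
        return cls(**d)


def filter_missingness(table: FeatureTable, max_frac: float = 0.20) -> FeatureTable:
    """Drop columns whose missing fraction strictly exceeds ``max_frac``."""
    if not 0 <= max_frac <= 1:
        raise ValueError("max_frac must lie in [0, 1]")
    frac = table.data.isna().mean(axis=0)
    keep = [c for c in table.feature_names if frac[c] <= max_frac]
    return FeatureTable(table.data[keep].copy(), table.modality)


def impute_median(table: FeatureTable, medians: dict[str, float] | None = None,
                  modal_levels: dict[str, str] | None = None,
                  categorical: list[str] | None = None):
    """Fill missing values. Fit mode (medians=None) computes training medians
    (modal level for categoricals) and returns them; transform mode replays
    the supplied values.

    Returns (table, medians, modal_levels).
    """
    categorical = categorical or []
    df = table.data.copy()
    fit = medians is None
    if fit:
        medians, modal_levels = {}, {}
        for c in df.columns:
            if c in categorical:
                obs = df[c].dropna()
                if obs.empty:
                    raise ValueError(f"categorical column {c!r} is entirely missing at fit time")
                modal_levels[c] = str(obs.mode().iloc[0])
            else:
                obs = pd.to_numeric(df[c], errors="coerce").dropna()
                if obs.empty:
                    raise ValueError(f"column {c!r} is entirely missing at fit time")
                medians[c] = float(obs.median())
    assert medians is not None and modal_levels is not None
    for c in df.columns:
        if c in medians:
            df[c] = pd.to_numeric(df[c], errors="coerce").fillna(medians[c])
        elif c in modal_levels:
            df[c] = df[c].where(df[c].notna(), modal_levels[c]).astype(str)
    return FeatureTable(df, table.modality), medians, modal_levels


def one_hot_encode(table: FeatureTable, categorical: list[str],
                   level_maps: dict[str, list[str]] | None = None):
    """k-1 dummy coding; the fit-time modal level is the reference.

    Returns (table, level_maps) where level_maps lists the non-reference
    levels (column order of the indicators). Unseen test levels produce
    all-zero indicator rows.
    """
    df = table.data
    fit = level_maps is None
    if fit:
        level_maps = {}
        for c in categorical:
            if c not in df.columns:
                continue
            counts = df[c].astype(str).value_counts()
            ref = counts.index[0]  # most frequent; value_counts breaks ties by first occurrence
            level_maps[c] = [lv for lv in sorted(counts.index) if lv != ref]
    assert level_maps is not None
    cols = {}
    for c in table.feature_names:
        if c in level_maps:
            vals = df[c].astype(str)
            for lv in level_maps[c]:
                cols[f"{c}={lv}"] = (vals == lv).astype(float)
        elif c in categorical:
            continue  # categorical column absent from the fitted map
        else:
            cols[c] = pd.to_numeric(df[c], errors="coerce")
    return FeatureTable(pd.DataFrame(cols, index=df.index), table.modality), level_maps


def zscore(table: FeatureTable, means: dict[str, float] | None = None,
           sds: dict[str, float] | None = None, ddof: int = 1,
           skip: set[str] | None = None):
    """Standardize numeric columns with training mean/sd.

    Fit mode computes the statistics; columns with zero training sd are
    dropped (recorded via sd=0 in the returned map). ``skip`` columns
    (e.g. 0/1 indicators) pass through untouched.

    Returns (table, means, sds, dropped).
    """
    df = table.data.copy()
    skip = skip or set()
    fit = means is None
    if fit:
        means, sds = {}, {}
        for c in df.columns:
            if c in skip:
                continue
            means[c] = float(df[c].mean())
            sds[c] = float(df[c].std(ddof=ddof)) if len(df) > ddof else 0.0
    assert means is not None and sds is not None
    dropped = [c for c in df.columns if c in sds and (sds[c] == 0 or not np.isfinite(sds[c]))]
    df = df.drop(columns=dropped)
    for c in df.columns:
        if c in means:
            df[c] = (df[c] - means[c]) / sds[c]
    return FeatureTable(df, table.modality), means, sds, dropped


def spearman_dedup(table: FeatureTable, rho_max: float = 0.8, signed: bool = False,
                   keep: list[str] | None = None):
    """Greedy Spearman-correlation deduplication in column order.

    Fit mode (keep=None): scan columns left to right, dropping any column
    whose correlation with an already-kept column exceeds ``rho_max``
    (absolute rho by default). Transform mode replays a kept-column list.

    Returns (table, kept, dropped_log) with dropped_log entries
    (dropped, kept_partner, rho).
    """
    df = table.data
    if df.isna().any().any():
        raise ValueError("deduplication requires a complete (imputed) matrix")
    if keep is not None:
        return FeatureTable(df[keep].copy(), table.modality), list(keep), []
    cols = list(df.columns)
    if len(cols) <= 1:
        return FeatureTable(df.copy(), table.modality), cols, []
    rho = stats.spearmanr(df.to_numpy()).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    if not signed:
        rho = np.abs(rho)
    kept_idx: list[int] = []
    dropped_log: list[tuple[str, str, float]] = []
    for j in range(len(cols)):
        offender = next((i for i in kept_idx if rho[j, i] > rho_max), None)
        if offender is None:
            kept_idx.append(j)
        else:
            raw = stats.spearmanr(df.iloc[:, j], df.iloc[:, offender]).statistic
            dropped_log.append((cols[j], cols[offender], float(raw)))
    kept = [cols[i] for i in kept_idx]
    return FeatureTable(df[kept].copy(), table.modality), kept, dropped_log


def fit_preprocess(table: FeatureTable, categorical: list[str] | None = None,
                   max_missing_frac: float = 0.20, rho_max: float = 0.8,
                   ddof: int = 1, signed_rho: bool = False):
    """Fit the full pipeline on a training table.

    Returns (transformed_table, spec). ``apply_preprocess(spec)`` replays the
    identical transform on any table with the same raw columns.
    """
    categorical = list(categorical or [])
    spec = PreprocessSpec(modality=table.modality, categorical=categorical,
                          max_missing_frac=max_missing_frac, rho_max=rho_max,
                          ddof=ddof, signed_rho=signed_rho)
    t = filter_missingness(table, max_missing_frac)
    spec.kept_after_missingness = t.feature_names
    t, spec.medians, spec.modal_levels = impute_median(t, categorical=categorical)
    t, spec.level_maps = one_hot_encode(t, categorical)
    indicator_cols = {f"{c}={lv}" for c, lvs in spec.level_maps.items() for lv in lvs}
    t, spec.means, spec.sds, spec.constant_dropped = zscore(t, ddof=ddof, skip=indicator_cols)
    t, kept, spec.dedup_dropped = spearman_dedup(t, rho_max, signed_rho)
    spec.final_features = kept
    return t, spec


def apply_preprocess(table: FeatureTable, spec: PreprocessSpec) -> FeatureTable:
    """Replay a fitted spec on new data; uses only fit-time statistics."""
    t = FeatureTable(table.data[spec.kept_after_missingness].copy(), table.modality)
    t, _, _ = impute_median(t, spec.medians, spec.modal_levels, spec.categorical)
    t, _ = one_hot_encode(t, spec.categorical, spec.level_maps)
    t, _, _, _ = zscore(t, spec.means, spec.sds, spec.ddof)
    t, _, _ = spearman_dedup(t, spec.rho_max, spec.signed_rho, keep=spec.final_features)
    return t
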