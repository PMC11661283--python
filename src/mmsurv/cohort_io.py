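"""Data model for multimodal survival cohorts and readers/writers.

A cohort bundles, per patient: right-censored follow-up outcomes (overall
survival and disease-free survival, in months), one or more tabular feature
modalities (clinical, omics-like matrices), and optionally a bag of patch
embedding vectors derived from a whole-slide image.

Tabular data live in CSV/TSV files with a header row and a ``patient_id``
column; embedding bags live in HDF5 files with one group per patient holding
an ``embeddings`` (n x d, float32) dataset and an optional ``coords``
(n x 2, int64) dataset of level-0 patch origins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ID_COLUMN = "patient_id"


@dataclass
class SurvivalOutcome:
    """Right-censored follow-up for one endpoint, aligned to ``patient_ids``.

    ``time`` is months since diagnosis; ``event`` is 1 when the endpoint
    (death for OS, recurrence for DFS) was observed and 0 when censored.
    """

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if len(self.patient_ids) != self.time.shape[0] or self.time.shape != self.event.shape:
            raise ValueError("patient_ids, time and event must have equal length")
        finite = np.isfinite(self.time)
        if np.any(self.time[finite] < 0):
            raise ValueError("follow-up times must be non-negative")
        ev = self.event[~np.isnan(self.event.astype(float))]
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")
        self.event = self.event.astype(float)

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, ids: list[str]) -> "SurvivalOutcome":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        idx = [pos[p] for p in ids]
        return SurvivalOutcome(list(ids), self.time[idx], self.event[idx], self.endpoint)

    def complete_ids(self) -> set[str]:
        """Patients with a finite time and a non-missing event flag."""
        ok = np.isfinite(self.time) & ~np.isnan(self.event)
        return {p for p, o in zip(self.patient_ids, ok) if o}


@dataclass
class FeatureTable:
    """Patients x features matrix for one tabular modality.

    Values are stored in a pandas DataFrame indexed by patient id; missing
    entries are NaN (allowed before preprocessing only).
    """

    data: pd.DataFrame
    modality: str = "tabular"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate patient ids: {dups}")
        self.data.index = self.data.index.astype(str)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, ids: list[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(ids)].copy(), self.modality)


@dataclass
class EmbeddingBag:
    """Variable-length set of patch embedding vectors for one slide."""

    patient_id: str
    vectors: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError(f"bag for {self.patient_id} must be a non-empty n x d matrix")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.int64)
            if self.coords.shape != (self.vectors.shape[0], 2):
                raise ValueError(f"coords for {self.patient_id} must be n x 2")

    @property
    def n_patches(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class RiskVector:
    """Per-patient risk scores on the log-partial-hazard scale."""

    patient_ids: list[str]
    scores: np.ndarray
    modality: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.patient_ids),):
            raise ValueError("scores must align with patient_ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("risk scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                ID_COLUMN: self.patient_ids,
                "endpoint": self.endpoint,
                "modality": self.modality,
                "risk": self.scores,
            }
        )


@dataclass
class MultimodalBundle:
    """A cohort complete in every modality and every endpoint."""

    patients: list[str]
    outcomes: dict[str, SurvivalOutcome]
    tables: dict[str, FeatureTable] = field(default_factory=dict)
    bags: dict[str, EmbeddingBag] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patients)


def read_feature_table(path: str | Path, modality: str, sep: str | None = None) -> FeatureTable:
    """Read a delimited table (CSV/TSV inferred from suffix) into a FeatureTable.

    Empty cells become NaN. Non-numeric content in a column that otherwise
    parses as numeric raises with the offending row/column named.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    if ID_COLUMN not in df.columns:
        raise ValueError(f"{path} lacks required id column {ID_COLUMN!r}")
    if df[ID_COLUMN].duplicated().any():
        dups = df[ID_COLUMN][df[ID_COLUMN].duplicated()].tolist()
        raise ValueError(f"duplicate patient ids in {path}: {dups}")
    df = df.set_index(ID_COLUMN)
    out = {}
    for col in df.columns:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            if bad.sum() == raw.notna().sum():
                out[col] = raw  # genuinely categorical column
                continue
            raise ValueError(
                f"non-numeric value {raw[bad].iloc[0]!r} in numeric column {col!r}, row {raw.index[bad][0]!r}"
            )
        out[col] = num
    return FeatureTable(pd.DataFrame(out, index=df.index), modality)


def write_feature_table(table: FeatureTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    table.data.to_csv(path, sep=sep, index_label=ID_COLUMN)


def read_outcomes(path: str | Path, endpoint: str, time_col: str | None = None,
                  event_col: str | None = None) -> SurvivalOutcome:
    """Read one endpoint from a CSV with patient_id, <endpoint>_time, <endpoint>_event."""
    time_col = time_col or f"{endpoint.lower()}_time"
    event_col = event_col or f"{endpoint.lower()}_event"
    df = pd.read_csv(path)
    if df[ID_COLUMN].duplicated().any():
        raise ValueError(f"duplicate patient ids in {path}")
    return SurvivalOutcome(
        df[ID_COLUMN].astype(str).tolist(),
        df[time_col].to_numpy(dtype=float),
        df[event_col].to_numpy(dtype=float),
        endpoint,
    )


def write_outcomes(outcomes: Mapping[str, SurvivalOutcome], path: str | Path) -> None:
    base = None
    for ep, out in outcomes.items():
        cols = {f"{ep.lower()}_time": out.time, f"{ep.lower()}_event": out.event}
        df = pd.DataFrame(cols, index=pd.Index(out.patient_ids, name=ID_COLUMN))
        base = df if base is None else base.join(df, how="outer")
    assert base is not None
    base.to_csv(path)


def read_embedding_bags(path: str | Path) -> dict[str, EmbeddingBag]:
    """Read all per-patient embedding bags from an HDF5 file.

    Every bag must be non-empty and share one embedding dimension d.
    """
    bags: dict[str, EmbeddingBag] = {}
    dim = None
    with h5py.File(path, "r") as f:
        for pid in f:
            grp = f[pid]
            vec = np.asarray(grp["embeddings"], dtype=np.float32)
            if vec.ndim != 2 or vec.shape[0] == 0:
                raise ValueError(f"empty or malformed bag for patient {pid!r}")
            if dim is None:
                dim = vec.shape[1]
            elif vec.shape[1] != dim:
                raise ValueError(
                    f"inconsistent embedding dimension: {pid!r} has d={vec.shape[1]}, expected {dim}"
                )
            coords = np.asarray(grp["coords"], dtype=np.int64) if "coords" in grp else None
            bags[pid] = EmbeddingBag(pid, vec, coords)
    return bags


def write_embedding_bags(bags: Mapping[str, EmbeddingBag], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for pid, bag in bags.items():
            grp = f.create_group(pid)
            grp.create_dataset("embeddings", data=bag.vectors.astype(np.float32))
            if bag.coords is not None:
                grp.create_dataset("coords", data=bag.coords.astype(np.int64))


def write_risk_vectors(risks: list[RiskVector], path: str | Path) -> None:
    pd.concat([r.to_frame() for r in risks], ignore_index=True).to_csv(path, index=False)


def align_cohort(
    tables: Mapping[str, FeatureTable],
    bags: Mapping[str, EmbeddingBag] | None,
    outcomes: Mapping[str, SurvivalOutcome],
) -> MultimodalBundle:
    """Restrict to patients complete in every modality and every endpoint.

    Mirrors the usual multimodal-cohort exclusion rule: a patient missing any
    modality, or missing follow-up for any endpoint, is dropped. Counts of
    patients dropped per reason are logged and kept on the bundle.
    """
    if not tables and not bags:
        raise ValueError("at least one modality required")
    universe: set[str] = set()
    for t in tables.values():
        universe |= set(t.patient_ids)
    if bags:
        universe |= set(bags.keys())
    for o in outcomes.values():
        universe |= set(o.patient_ids)

    keep = set(universe)
    dropped: dict[str, int] = {}
    for name, t in tables.items():
        before = len(keep)
        keep &= set(t.patient_ids)
        dropped[f"missing_{name}"] = before - len(keep)
    if bags is not None and len(bags) > 0:
        before = len(keep)
        keep &= set(bags.keys())
        dropped["missing_bags"] = before - len(keep)
    for ep, o in outcomes.items():
        before = len(keep)
        keep &= o.complete_ids()
        dropped[f"incomplete_{ep}"] = before - len(keep)

    if not keep:
        raise ValueError("no patient is complete in all modalities and endpoints")
    patients = sorted(keep)
    for reason, n in dropped.items():
        if n:
            logger.info("align_cohort: dropped %d patients (%s)", n, reason)
    return MultimodalBundle(
        patients=patients,
        outcomes={ep: o.subset(patients) for ep, o in outcomes.items()},
        tables={m: t.subset(patients) for m, t in tables.items()},
        bags={p: bags[p] for p in patients} if bags else {},
        dropped=dropped,
    )
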