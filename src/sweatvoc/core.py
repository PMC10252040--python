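"""Core data model for vectorized GC×GC-MS sweat-volatilomics datasets.

A *descriptor* is one compound from a fixed screening library; every
chromatogram is reduced to a vector of integrated peak areas, one per library
descriptor (0 when the compound is absent).  Measurements carry closed-
vocabulary metadata: the subject, the sampled body site, the pre/post-surgery
status, the GC-column batch, and a technical-replicate index.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SITES = ("hand", "breast")
STATUSES = ("pre", "post")
BATCHES = ("column1", "column2")
META_COLUMNS = ("subject_id", "site", "status", "batch", "replicate")

#: Status treated as the positive class throughout (the "sick", pre-surgery
#: state); sensitivity is the recall of this label.
POSITIVE_STATUS = "pre"

DEFAULT_MAX_REPLICATES = 4

TRANSFORM_STATES = ("raw", "logged", "standardized")


class ValidationError(ValueError):
    """Raised when a table, dataset or configuration violates its contract."""


class StateError(RuntimeError):
    """Raised when a transform is applied to a dataset in the wrong state."""


@dataclass(frozen=True)
class DescriptorLibrary:
    """Ordered registry of screened compounds; order defines vector position.

    Display names are informative only (tentative spectral-match identities);
    all joins and alignments go through ``descriptor_id``.
    """

    ids: tuple[str, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) < 1:
            raise ValidationError("library must contain at least one descriptor")
        if len(self.ids) != len(self.names):
            raise ValidationError("library ids and names differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({d for d in self.ids if list(self.ids).count(d) > 1})
            raise ValidationError(f"duplicate descriptor ids: {dupes}")

    @property
    def size(self) -> int:
        return len(self.ids)

    def index_of(self, descriptor_id: str) -> int:
        return self.ids.index(descriptor_id)

    def indices(self, descriptor_ids) -> np.ndarray:
        lookup = {d: i for i, d in enumerate(self.ids)}
        return np.array([lookup[d] for d in descriptor_ids], dtype=int)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorLibrary":
        if not {"descriptor_id", "display_name"}.issubset(frame.columns):
            raise ValidationError(
                "library table needs columns descriptor_id, display_name"
            )
        return cls(
            ids=tuple(str(v) for v in frame["descriptor_id"]),
            names=tuple(str(v) for v in frame["display_name"]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"descriptor_id": self.ids, "display_name": self.names})


@dataclass(frozen=True)
class Measurement:
    """One vectorized chromatogram plus its sampling metadata."""

    subject_id: str
    site: str
    status: str
    batch: str
    replicate: int
    areas: np.ndarray

    def __post_init__(self) -> None:
        _check_token("site", self.site, SITES)
        _check_token("status", self.status, STATUSES)
        _check_token("batch", self.batch, BATCHES)
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")


def _check_token(name: str, value: str, allowed: tuple[str, ...]) -> None:
    if value not in allowed:
        raise ValidationError(f"unknown {name} token {value!r}; allowed: {allowed}")


@dataclass
class Dataset:
    """A descriptor library, a metadata table and the area matrix.

    ``areas`` has one row per measurement and one column per library
    descriptor, in library order.  ``transform_state`` tracks the position in
    the log → standardize chain so stages cannot run out of order.
    """

    library: DescriptorLibrary
    meta: pd.DataFrame
    areas: np.ndarray
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(f"bad transform_state {self.transform_state!r}")
        self.meta = self.meta.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 2 or self.areas.shape[1] != self.library.size:
            raise ValidationError(
                f"area matrix shape {self.areas.shape} does not match "
                f"library size {self.library.size}"
            )
        if len(self.meta) != self.areas.shape[0]:
            raise ValidationError("metadata rows and area rows differ")
        if not np.all(np.isfinite(self.areas)):
            raise ValidationError("areas contain non-finite values")
        if self.transform_state in ("raw", "logged") and np.any(self.areas < 0):
            r, c = np.argwhere(self.areas < 0)[0]
            raise ValidationError(
                f"negative area at row {r}, descriptor {self.library.ids[c]!r}"
            )
        for i, row in self.meta.iterrows():
            _check_token("site", row["site"], SITES)
            _check_token("status", row["status"], STATUSES)
            _check_token("batch", row["batch"], BATCHES)
            if int(row["replicate"]) < 1:
                raise ValidationError(f"row {i}: replicate must be >= 1")

    @property
    def n(self) -> int:
        return self.areas.shape[0]

    def labels(self) -> np.ndarray:
        """Binary class labels: 1 for the positive (pre-surgery) status."""
        return (self.meta["status"].to_numpy() == POSITIVE_STATUS).astype(int)

    def groups(self) -> np.ndarray:
        """Sampling-group key per row: technical replicates share a group."""
        return (
            self.meta["subject_id"].astype(str) + "|" + self.meta["status"].astype(str)
        ).to_numpy()

    def with_areas(self, areas: np.ndarray, transform_state: str) -> "Dataset":
        return Dataset(self.library, self.meta.copy(), areas, transform_state)

    def select_rows(self, rows) -> "Dataset":
        rows = np.asarray(rows)
        return Dataset(
            self.library,
            self.meta.iloc[rows].reset_index(drop=True),
            self.areas[rows],
            self.transform_state,
        )

    @classmethod
    def from_measurements(
        cls,
        library: DescriptorLibrary,
        measurements,
        transform_state: str = "raw",
    ) -> "Dataset":
        meta = pd.DataFrame(
            [
                {
                    "subject_id": m.subject_id,
                    "site": m.site,
                    "status": m.status,
                    "batch": m.batch,
                    "replicate": int(m.replicate),
                }
                for m in measurements
            ],
            columns=list(META_COLUMNS),
        )
        if measurements:
            areas = np.vstack([np.asarray(m.areas, dtype=float) for m in measurements])
        else:
            areas = np.empty((0, library.size))
        return cls(library, meta, areas, transform_state)


DEFAULT_C_GRID = tuple(float(10.0**e) for e in np.arange(-4, 1.5, 0.5))
DEFAULT_N_GRID = (5, 10, 20, 40, 80, 120, 175, 250)


@dataclass
class RunConfig:
    """Knobs for a full analysis run.

    ``probe_realizations`` defaults to the study-scale 100,000; scaled-down
    runs pass a smaller value explicitly.
    """

    alpha: float = 0.05
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_grid: tuple[int, ...] = DEFAULT_N_GRID
    smote_k: int = 5
    probe_realizations: int = 100_000
    delta_grid: tuple[float, ...] = (0.05, 0.10, 0.20)
    cv_scheme: str = "leave_one_out"  # or "stratified_kfold"
    k_folds: int = 5
    test_fraction: float = 0.3
    max_replicates: int = DEFAULT_MAX_REPLICATES
    pool_batches: bool = False
    seed: int = 0

    def validate(self, library_size: int | None = None) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise ValidationError("c_grid must be non-empty and positive")
        if not self.n_grid or any(n < 1 for n in self.n_grid):
            raise ValidationError("n_grid must be non-empty positive integers")
        if library_size is not None and any(n > library_size for n in self.n_grid):
            bad = [n for n in self.n_grid if n > library_size]
            raise ValidationError(
                f"n_grid values {bad} exceed library size {library_size}"
            )
        if self.probe_realizations < 100:
            raise ValidationError("probe_realizations must be >= 100")
        if any(not 0 < d < 1 for d in self.delta_grid):
            raise ValidationError("delta values must lie in (0, 1)")
        if self.cv_scheme not in ("leave_one_out", "stratified_kfold"):
            raise ValidationError(f"unknown cv_scheme {self.cv_scheme!r}")
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


@dataclass
class ValidationReport:
    """Reporting-only summary of a dataset's structure."""

    nonzero_counts: np.ndarray
    status_counts: dict[str, int]
    replicate_counts: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_dataset(
    dataset: Dataset, max_replicates: int = DEFAULT_MAX_REPLICATES
) -> ValidationReport:
    """Summarize a dataset and flag structural oddities (never raises).

    Flags subjects present in only one status and sampling events with more
    technical replicates than the configured maximum.
    """
    nonzero = (dataset.areas > 0).sum(axis=1)
    status_counts = dataset.meta["status"].value_counts().to_dict()
    rep = (
        dataset.meta.groupby(["subject_id", "site", "status"], sort=True)
        .size()
        .rename("n_replicates")
        .reset_index()
    )
    flags: list[str] = []
    for _, row in rep.iterrows():
        if row["n_replicates"] > max_replicates:
            flags.append(
                f"subject {row['subject_id']} {row['site']}/{row['status']}: "
                f"{row['n_replicates']} replicates exceeds maximum {max_replicates}"
            )
    by_subject = dataset.meta.groupby("subject_id")["status"].agg(set)
    for subject, statuses in by_subject.items():
        if len(statuses) < 2:
            only = next(iter(statuses))
            flags.append(f"subject {subject} present only in status {only!r}")
    return ValidationReport(nonzero, status_counts, rep, flags)
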