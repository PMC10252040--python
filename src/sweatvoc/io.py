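"""Delimited-text readers/writers, config loading and run logging.

All interchange is plain UTF-8 CSV with a comma delimiter and decimal point.
Measurement tables carry the transform state in a ``#`` header comment so a
logged table is never silently mistaken for raw areas.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    BATCHES,
    META_COLUMNS,
    SITES,
    STATUSES,
    Dataset,
    DescriptorLibrary,
    RunConfig,
    ValidationError,
)

_STATE_COMMENT = "# transform_state:"


def read_library(path) -> DescriptorLibrary:
    return DescriptorLibrary.from_frame(pd.read_csv(path, dtype=str))


def write_library(library: DescriptorLibrary, path) -> None:
    library.to_frame().to_csv(path, index=False)


def write_measurement_table(dataset: Dataset, path) -> None:
    """Write a dataset as CSV; full float precision so round trips are exact."""
    path = Path(path)
    frame = dataset.meta.copy()
    for j, did in enumerate(dataset.library.ids):
        frame[did] = dataset.areas[:, j]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_STATE_COMMENT} {dataset.transform_state}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_measurement_table(path, library: DescriptorLibrary) -> Dataset:
    """Read a measurement CSV, re-aligning descriptor columns to library order.

    The header must contain exactly the metadata columns plus one column per
    library descriptor (any order).  Missing or extra descriptor columns,
    non-numeric or negative areas, and unknown metadata tokens all raise
    :class:`ValidationError` naming the offending row/column.
    """
    path = Path(path)
    state = "raw"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith(_STATE_COMMENT):
        state = first[len(_STATE_COMMENT):].strip()
    frame = pd.read_csv(
        path, comment="#", dtype={"subject_id": str}, float_precision="round_trip"
    )
    columns = list(frame.columns)
    missing_meta = [c for c in META_COLUMNS if c not in columns]
    if missing_meta:
        raise ValidationError(f"missing metadata columns: {missing_meta}")
    descriptor_cols = [c for c in columns if c not in META_COLUMNS]
    missing = [d for d in library.ids if d not in descriptor_cols]
    if missing:
        raise ValidationError(f"missing descriptor columns: {missing}")
    extra = [c for c in descriptor_cols if c not in set(library.ids)]
    if extra:
        raise ValidationError(f"columns not in library: {extra}")

    n = len(frame)
    areas = np.empty((n, library.size))
    for j, did in enumerate(library.ids):
        col = pd.to_numeric(frame[did], errors="coerce")
        bad = col.isna() & frame[did].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"non-numeric area at row {row}, descriptor {did!r}: "
                f"{frame[did].iloc[row]!r}"
            )
        if col.isna().any():
            row = int(np.flatnonzero(col.isna())[0])
            raise ValidationError(f"missing area at row {row}, descriptor {did!r}")
        if state in ("raw", "logged") and (col < 0).any():
            row = int(np.flatnonzero(col < 0)[0])
            raise ValidationError(
                f"negative area at row {row}, descriptor {did!r}: {col.iloc[row]}"
            )
        areas[:, j] = col.to_numpy(dtype=float)

    meta = frame[list(META_COLUMNS)].copy()
    meta["replicate"] = meta["replicate"].astype(int)
    for name, allowed in (("site", SITES), ("status", STATUSES), ("batch", BATCHES)):
        bad = ~meta[name].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"unknown {name} token {meta[name].iloc[row]!r} at row {row}"
            )
    return Dataset(library, meta, areas, transform_state=state)


def read_run_config(path) -> RunConfig:
    """Load a YAML key/value config; unknown keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = set(RunConfig().__dict__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("c_grid", "n_grid", "delta_grid"):
        if key in raw:
            raw[key] = tuple(raw[key])
    config = RunConfig(**raw)
    config.validate()
    return config


def setup_logging(log_path=None, level=logging.INFO) -> logging.Logger:
    """Timestamped text logging for pipeline stages."""
    logger = logging.getLogger("sweatvoc")
    logger.setLevel(level)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if log_path is not None:
        handler = logging.FileHandler(log_path, encoding="utf-8")
        handler.setFormatter(fmt)
        logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        stream = logging.StreamHandler()
        stream.setFormatter(fmt)
        logger.addHandler(stream)
    logger.propagate = False
    return logger


def log_run_header(logger: logging.Logger, config: RunConfig) -> None:
    logger.info(
        "run start %s seed=%d config_hash=%s",
        time.strftime("%Y-%m-%dT%H:%M:%S"),
        config.seed,
        config.config_hash(),
    )
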