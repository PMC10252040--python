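"""Transform chain and univariate screening: ln(1+a) → standardize → rank → PCA.

Zero areas mean "compound absent", so the log transform is ln(1 + a), which
keeps zeros at zero and is strictly monotone.  Descriptor ranking uses the
two-sided Mann-Whitney U test comparing pre vs post measurements per
descriptor, with no multiplicity correction; rank 1 is the smallest p-value
and ties are broken by library order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core import Dataset, StateError, ValidationError


@dataclass
class RankedDescriptors:
    """Descriptors ordered by ascending Mann-Whitney p-value."""

    frame: pd.DataFrame  # columns: descriptor_id, U, p_value, rank

    def __post_init__(self) -> None:
        expected = ["descriptor_id", "U", "p_value", "rank"]
        if list(self.frame.columns) != expected:
            raise ValidationError(f"ranked frame must have columns {expected}")

    @property
    def ids(self) -> list[str]:
        return list(self.frame["descriptor_id"])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ScalerState:
    """Per-descriptor location/scale learned on a fitting subset."""

    mean: np.ndarray
    sd: np.ndarray  # population sd (ddof=0)
    constant: np.ndarray  # boolean mask: sd == 0


def log_transform(dataset: Dataset) -> Dataset:
    """Natural-log normalization a → ln(1 + a); requires a raw dataset."""
    if dataset.transform_state != "raw":
        raise StateError(
            f"log_transform expects raw areas, got {dataset.transform_state!r}"
        )
    return dataset.with_areas(np.log1p(dataset.areas), "logged")


def fit_scaler(dataset: Dataset, rows) -> ScalerState:
    """Learn per-descriptor mean/sd on the fitting rows of a logged dataset."""
    if dataset.transform_state != "logged":
        raise StateError(
            f"fit_scaler expects a logged dataset, got {dataset.transform_state!r}"
        )
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValidationError("empty fitting subset for scaler")
    X = dataset.areas[rows]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    return ScalerState(mean=mean, sd=sd, constant=sd == 0)


def apply_scaler(dataset: Dataset, state: ScalerState) -> Dataset:
    """Standardize all rows with a previously fitted scaler (no refit).

    Constant descriptors (sd = 0 on the fitting rows) map to 0.
    """
    if dataset.transform_state != "logged":
        raise StateError("apply_scaler expects a logged dataset")
    safe_sd = np.where(state.constant, 1.0, state.sd)
    scaled = (dataset.areas - state.mean) / safe_sd
    scaled[:, state.constant] = 0.0
    return dataset.with_areas(scaled, "standardized")


def _exact_eligible(pre: np.ndarray, post: np.ndarray) -> bool:
    if pre.size > 8 or post.size > 8:
        return False
    combined = np.concatenate([pre, post])
    return np.unique(combined).size == combined.size


def mannwhitney_rank(dataset: Dataset, rows) -> RankedDescriptors:
    """Two-sided Mann-Whitney U per descriptor, pre vs post, over given rows.

    The exact null distribution is used when both groups have at most 8
    observations and the descriptor has no ties; otherwise the tie-corrected
    normal approximation (with continuity correction).  Output is sorted by
    ascending p-value, ties broken by library order.
    """
    rows = np.asarray(rows)
    status = dataset.meta["status"].to_numpy()[rows]
    pre_rows = rows[status == "pre"]
    post_rows = rows[status == "post"]
    if pre_rows.size == 0 or post_rows.size == 0:
        raise ValidationError("both statuses must be present for ranking")
    X_pre = dataset.areas[pre_rows]
    X_post = dataset.areas[post_rows]

    with warnings.catch_warnings():
        # all-tied descriptors give sd 0 in the normal approximation
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(
            X_pre, X_post, alternative="two-sided", method="asymptotic", axis=0
        )
    U = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # a descriptor identical in both groups carries no information
    all_tied = np.all(dataset.areas[rows] == dataset.areas[rows][0], axis=0)
    p[all_tied] = 1.0
    if pre_rows.size <= 8 and post_rows.size <= 8:
        for j in range(dataset.library.size):
            if _exact_eligible(X_pre[:, j], X_post[:, j]):
                r = stats.mannwhitneyu(
                    X_pre[:, j], X_post[:, j], alternative="two-sided", method="exact"
                )
                U[j], p[j] = float(r.statistic), float(r.pvalue)
    p = np.clip(p, 0.0, 1.0)

    order = np.lexsort((np.arange(dataset.library.size), p))
    frame = pd.DataFrame(
        {
            "descriptor_id": np.asarray(dataset.library.ids)[order],
            "U": U[order],
            "p_value": p[order],
            "rank": np.arange(1, dataset.library.size + 1),
        }
    )
    return RankedDescriptors(frame)


def select_significant(ranked: RankedDescriptors, alpha: float) -> list[str]:
    """Descriptors with p < alpha, in rank order; no multiplicity correction."""
    kept = ranked.frame.loc[ranked.frame["p_value"] < alpha, "descriptor_id"]
    result = list(kept)
    if not result:
        warnings.warn(
            f"no descriptor significant at alpha={alpha}", stacklevel=2
        )
    return result


def select_top(ranked: RankedDescriptors, n: int) -> list[str]:
    """First n descriptors by rank (deterministic library-order tie-break)."""
    if not 1 <= n <= len(ranked):
        raise ValidationError(f"n must be in [1, {len(ranked)}], got {n}")
    return list(ranked.frame["descriptor_id"].iloc[:n])


def pca_project(
    dataset: Dataset, subset, k: int, rows=None
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and explained-variance fractions of the top-k principal axes.

    Operates on the standardized areas restricted to ``subset`` descriptors;
    returns (scores (n, k), explained_variance_ratio (k,)).
    """
    if dataset.transform_state != "standardized":
        raise StateError("pca_project expects a standardized dataset")
    idx = dataset.library.indices(subset)
    if idx.size < k:
        raise ValidationError(f"subset of size {idx.size} < k={k}")
    X = dataset.areas[:, idx] if rows is None else dataset.areas[np.asarray(rows)][:, idx]
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 rows")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
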