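"""SHAP attribution for linear classifiers, probe-variable relevance, Jaccard.

For a linear decision function f(x) = w·x + b the Shapley attribution of
feature j on row i is exact and closed-form: φ_ij = w_j (x_ij − x̄_j), with
x̄ the background mean, so Σ_j φ_ij = f(x_i) − f(x̄).  Negative values push
the prediction toward the pre-surgery class's complement and positive toward
the positive class, matching the sign of the decision value.

The probe-variable method injects a label-independent standard-normal column,
refits the classifier at the same C, and records the probe's importance rank;
over many realizations the rank CDF F(r) gives, for a risk δ, the largest
rank r_δ with F(r_δ) ≤ δ.  Descriptors ranked ≤ r_δ in the probe-free
reference fit are retained: the chance that a pure-noise feature would beat
them is at most δ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .core import Dataset, ValidationError
from .modeling import FitResult


@dataclass
class ShapSummary:
    """Per-row, per-descriptor attributions and the derived importance ranking."""

    phi: np.ndarray  # (n_rows, n_features)
    mean_abs: np.ndarray  # per-feature mean |φ|
    ranks: np.ndarray  # 1 = most important; permutation of 1..n_features
    descriptor_ids: tuple[str, ...]

    def ranking(self) -> list[str]:
        """Descriptor ids from most to least important."""
        order = np.argsort(self.ranks)
        return [self.descriptor_ids[i] for i in order]


def _importance_ranks(mean_abs: np.ndarray) -> np.ndarray:
    order = np.lexsort((np.arange(mean_abs.size), -mean_abs))
    ranks = np.empty(mean_abs.size, dtype=int)
    ranks[order] = np.arange(1, mean_abs.size + 1)
    return ranks


def linear_shap(fit: FitResult, X: np.ndarray, background: np.ndarray) -> ShapSummary:
    """Exact Shapley attributions for the linear decision value."""
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValidationError("background must be non-empty")
    if X.shape[1] != fit.weights.size or background.shape[1] != fit.weights.size:
        raise ValidationError("X/background width does not match fitted weights")
    mu = background.mean(axis=0)
    phi = (X - mu) * fit.weights
    mean_abs = np.abs(phi).mean(axis=0)
    ids = fit.descriptor_ids or tuple(f"f{j}" for j in range(fit.weights.size))
    return ShapSummary(phi, mean_abs, _importance_ranks(mean_abs), tuple(ids))


def shap_importance(summary: ShapSummary) -> list[tuple[str, float, int]]:
    """(descriptor_id, mean |φ|, rank) sorted by descending importance."""
    order = np.argsort(summary.ranks)
    return [
        (summary.descriptor_ids[i], float(summary.mean_abs[i]), int(summary.ranks[i]))
        for i in order
    ]


@dataclass
class ProbeResult:
    """Empirical probe-rank distribution and δ-threshold retained sets."""

    R: int
    n_features: int
    rank_counts: np.ndarray  # index r-1 holds count of rank r, r = 1..N+1
    cdf: np.ndarray  # F(r) = P(probe rank <= r)
    thresholds: dict[float, int]  # δ -> r_δ
    retained: dict[float, tuple[str, ...]]
    min_rank: int
    max_rank: int
    reference_ranking: tuple[str, ...]  # probe-free fit, most important first


def thresholds_from_cdf(cdf: np.ndarray, deltas) -> dict[float, int]:
    """r_δ = max{r : F(r) ≤ δ}, or 0 when even rank 1 exceeds the risk."""
    out: dict[float, int] = {}
    for d in deltas:
        eligible = np.flatnonzero(cdf <= d)
        out[float(d)] = int(eligible[-1] + 1) if eligible.size else 0
    return out


def probe_relevance(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    R: int,
    seed: int,
    deltas=(0.05, 0.10, 0.20),
    descriptor_ids=None,
) -> ProbeResult:
    """Probe-variable relevance selection on a standardized feature matrix.

    Each of the R realizations appends an i.i.d. standard-normal probe column,
    refits the logistic regression at the same C, and ranks all N+1 columns by
    mean |φ| (background = the rows of X themselves).  Retained sets per δ are
    the descriptors whose rank in the probe-free reference fit is ≤ r_δ.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, N = X.shape
    if N == 0:
        raise ValidationError("probe_relevance needs at least one feature")
    if R < 100:
        raise ValidationError("R must be >= 100 for a usable rank CDF")
    ids = tuple(descriptor_ids) if descriptor_ids is not None else tuple(
        f"f{j}" for j in range(N)
    )
    if len(ids) != N:
        raise ValidationError("descriptor_ids length does not match X width")
    rng = np.random.default_rng(seed)

    # probe-free reference ranking
    ref_clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-8, max_iter=10_000)
    ref_clf.fit(X, y)
    dev = np.abs(X - X.mean(axis=0)).mean(axis=0)  # fixed across realizations
    ref_imp = np.abs(ref_clf.coef_[0]) * dev
    ref_ranks = _importance_ranks(ref_imp)
    reference_ranking = tuple(np.asarray(ids)[np.argsort(ref_ranks)])

    clf = LogisticRegression(
        C=C, solver="lbfgs", tol=1e-8, max_iter=10_000, warm_start=True
    )
    Xp = np.empty((n, N + 1))
    Xp[:, :N] = X
    rank_counts = np.zeros(N + 1, dtype=int)
    for _ in range(R):
        probe = rng.standard_normal(n)
        Xp[:, N] = probe
        clf.fit(Xp, y)
        w = clf.coef_[0]
        real_imp = np.abs(w[:N]) * dev
        probe_imp = abs(w[N]) * np.abs(probe - probe.mean()).mean()
        # ties go against the probe (library-order tie-break; probe is last)
        probe_rank = 1 + int(np.sum(real_imp >= probe_imp))
        rank_counts[probe_rank - 1] += 1

    cdf = np.cumsum(rank_counts) / R
    thresholds = thresholds_from_cdf(cdf, deltas)
    retained = {
        d: tuple(np.asarray(ids)[ref_ranks <= r]) for d, r in thresholds.items()
    }
    observed = np.flatnonzero(rank_counts) + 1
    return ProbeResult(
        R=R,
        n_features=N,
        rank_counts=rank_counts,
        cdf=cdf,
        thresholds=thresholds,
        retained={d: tuple(sorted(v, key=ids.index)) for d, v in retained.items()},
        min_rank=int(observed.min()),
        max_rank=int(observed.max()),
        reference_ranking=reference_ranking,
    )


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets are defined as identical (1.0)."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        warnings.warn("Jaccard of two empty sets defined as 1.0", stacklevel=2)
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class JaccardCurve:
    """Jaccard index of the top-m descriptors of two rankings, per size m."""

    sizes: tuple[int, ...]
    values: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "jaccard": self.values})


def jaccard_curve(ranked_a, ranked_b, sizes) -> JaccardCurve:
    """J(top-m of A, top-m of B) for each requested m."""
    ranked_a = list(ranked_a)
    ranked_b = list(ranked_b)
    values = []
    for m in sizes:
        if m < 1 or m > len(ranked_a) or m > len(ranked_b):
            raise ValidationError(f"size {m} outside both rankings")
        values.append(jaccard(ranked_a[:m], ranked_b[:m]))
    return JaccardCurve(tuple(int(m) for m in sizes), tuple(values))


def relevance_report(
    probe: ProbeResult,
    shap: ShapSummary,
    dataset: Dataset,
    rows=None,
    delta: float = 0.05,
) -> pd.DataFrame:
    """Per-retained-descriptor table: rank, mean |φ|, occurrence fractions.

    Occurrence fractions are the share of pre (sick) and post (healthy) rows
    in which the descriptor was detected (area > 0), plus their absolute
    difference.
    """
    if delta not in probe.retained:
        raise ValidationError(f"delta {delta} not among computed thresholds")
    rows = np.arange(dataset.n) if rows is None else np.asarray(rows)
    status = dataset.meta["status"].to_numpy()[rows]
    present = dataset.areas[rows] > 0
    id_to_col = {d: i for i, d in enumerate(dataset.library.ids)}
    id_to_shap = {d: i for i, d in enumerate(shap.descriptor_ids)}
    records = []
    for did in probe.retained[delta]:
        j = id_to_shap[did]
        col = id_to_col[did]
        frac_pre = float(present[status == "pre", col].mean()) if np.any(status == "pre") else 0.0
        frac_post = float(present[status == "post", col].mean()) if np.any(status == "post") else 0.0
        records.append(
            {
                "descriptor_id": did,
                "rank": int(shap.ranks[j]),
                "mean_abs_shap": float(shap.mean_abs[j]),
                "occurrence_pre": frac_pre,
                "occurrence_post": frac_post,
                "occurrence_abs_diff": abs(frac_pre - frac_post),
            }
        )
    frame = pd.DataFrame(
        records,
        columns=[
            "descriptor_id",
            "rank",
            "mean_abs_shap",
            "occurrence_pre",
            "occurrence_post",
            "occurrence_abs_diff",
        ],
    )
    return frame.sort_values("rank").reset_index(drop=True)
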