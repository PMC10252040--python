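"""Synthetic sweat-volatilomics cohorts with the structure the analysis assumes.

The generator emulates the descriptive statistics of vectorized GC×GC-MS
sweat screens: zero-inflated peak areas (Bernoulli presence × log-normal
abundance), U-shaped occurrence frequencies with over-represented extremes,
per-measurement non-zero descriptor counts inside a configured envelope
(77-242 for breast samplings, 82-348 for hand), per-measurement area sums
spread over about two orders of magnitude, an optional GC-column batch shift,
technical replicates correlated within a sampling event, and a planted
pre/post effect (log-scale abundance shift with descriptor-specific sign,
plus an occurrence shift) on a chosen descriptor subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Dataset, DescriptorLibrary, ValidationError


@dataclass
class GeneratorConfig:
    """Study-condition parameters for one synthetic cohort.

    ``n_subjects`` subjects all have a pre-surgery sampling; the first
    ``n_post_subjects`` also have a post-surgery sampling (class imbalance as
    in the study envelope: 21 pre vs 13 post).  ``effect_size`` is a natural-
    log abundance shift applied to planted descriptors in the pre status with
    a random per-descriptor sign; ``dropout_shift`` raises their occurrence
    probability in the pre status.  ``batch_shift`` is a natural-log offset
    applied to column2 measurements (plus per-descriptor jitter), and
    ``batch_fraction`` the fraction of subjects assigned to column1.
    """

    n_subjects: int = 21
    n_post_subjects: int | None = 13
    n_descriptors: int = 761
    site: str = "breast"
    replicates_per_sampling: int = 4
    occurrence_profile: np.ndarray | None = None
    area_log_mean: float = 11.0
    area_log_sd: float = 1.0
    area_scale_spread: float = 2.0  # orders of magnitude of per-measurement sums
    batch_shift: float = 0.0
    batch_fraction: float = 0.0
    planted_descriptors: tuple[int, ...] | None = None
    n_planted: int = 35
    effect_size: float = 3.5
    dropout_shift: float = 0.65
    nonzero_range: tuple[int, int] = (77, 242)
    subject_effect_sd: float = 0.4
    replicate_noise: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_descriptors < 1:
            raise ValidationError("n_subjects and n_descriptors must be >= 1")
        if not 1 <= self.replicates_per_sampling <= 4:
            raise ValidationError("replicates_per_sampling must be in [1, 4]")
        lo, hi = self.nonzero_range
        if lo > hi or lo < 0:
            raise ValidationError(f"bad nonzero_range {self.nonzero_range}")
        if self.planted_descriptors is not None:
            bad = [
                i
                for i in self.planted_descriptors
                if not 0 <= i < self.n_descriptors
            ]
            if bad:
                raise ValidationError(f"planted descriptor indices out of range: {bad}")
        if self.occurrence_profile is not None:
            p = np.asarray(self.occurrence_profile, dtype=float)
            if p.shape != (self.n_descriptors,) or np.any((p < 0) | (p > 1)):
                raise ValidationError("occurrence_profile must be n_descriptors probabilities in [0,1]")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def generate_occurrence_profile(
    n_descriptors: int,
    seed: int,
    extreme_fraction: float = 0.12,
    beta_shape: float = 0.3,
) -> np.ndarray:
    """Per-descriptor occurrence probabilities with a U-shaped law on [0, 1].

    A symmetric Beta(a, a) with a < 1 concentrates mass near 0 and 1; on top
    of that, a fraction of descriptors is pinned effectively-never (p ~ 0)
    and effectively-always (p ~ 1) present, matching screens where some
    library compounds appear in every chromatogram and others in none.
    """
    if n_descriptors < 1:
        raise ValidationError("n_descriptors must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.beta(beta_shape, beta_shape, size=n_descriptors)
    roles = rng.random(n_descriptors)
    p[roles < extreme_fraction] = rng.uniform(
        0.0, 0.01, size=int(np.sum(roles < extreme_fraction))
    )
    always = (roles >= extreme_fraction) & (roles < 2 * extreme_fraction)
    p[always] = rng.uniform(0.99, 1.0, size=int(np.sum(always)))
    return p


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of k items drawn without replacement, inclusion monotone in weight.

    Uses the exponential-keys trick: items with key Exp(1)/w sorted ascending;
    zero-weight items are never selected.
    """
    positive = weights > 0
    k = min(k, int(positive.sum()))
    if k == 0:
        return np.empty(0, dtype=int)
    keys = np.full(weights.shape, np.inf)
    keys[positive] = rng.exponential(size=int(positive.sum())) / weights[positive]
    return np.argpartition(keys, k - 1)[:k]


def default_library(n_descriptors: int = 761) -> DescriptorLibrary:
    ids = tuple(f"D{i:04d}" for i in range(n_descriptors))
    names = tuple(f"compound-{i:04d} (tentative)" for i in range(n_descriptors))
    return DescriptorLibrary(ids=ids, names=names)


def generate_cohort(config: GeneratorConfig) -> Dataset:
    """Draw one cohort; deterministic for a fixed config (including seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_descriptors
    profile = (
        np.asarray(config.occurrence_profile, dtype=float)
        if config.occurrence_profile is not None
        else generate_occurrence_profile(p, seed=int(rng.integers(2**31)))
    )
    planted = (
        np.asarray(config.planted_descriptors, dtype=int)
        if config.planted_descriptors is not None
        else _default_planted(profile, config.n_planted, rng)
    )
    effect_sign = rng.choice([-1.0, 1.0], size=planted.size)
    batch_jitter = rng.normal(0.0, 0.1 * abs(config.batch_shift), size=p)

    n_post = config.n_post_subjects if config.n_post_subjects is not None else config.n_subjects
    n_post = min(n_post, config.n_subjects)
    n_col1 = int(round(config.batch_fraction * config.n_subjects))
    lo, hi = config.nonzero_range
    lo = min(lo, p)
    hi = min(hi, p)

    meta_rows = []
    area_rows = []
    ln10 = np.log(10.0)
    subject_effect = rng.normal(0.0, config.subject_effect_sd, size=(config.n_subjects, p))
    for s in range(config.n_subjects):
        subject_id = f"S{s:03d}"
        batch = "column1" if s < n_col1 else "column2"
        statuses = ["pre"] + (["post"] if s < n_post else [])
        for status in statuses:
            weights = profile.copy()
            if status == "pre" and config.dropout_shift:
                # detection follows abundance: occurrence shifts in the same
                # direction as the planted log-abundance effect
                weights[planted] = np.clip(
                    weights[planted] + config.dropout_shift * effect_sign, 0.0, 1.0
                )
            sampling_scale = rng.uniform(-0.5, 0.5) * config.area_scale_spread * ln10
            for replicate in range(1, config.replicates_per_sampling + 1):
                target = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                present = _weighted_sample_without_replacement(weights, target, rng)
                loc = (
                    config.area_log_mean
                    + subject_effect[s]
                    + sampling_scale
                    + rng.normal(0.0, config.replicate_noise)
                )
                if batch == "column2" and config.batch_shift:
                    loc = loc + config.batch_shift + batch_jitter
                shift = np.zeros(p)
                if status == "pre" and config.effect_size:
                    shift[planted] = config.effect_size * effect_sign
                noise = rng.normal(0.0, config.area_log_sd, size=p)
                log_area_full = loc + shift + noise
                areas = np.zeros(p)
                areas[present] = np.exp(log_area_full[present])
                meta_rows.append(
                    {
                        "subject_id": subject_id,
                        "site": config.site,
                        "status": status,
                        "batch": batch,
                        "replicate": replicate,
                    }
                )
                area_rows.append(areas)
    meta = pd.DataFrame(meta_rows)
    dataset = Dataset(
        default_library(p), meta, np.vstack(area_rows), transform_state="raw"
    )
    dataset.planted_descriptors = tuple(int(i) for i in planted)  # provenance
    return dataset


def _default_planted(profile: np.ndarray, n_planted: int, rng: np.random.Generator) -> np.ndarray:
    """Plant effects on mid-occurrence descriptors, where an occurrence shift
    in either direction has room to act."""
    candidates = np.flatnonzero((profile > 0.30) & (profile < 0.70))
    if candidates.size < n_planted:
        candidates = np.argsort(-profile)[: max(n_planted, 1)]
    return rng.choice(candidates, size=min(n_planted, candidates.size), replace=False)


@dataclass
class PairConfig:
    """Options for the study-envelope two-site cohort pair."""

    planted_overlap: float = 0.3
    n_planted: int = 35
    effect_size: float = 3.5
    dropout_shift: float = 0.65
    replicates_per_sampling: int = 4
    n_descriptors: int = 761
    extra: dict = field(default_factory=dict)


def make_study_pair(
    seed: int, pair_config: PairConfig | None = None
) -> tuple[Dataset, Dataset]:
    """Breast-like and hand-like cohorts sized like the study envelope.

    21 pre-surgery subjects, 13 with a post-surgery sampling, up to 4
    technical replicates; per-measurement non-zero counts inside 77-242
    (breast) and 82-348 (hand); the planted descriptor sets of the two sites
    overlap by ``planted_overlap`` (fraction of the planted size).
    """
    pc = pair_config or PairConfig()
    rng = np.random.default_rng(seed)
    p = pc.n_descriptors
    n_overlap = int(round(pc.planted_overlap * pc.n_planted))
    profile_seed = int(rng.integers(2**31))
    profile = generate_occurrence_profile(p, seed=profile_seed)
    candidates = np.flatnonzero((profile > 0.30) & (profile < 0.70))
    need = 2 * pc.n_planted - n_overlap
    if candidates.size < need:
        candidates = np.argsort(-profile)[:need]
    chosen = rng.choice(candidates, size=need, replace=False)
    shared = chosen[:n_overlap]
    breast_planted = tuple(int(i) for i in np.concatenate([shared, chosen[n_overlap : pc.n_planted]]))
    hand_planted = tuple(int(i) for i in np.concatenate([shared, chosen[pc.n_planted :]]))

    common = dict(
        n_subjects=21,
        n_post_subjects=13,
        n_descriptors=p,
        replicates_per_sampling=pc.replicates_per_sampling,
        occurrence_profile=profile,
        effect_size=pc.effect_size,
        dropout_shift=pc.dropout_shift,
        **pc.extra,
    )
    breast = generate_cohort(
        GeneratorConfig(
            site="breast",
            planted_descriptors=breast_planted,
            nonzero_range=(77, 242),
            seed=int(rng.integers(2**31)),
            **common,
        )
    )
    hand = generate_cohort(
        GeneratorConfig(
            site="hand",
            planted_descriptors=hand_planted,
            nonzero_range=(82, 348),
            seed=int(rng.integers(2**31)),
            **common,
        )
    )
    return breast, hand
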