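"""The AU match score and everything built directly on it.

The match score between two sets of activated AUs is the Dice-style
overlap statistic

    m = 2 * |A ∩ B| / (|A| + |B|)

which is 0 for disjoint sets and 1 for identical non-empty sets.  Poses
are scored against a category by evaluating m against every hypothesized
variant and combining the per-variant scores (median by default, a
compromise between the liberal max and the conservative min).  Dynamic
AUs, which cannot be coded from static photographs, are handled by a
base-rate imputation simulation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .core import AUCoding, CODABLE_AUS, ConfigurationRegistry

log = logging.getLogger(__name__)

_AGGREGATIONS = {
    "median": np.median,
    "max": np.max,
    "min": np.min,
}


class UnscorablePoseError(ValueError):
    """A pose has no activated AUs after filtering and cannot be scored."""


@dataclass(frozen=True)
class MatchScore:
    """Dice-style overlap score between two AU sets: m = 2*overlap/total."""

    value: float
    overlap: int
    total: int


def match_score(a: Iterable[int], b: Iterable[int]) -> MatchScore:
    """Match score between two sets of activated AUs.

    Symmetric; raises if both sets are empty (0/0 undefined).
    """
    sa, sb = frozenset(a), frozenset(b)
    total = len(sa) + len(sb)
    if total == 0:
        raise UnscorablePoseError("match score undefined for two empty AU sets")
    overlap = len(sa & sb)
    return MatchScore(value=2.0 * overlap / total, overlap=overlap, total=total)


def _aggregate(scores: Sequence[float], aggregation: str) -> float:
    try:
        fn = _AGGREGATIONS[aggregation]
    except KeyError:
        raise ValueError(
            f"unknown aggregation {aggregation!r}; choose from "
            f"{sorted(_AGGREGATIONS)}"
        )
    return float(fn(scores))


def variant_scores(pose_aus: FrozenSet[int], category: str,
                   registry: ConfigurationRegistry) -> List[float]:
    """Match score of an AU set against each of a category's variants."""
    return [match_score(pose_aus, v.au_set).value
            for v in registry[category]]


def pose_vs_category(pose: AUCoding, category: str,
                     registry: ConfigurationRegistry,
                     aggregation: str = "median",
                     intensity_floor: Optional[int] = None) -> float:
    """Score one pose against a category's hypothesized variants.

    The pose's activated AU set (optionally restricted to intensities at
    or above ``intensity_floor``) is scored against every variant; the
    per-variant scores are combined by ``aggregation`` (median, max, min).
    """
    aus = pose.activated(intensity_floor)
    if not aus:
        raise UnscorablePoseError(
            f"pose {pose.pose_id}: no activated AUs after filtering"
        )
    return _aggregate(variant_scores(aus, category, registry), aggregation)


def median_base_rate(codings: Sequence[AUCoding],
                     aus: Iterable[int] = CODABLE_AUS) -> float:
    """Median per-AU activation frequency across poses.

    Computes each codable AU's activation frequency over the pose
    collection, then the median across AUs.  Used as the imputation rate
    for dynamic AUs, on the assumption that uncoded AUs occur about as
    often as coded ones.
    """
    if not codings:
        raise ValueError("median_base_rate requires at least one coding")
    aus = sorted(aus)
    n = len(codings)
    counts = {au: 0 for au in aus}
    for c in codings:
        for au in c.activated():
            if au in counts:
                counts[au] += 1
    return float(np.median([counts[au] / n for au in aus]))


@dataclass(frozen=True)
class ImputationSpec:
    """Monte-Carlo settings for dynamic-AU imputation.

    Each missing AU is independently added to a pose with probability
    ``base_rate`` in each of ``iterations`` draws; the reported score is
    the median over draws.
    """

    base_rate: float
    iterations: int = 1000
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0.0 <= self.base_rate <= 1.0):
            raise ValueError(f"base_rate {self.base_rate} outside [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def imputed_match(pose: AUCoding, category: str,
                  registry: ConfigurationRegistry,
                  spec: ImputationSpec,
                  aggregation: str = "median",
                  intensity_floor: Optional[int] = None) -> float:
    """Reliability of a pose against a category with uncodable AUs.

    The category's dynamic AUs that are absent from the pose are treated
    as missing: in each iteration, each is coded present with probability
    ``spec.base_rate``, the augmented pose is scored with
    :func:`pose_vs_category` semantics, and the median score across
    iterations is returned.  Seeded and reproducible.
    """
    base = pose.activated(intensity_floor)
    if not base:
        raise UnscorablePoseError(
            f"pose {pose.pose_id}: no activated AUs after filtering"
        )
    missing = sorted(registry.dynamic_aus(category) - base)
    if not missing:
        return _aggregate(variant_scores(base, category, registry), aggregation)
    rng = np.random.default_rng(spec.seed)
    draws = rng.random((spec.iterations, len(missing))) < spec.base_rate
    # Only 2^k distinct augmented sets exist; cache their scores.
    cache: Dict[FrozenSet[int], float] = {}
    scores = np.empty(spec.iterations)
    for i, row in enumerate(draws):
        added = frozenset(au for au, hit in zip(missing, row) if hit)
        if added not in cache:
            cache[added] = _aggregate(
                variant_scores(base | added, category, registry), aggregation
            )
        scores[i] = cache[added]
    return float(np.median(scores))


def consolidate_coders(codings: Sequence[AUCoding],
                       pose_id: Optional[str] = None) -> AUCoding:
    """Collapse several coders' codings of one pose into one coding.

    An AU is present iff a strict majority of coders marked it present;
    its intensity is the rounded median of the intensities given by the
    coders who marked it present.
    """
    if not codings:
        raise ValueError("consolidate_coders requires at least one coding")
    pid = pose_id or codings[0].pose_id
    n = len(codings)
    levels: Dict[int, List[int]] = {}
    for c in codings:
        for au, level in c.intensity.items():
            levels.setdefault(au, []).append(level)
    intensity = {
        au: int(round(float(np.median(vals))))
        for au, vals in levels.items()
        if 2 * len(vals) > n
    }
    return AUCoding(pose_id=pid, coder_id="consensus", intensity=intensity)


@dataclass
class IntercoderReliability:
    """Pairwise inter-coder agreement summarized per pose and overall."""

    per_pose: pd.Series                  # pose_id -> median pairwise m
    overall_median: float
    iqr: tuple                           # (25th, 75th percentile)
    excluded: List[str] = field(default_factory=list)
    per_category: Optional[pd.DataFrame] = None


def intercoder_reliability(
    codings: Sequence[AUCoding],
    assignments: Optional[Mapping[str, str]] = None,
) -> IntercoderReliability:
    """Pairwise match scores between coders, per pose and overall.

    For each pose coded by >= 2 coders, the pose value is the median of
    the pairwise match scores between coders' activated-AU sets; poses
    with fewer than two coders (or no scorable pair) are excluded with a
    log entry.  If ``assignments`` maps pose ids to categories, a
    per-category summary (median and IQR) is included.
    """
    by_pose: Dict[str, List[AUCoding]] = {}
    for c in codings:
        by_pose.setdefault(c.pose_id, []).append(c)

    values: Dict[str, float] = {}
    excluded: List[str] = []
    for pid, group in by_pose.items():
        if len(group) < 2:
            excluded.append(pid)
            log.info("pose %s has <2 coders; excluded from ICR", pid)
            continue
        pair_scores = []
        for a, b in itertools.combinations(group, 2):
            try:
                pair_scores.append(match_score(a.activated(), b.activated()).value)
            except UnscorablePoseError:
                continue
        if not pair_scores:
            excluded.append(pid)
            log.info("pose %s has no scorable coder pair; excluded", pid)
            continue
        values[pid] = float(np.median(pair_scores))

    if not values:
        raise ValueError("no pose has two or more coders with activated AUs")
    per_pose = pd.Series(values, name="icr").sort_index()
    q25, q75 = np.percentile(per_pose.values, [25, 75])

    per_cat = None
    if assignments is not None:
        rows = []
        cat_series = per_pose.groupby(
            per_pose.index.map(lambda p: assignments.get(p))
        )
        for cat, vals in cat_series:
            if cat is None:
                continue
            lo, hi = np.percentile(vals.values, [25, 75])
            rows.append({"category": cat, "n_poses": len(vals),
                         "median_icr": float(vals.median()),
                         "iqr_low": float(lo), "iqr_high": float(hi)})
        per_cat = pd.DataFrame(rows).set_index("category") if rows else None

    return IntercoderReliability(
        per_pose=per_pose,
        overall_median=float(per_pose.median()),
        iqr=(float(q25), float(q75)),
        excluded=sorted(excluded),
        per_category=per_cat,
    )
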