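"""Inductive discovery of expression categories.

Scenario emotion profiles are clustered hierarchically; the linkage
method and distance metric are selected by cophenetic correlation, and
the cut level is selected by maximizing the median within-cluster match
score of the associated facial poses — i.e., clusters are discovered from
what raters perceived, then judged by how consistently the actors moved
their faces within each cluster.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .core import AUCoding, CATEGORIES, ConfigurationRegistry, ValidationError
from .matching import match_score

log = logging.getLogger(__name__)

#: Default linkage/metric candidates.  Geometric methods (centroid,
#: median, ward) are only defined for Euclidean distances.
DEFAULT_METHODS = ("single", "complete", "average", "weighted",
                   "centroid", "median", "ward")
DEFAULT_METRICS = ("euclidean", "cityblock", "cosine", "correlation")
_EUCLIDEAN_ONLY = {"centroid", "median", "ward"}


def profile_distances(profiles: pd.DataFrame, metric: str = "euclidean"
                      ) -> np.ndarray:
    """Condensed pairwise distances between scenario emotion profiles."""
    X = profiles[list(CATEGORIES)].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least two profiles")
    if X.shape[1] != len(CATEGORIES):
        raise ValidationError("profiles must have 13 category columns")
    return pdist(X, metric=metric)


@dataclass(frozen=True)
class LinkageEvaluation:
    """One linkage/metric candidate and its cophenetic correlation."""

    method: str
    metric: str
    cophenetic_c: float
    linkage_matrix: np.ndarray = field(repr=False, compare=False, default=None)


def select_linkage(
    profiles: pd.DataFrame,
    methods: Sequence[str] = DEFAULT_METHODS,
    metrics: Sequence[str] = DEFAULT_METRICS,
    tie_tolerance: float = 1e-9,
) -> Tuple[LinkageEvaluation, List[LinkageEvaluation]]:
    """Choose the linkage method and metric by cophenetic correlation.

    Every valid method x metric candidate is fitted and scored by the
    correlation between original pairwise distances and the cophenetic
    distances of its tree.  The highest c wins; candidates within
    ``tie_tolerance`` of the best are tied, and ties prefer average
    linkage (within-cluster homogeneity over centroid separation), then
    candidate order.  Returns (winner, all evaluations).
    """
    if len(profiles) < 3:
        raise ValidationError("need at least three profiles to cluster")
    evals: List[LinkageEvaluation] = []
    for metric in metrics:
        d = profile_distances(profiles, metric=metric)
        if not np.all(np.isfinite(d)):
            log.info("metric %s produced non-finite distances; skipped", metric)
            continue
        if np.all(d == 0):
            raise ValidationError("all profiles identical; clustering degenerate")
        for method in methods:
            if method in _EUCLIDEAN_ONLY and metric != "euclidean":
                continue
            Z = linkage(d, method=method)
            c, _ = cophenet(Z, d)
            if not np.isfinite(c):
                continue
            evals.append(LinkageEvaluation(method, metric, float(c), Z))
    if not evals:
        raise ValidationError("no linkage candidate could be evaluated")
    best_c = max(e.cophenetic_c for e in evals)
    tied = [e for e in evals if best_c - e.cophenetic_c <= tie_tolerance]
    winner = next((e for e in tied if e.method == "average"), tied[0])
    return winner, evals


def intra_cluster_m(codings: Sequence[AUCoding]) -> float:
    """Median pairwise match score among a cluster's member poses.

    Undefined for singletons (raises ValueError): a single pose yields no
    pairs.
    """
    if len(codings) < 2:
        raise ValueError("intra-cluster match score undefined for singletons")
    scores = [
        match_score(a.activated(), b.activated()).value
        for a, b in itertools.combinations(codings, 2)
    ]
    return float(np.median(scores))


@dataclass
class ClusterSolution:
    """A chosen cut of the hierarchy and its within-cluster reliability."""

    cut_k: int
    clusters: Dict[int, List[str]]            # cluster id -> stimulus ids
    per_cluster_median_m: Dict[int, float]    # non-singleton clusters only
    overall_median_m: float
    scan: pd.DataFrame = field(repr=False, default=None)  # k, overall_median_m


def _pair_matrix(stimulus_ids: Sequence[str],
                 poses: Mapping[str, AUCoding]) -> np.ndarray:
    """Dense symmetric matrix of pairwise pose match scores."""
    sets = [poses[s].activated() for s in stimulus_ids]
    n = len(sets)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = match_score(sets[i], sets[j]).value
    return M


def select_cut(
    Z: np.ndarray,
    stimulus_ids: Sequence[str],
    poses: Mapping[str, AUCoding],
    pooling: str = "pooled",
) -> ClusterSolution:
    """Scan every cut of the tree and keep the most reliable solution.

    For each number of clusters k = 1..n the tree is cut and the solution
    is scored by the median within-cluster pairwise match score of the
    member poses.  ``pooling="pooled"`` (default) pools all within-cluster
    pairs across non-singleton clusters before taking the median;
    ``pooling="median_of_medians"`` takes the median of per-cluster
    medians.  Singleton clusters contribute no pairs.  The maximizing k is
    returned, smallest k on ties.
    """
    if pooling not in ("pooled", "median_of_medians"):
        raise ValueError(f"unknown pooling {pooling!r}")
    ids = [str(s) for s in stimulus_ids]
    n = len(ids)
    missing = [s for s in ids if s not in poses]
    if missing:
        raise ValidationError(f"stimuli without poses: {missing[:10]}")
    M = _pair_matrix(ids, poses)

    rows = []
    best: Optional[Tuple[float, int, np.ndarray]] = None
    for k in range(1, n + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        value = _cut_score(M, labels, pooling)
        rows.append({"k": k, "n_clusters": int(len(np.unique(labels))),
                     "overall_median_m": value})
        if value is not None and (best is None or value > best[0]):
            best = (value, k, labels)
    if best is None:
        raise ValidationError("every cut yields only singleton clusters")

    value, k, labels = best
    clusters: Dict[int, List[str]] = {}
    for sid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(sid)
    per_cluster = {}
    for cid, members in clusters.items():
        if len(members) >= 2:
            per_cluster[cid] = intra_cluster_m([poses[s] for s in members])
    scan = pd.DataFrame(rows)
    return ClusterSolution(
        cut_k=k, clusters=clusters, per_cluster_median_m=per_cluster,
        overall_median_m=float(value), scan=scan,
    )


def _cut_score(M: np.ndarray, labels: np.ndarray, pooling: str
               ) -> Optional[float]:
    values: List[float] = []
    per_cluster: List[float] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        sub = M[np.ix_(idx, idx)]
        pair_vals = sub[np.triu_indices(len(idx), k=1)]
        values.extend(pair_vals)
        per_cluster.append(float(np.median(pair_vals)))
    if not values:
        return None
    if pooling == "pooled":
        return float(np.median(values))
    return float(np.median(per_cluster))


@dataclass
class ClusterProfile:
    """Characterization of one inductive cluster against the registry.

    ``common_au_set`` holds the AUs whose median intensity across member
    poses (absent = 0) is at least moderate (FACS level C = 3).
    ``category_scores`` maps each registry category to its match score
    (dynamic AUs assumed active in the poses, an upper bound);
    ``matched_prototypes`` counts categories scoring >= 0.4.
    """

    cluster_id: int
    common_au_set: FrozenSet[int]
    category_scores: Dict[str, Optional[float]]
    matched_prototypes: int
    associated_categories: List[str]
    method: str = "common_set"


def characterize_cluster(
    cluster_id: int,
    members: Sequence[str],
    poses: Mapping[str, AUCoding],
    registry: ConfigurationRegistry,
    assignments: Optional[Mapping[str, str]] = None,
    method: str = "common_set",
    match_threshold: float = 0.4,
    moderate_intensity: int = 3,
) -> ClusterProfile:
    """Score one non-singleton cluster against every hypothesized category.

    Two methods are supported.  ``common_set``: build the cluster's common
    AU set (median intensity across members >= moderate, absent counted as
    0), score it against each category's variants and keep the maximum.
    ``per_pose_median``: score each member pose (all AUs, any intensity)
    against each category (max over variants) and take the median across
    members.  In both, each category's dynamic AUs are assumed active on
    the pose side, producing upper-bound scores for categories whose
    configurations could not be fully coded.
    """
    if len(members) < 2:
        raise ValueError("cannot characterize a singleton cluster")
    if method not in ("common_set", "per_pose_median"):
        raise ValueError(f"unknown method {method!r}")
    member_poses = [poses[str(s)] for s in members]

    all_aus = sorted({au for p in member_poses for au in p.intensity})
    common = frozenset(
        au for au in all_aus
        if np.median([p.intensity.get(au, 0) for p in member_poses])
        >= moderate_intensity
    )

    scores: Dict[str, Optional[float]] = {}
    for cat in registry.categories:
        dyn = registry.dynamic_aus(cat)
        if method == "common_set":
            if not common and not dyn:
                scores[cat] = None
                log.info("cluster %s: empty common AU set; %s unscored",
                         cluster_id, cat)
                continue
            pose_side = common | dyn
            scores[cat] = max(
                match_score(pose_side, v.au_set).value
                for v in registry[cat]
            )
        else:
            per_pose = [
                max(match_score(p.activated() | dyn, v.au_set).value
                    for v in registry[cat])
                for p in member_poses
            ]
            scores[cat] = float(np.median(per_pose))

    matched = sum(
        1 for v in scores.values() if v is not None and v >= match_threshold
    )
    associated = sorted({
        assignments[str(s)] for s in members
        if assignments is not None and str(s) in assignments
    })
    return ClusterProfile(
        cluster_id=cluster_id, common_au_set=common, category_scores=scores,
        matched_prototypes=matched, associated_categories=associated,
        method=method,
    )
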