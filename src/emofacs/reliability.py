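"""Supervised reliability and specificity of hypothesized configurations.

For each emotion category, the poses of its assigned scenarios are scored
against the category's hypothesized configuration (median over variants).
Reliability is summarized by the match-score distribution and tested by a
Bayesian interval-hypothesis binomial model comparison; specificity is
the complement of the false positive rate p̂_e = k_e / n_e, with a
Jeffreys-prior credibility interval and a one-tailed posterior test
against the chance rate.  A multiverse runner re-executes both analyses
over a factorial grid of defensible analytic choices.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import (AUCoding, CATEGORIES, ConfigurationRegistry, band_of)
from .matching import (ImputationSpec, UnscorablePoseError, imputed_match,
                       pose_vs_category)
from .ratings import CategoryAssignment

log = logging.getLogger(__name__)

#: Interval hypotheses for the Bayesian reliability test: the null spans
#: the none+weak bands, the alternatives the moderate and high bands.
DEFAULT_HYPOTHESES = {
    "null": (0.0, 0.4),
    "moderate": (0.4, 0.7),
    "high": (0.7, 1.0),
}

#: Chance false-positive threshold: 1 out of the 9 testable categories.
CHANCE_RATE = 1.0 / 9.0


@dataclass(frozen=True)
class ReliabilityOptions:
    """Analytic choices for the supervised reliability pipeline."""

    aggregation: str = "median"           # over configuration variants
    intensity_floor: Optional[int] = None  # None = any intensity
    match_threshold: float = 0.4          # m >= this counts as a match
    imputation_iterations: int = 1000
    base_rate: Optional[float] = None     # None = compute from codings
    seed: Optional[int] = None


@dataclass
class ReliabilityResult:
    """Per-category match-score distribution and its reliability band."""

    category: str
    match_scores: pd.Series          # pose_id -> m
    median_m: float
    band: str
    simulated: bool                  # dynamic-AU imputation used
    unscorable: List[str] = field(default_factory=list)


def category_reliability(
    assignments: Mapping[str, CategoryAssignment],
    poses: Mapping[str, AUCoding],
    registry: ConfigurationRegistry,
    options: ReliabilityOptions = ReliabilityOptions(),
    base_rate: Optional[float] = None,
) -> Dict[str, ReliabilityResult]:
    """Match-score distribution per category over its assigned scenarios.

    Categories whose every variant contains dynamic AUs are scored with
    :func:`~emofacs.matching.imputed_match` at the supplied base rate
    (``simulated`` flag set); the rest use direct pose-vs-category
    scoring.  Poses left without activated AUs by the intensity filter
    are excluded with a log entry.
    """
    rate = options.base_rate if options.base_rate is not None else base_rate
    by_cat: Dict[str, List[str]] = {c: [] for c in registry.categories}
    for sid, a in assignments.items():
        by_cat[a.category].append(sid)

    results: Dict[str, ReliabilityResult] = {}
    for i, cat in enumerate(registry.categories):
        members = sorted(by_cat[cat])
        simulated = registry.is_simulation_required(cat)
        if simulated and rate is None:
            raise ValueError(
                f"category {cat} requires imputation but no base rate given"
            )
        scores: Dict[str, float] = {}
        unscorable: List[str] = []
        for sid in members:
            pose = poses[sid]
            try:
                if simulated:
                    spec = ImputationSpec(
                        base_rate=rate,
                        iterations=options.imputation_iterations,
                        seed=None if options.seed is None
                        else options.seed + 1000 * i + _stable_hash(sid),
                    )
                    m = imputed_match(pose, cat, registry, spec,
                                      aggregation=options.aggregation,
                                      intensity_floor=options.intensity_floor)
                else:
                    m = pose_vs_category(pose, cat, registry,
                                         aggregation=options.aggregation,
                                         intensity_floor=options.intensity_floor)
            except UnscorablePoseError:
                unscorable.append(sid)
                log.info("pose %s unscorable for %s; excluded", sid, cat)
                continue
            scores[sid] = m
        series = pd.Series(scores, dtype=float, name=cat).sort_index()
        if series.empty:
            log.info("category %s has no scorable scenarios", cat)
            results[cat] = ReliabilityResult(cat, series, float("nan"),
                                             "none", simulated, unscorable)
            continue
        med = float(series.median())
        results[cat] = ReliabilityResult(
            category=cat, match_scores=series, median_m=med,
            band=band_of(med), simulated=simulated, unscorable=unscorable,
        )
    return results


def _stable_hash(s: str) -> int:
    """Deterministic small hash (process-independent, unlike hash())."""
    h = 0
    for ch in str(s):
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


@dataclass
class BayesComparison:
    """Interval-hypothesis binomial model comparison.

    Marginal likelihood of hypothesis H = [a, b):
    ``∫ C(n,k) θ^k (1-θ)^(n-k) / (b - a) dθ`` over [a, b] — a uniform
    prior on θ within the interval.  Bayes factors are reported against
    the null interval.
    """

    category: str
    k: int
    n: int
    hypotheses: Dict[str, Tuple[float, float]]
    marginal_likelihoods: Dict[str, float]
    bayes_factors: Dict[str, float]
    best: str


def bayes_reliability(
    k: int,
    n: int,
    hypotheses: Mapping[str, Tuple[float, float]] = None,
    category: str = "",
    null: str = "null",
) -> BayesComparison:
    """Compare interval hypotheses about the match rate θ = P(m >= 0.4).

    Marginal likelihoods are computed in closed form from the regularized
    incomplete beta function; the hypothesis intervals must partition
    [0, 1].
    """
    hyps = dict(hypotheses) if hypotheses is not None else dict(DEFAULT_HYPOTHESES)
    if n <= 0:
        raise ValueError("bayes_reliability requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    edges = sorted(hyps.values())
    if edges[0][0] != 0.0 or edges[-1][1] != 1.0 or any(
        edges[i][1] != edges[i + 1][0] for i in range(len(edges) - 1)
    ):
        raise ValueError(f"hypothesis intervals must partition [0, 1]: {hyps}")
    if null not in hyps:
        raise ValueError(f"null hypothesis {null!r} not among {sorted(hyps)}")

    ml: Dict[str, float] = {}
    logC = (special.gammaln(n + 1) - special.gammaln(k + 1)
            - special.gammaln(n - k + 1))
    logB = special.betaln(k + 1, n - k + 1)
    for name, (a, b) in hyps.items():
        mass = (special.betainc(k + 1, n - k + 1, b)
                - special.betainc(k + 1, n - k + 1, a))
        # Guard against underflow to keep marginals positive.
        ml[name] = max(math.exp(logC + logB) * mass / (b - a), 5e-324)
    bf = {name: ml[name] / ml[null] for name in hyps}
    best = max(ml, key=ml.get)
    return BayesComparison(category=category, k=k, n=n, hypotheses=hyps,
                           marginal_likelihoods=ml, bayes_factors=bf,
                           best=best)


def reliability_bayes_tests(
    reliability: Mapping[str, ReliabilityResult],
    match_threshold: float = 0.4,
    hypotheses: Mapping[str, Tuple[float, float]] = None,
) -> Dict[str, BayesComparison]:
    """Run the Bayesian model comparison for every non-empty category."""
    out = {}
    for cat, res in reliability.items():
        n = len(res.match_scores)
        if n == 0:
            continue
        k = int((res.match_scores >= match_threshold).sum())
        out[cat] = bayes_reliability(k, n, hypotheses, category=cat)
    return out


@dataclass
class SpecificityResult:
    """False positive rate p̂_e = k_e / n_e and its complement.

    ``credibility_interval`` is the equal-tailed 95% interval of the
    Jeffreys Beta(k+1/2, n-k+1/2) posterior on the false-positive
    probability θ; ``posterior_prob_exceeds_chance`` is P(θ > chance)
    under the same posterior (one-tailed Bayesian binomial test).
    """

    category: str
    k_e: int
    n_e: int
    p_hat_e: float
    specificity: float
    credibility_interval: Tuple[float, float]
    posterior_prob_exceeds_chance: float
    chance: float = CHANCE_RATE


def false_positive_rate(
    category: str,
    poses: Mapping[str, AUCoding],
    registry: ConfigurationRegistry,
    profiles: pd.DataFrame,
    match_threshold: float = 0.4,
    target_lt: float = 2.0,
    other_gt: float = 2.0,
    aggregation: str = "median",
    intensity_floor: Optional[int] = None,
    chance: float = CHANCE_RATE,
    ci_level: float = 0.95,
    stimulus_ids: Optional[Sequence[str]] = None,
) -> SpecificityResult:
    """False-positive-rate specificity for one category across all poses.

    ``n_e`` counts poses (over all scenarios, or ``stimulus_ids`` if
    given) whose match to the category's configuration is at least
    ``match_threshold``; ``k_e`` counts those whose scenario profile has
    a median rating for the category below ``target_lt`` while some other
    category's median exceeds ``other_gt`` — poses that look like the
    category but were evoked by scenarios rated as other emotions.
    Not defined for simulation-required categories.
    """
    if registry.is_simulation_required(category):
        raise ValueError(
            f"specificity undefined for simulation-required category "
            f"{category!r} (dynamic AUs cannot be observed)"
        )
    ids = [str(s) for s in (stimulus_ids if stimulus_ids is not None
                            else profiles.index)]
    others = [c for c in registry.categories if c != category]
    n_e = 0
    k_e = 0
    for sid in ids:
        pose = poses[sid]
        try:
            m = pose_vs_category(pose, category, registry,
                                 aggregation=aggregation,
                                 intensity_floor=intensity_floor)
        except UnscorablePoseError:
            continue
        if m < match_threshold:
            continue
        n_e += 1
        row = profiles.loc[sid]
        if row[category] < target_lt and any(row[c] > other_gt for c in others):
            k_e += 1
    if n_e == 0:
        raise ValueError(
            f"no pose matches {category!r} at m >= {match_threshold}; "
            "specificity undefined"
        )
    p_hat = k_e / n_e
    lo, hi = jeffreys_interval(k_e, n_e, level=ci_level)
    post = float(stats.beta.sf(chance, k_e + 0.5, n_e - k_e + 0.5))
    return SpecificityResult(
        category=category, k_e=k_e, n_e=n_e, p_hat_e=p_hat,
        specificity=1.0 - p_hat, credibility_interval=(lo, hi),
        posterior_prob_exceeds_chance=post, chance=chance,
    )


def jeffreys_interval(k: int, n: int, level: float = 0.95
                      ) -> Tuple[float, float]:
    """Equal-tailed credibility interval under the Jeffreys prior."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k + 0.5,
                                                 n - k + 0.5))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 0.5,
                                                 n - k + 0.5))
    return lo, hi


#: Default multiverse axes: the analytic choices with more than one
#: defensible level.
DEFAULT_AXES = {
    "aggregation": ["median", "max", "min"],
    "intensity_floor": [None, 3],
    "match_threshold": [0.4],
}


@dataclass
class MultiverseCell:
    """One grid cell: its choices and per-category summaries."""

    choices: Dict[str, object]
    reliability_medians: Dict[str, float]
    specificity: Dict[str, float]
    error: Optional[str] = None


@dataclass
class MultiverseSummary:
    cells: List[MultiverseCell]
    table: pd.DataFrame
    reliability_mean: float
    reliability_sd: float
    specificity_mean: float
    specificity_sd: float


def run_multiverse(
    assignments: Mapping[str, CategoryAssignment],
    poses: Mapping[str, AUCoding],
    registry: ConfigurationRegistry,
    profiles: pd.DataFrame,
    axes: Mapping[str, Sequence] = None,
    base_rate: Optional[float] = None,
    base_options: ReliabilityOptions = ReliabilityOptions(),
) -> MultiverseSummary:
    """Re-run reliability and specificity over a factorial grid of choices.

    ``axes`` maps option names of :class:`ReliabilityOptions` (plus
    ``match_threshold``) to lists of levels; every combination is one
    cell.  Cell failures are recorded and do not stop the run.  Summary
    means/SDs are taken over per-cell, per-category medians.
    """
    axes = dict(axes) if axes is not None else dict(DEFAULT_AXES)
    names = sorted(axes)
    cells: List[MultiverseCell] = []
    rows = []
    for combo in itertools.product(*(axes[n] for n in names)):
        choices = dict(zip(names, combo))
        opts = replace(base_options, **{
            k: v for k, v in choices.items()
            if k in ReliabilityOptions.__dataclass_fields__
        })
        try:
            rel = category_reliability(assignments, poses, registry, opts,
                                       base_rate=base_rate)
            rel_medians = {c: r.median_m for c, r in rel.items()
                           if len(r.match_scores) > 0}
            spec: Dict[str, float] = {}
            for cat in registry.categories:
                if registry.is_simulation_required(cat):
                    continue
                try:
                    res = false_positive_rate(
                        cat, poses, registry, profiles,
                        match_threshold=opts.match_threshold,
                        aggregation=opts.aggregation,
                        intensity_floor=opts.intensity_floor,
                    )
                    spec[cat] = res.specificity
                except ValueError:
                    continue
            cell = MultiverseCell(choices, rel_medians, spec)
        except Exception as exc:  # cell failure: record, continue
            log.warning("multiverse cell %s failed: %s", choices, exc)
            cell = MultiverseCell(choices, {}, {}, error=str(exc))
        cells.append(cell)
        row = dict(cell.choices)
        row["error"] = cell.error
        vals = [v for v in cell.reliability_medians.values()
                if np.isfinite(v)]
        row["median_reliability"] = float(np.median(vals)) if vals else np.nan
        svals = list(cell.specificity.values())
        row["median_specificity"] = float(np.median(svals)) if svals else np.nan
        rows.append(row)

    table = pd.DataFrame(rows)
    all_rel = [v for c in cells for v in c.reliability_medians.values()
               if np.isfinite(v)]
    all_spec = [v for c in cells for v in c.specificity.values()]
    return MultiverseSummary(
        cells=cells, table=table,
        reliability_mean=float(np.mean(all_rel)) if all_rel else float("nan"),
        reliability_sd=float(np.std(all_rel, ddof=1)) if len(all_rel) > 1
        else float("nan"),
        specificity_mean=float(np.mean(all_spec)) if all_spec else float("nan"),
        specificity_sd=float(np.std(all_spec, ddof=1)) if len(all_spec) > 1
        else float("nan"),
    )
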