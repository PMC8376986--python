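"""Rater-panel aggregation: emotion profiles, category assignment,
intensity subsets and the complexity index.

Ratings use the "unambiguous Likert" convention: a NO response is encoded
as 0, a YES response carries its intensity 1-4, so every rating is an
integer on [0, 4] and per-category medians are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CATEGORIES, N_CATEGORIES, EmotionProfile, ValidationError

log = logging.getLogger(__name__)

RATING_COLUMNS = ["rater_id", "stimulus_id", "condition", "category", "value"]


@dataclass(frozen=True)
class CategoryAssignment:
    """A stimulus's assigned emotion category and how the tie was broken.

    ``tiebreak_level`` records the deepest rule actually used: ``median``
    (unique highest median), ``iqr`` (smallest interquartile range among
    the tied), ``match_score`` (highest pose match score among those still
    tied), or ``category_order`` (fixed-order fallback, logged loudly).
    """

    stimulus_id: str
    category: str
    median_rating: float
    iqr: float
    tiebreak_level: str


class UnassignableProfileError(ValueError):
    """All-zero profile: no category can be assigned."""


def _check_ratings(ratings: pd.DataFrame) -> None:
    missing = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing:
        raise ValidationError(f"ratings table missing columns: {missing}")
    bad = set(ratings["category"]) - set(CATEGORIES)
    if bad:
        raise ValidationError(f"unknown categories in ratings: {sorted(bad)}")
    vals = ratings["value"]
    if not vals.isin([0, 1, 2, 3, 4]).all():
        raise ValidationError("rating values must be integers in {0,...,4}")


def build_profiles(ratings: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-stimulus emotion profiles: median rating per category.

    ``ratings`` is the long table (rater_id, stimulus_id, condition,
    category, value).  Returns a frame indexed by stimulus_id with the 13
    category columns in fixed order; medians of even-sized panels are
    interpolated (midpoint).  A stimulus with any unrated category is an
    error listing the gaps.
    """
    _check_ratings(ratings)
    sub = ratings[ratings["condition"] == condition]
    if sub.empty:
        raise ValidationError(f"no ratings for condition {condition!r}")
    prof = (
        sub.pivot_table(index="stimulus_id", columns="category",
                        values="value", aggfunc="median")
    )
    gaps = [
        (stim, [c for c in CATEGORIES if c not in prof.columns
                or pd.isna(prof.loc[stim, c])])
        for stim in prof.index
    ]
    gaps = [(s, cs) for s, cs in gaps if cs]
    if gaps:
        raise ValidationError(f"stimuli with unrated categories: {gaps[:10]}")
    return prof.reindex(columns=list(CATEGORIES)).astype(float)


def profile_iqrs(ratings: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-stimulus, per-category interquartile range of rater values."""
    _check_ratings(ratings)
    sub = ratings[ratings["condition"] == condition]
    iqr = sub.pivot_table(
        index="stimulus_id", columns="category", values="value",
        aggfunc=lambda v: np.percentile(v, 75) - np.percentile(v, 25),
    )
    return iqr.reindex(columns=list(CATEGORIES)).astype(float)


def profile_row(frame: pd.DataFrame, stimulus_id: str,
                condition: str = "scenario_alone") -> EmotionProfile:
    """View one row of a profile frame as an :class:`EmotionProfile`."""
    return EmotionProfile(
        stimulus_id=str(stimulus_id), condition=condition,
        medians=tuple(float(x) for x in frame.loc[stimulus_id, list(CATEGORIES)]),
    )


def assign_category(
    profile: Sequence[float],
    per_category_iqr: Sequence[float],
    pose_match_scores: Optional[Sequence[float]] = None,
    stimulus_id: str = "",
) -> CategoryAssignment:
    """Assign a stimulus to its highest-median category.

    Tie-breaking cascade: highest median rating; then smallest IQR among
    the tied categories; then highest pose match score; then fixed
    category order (logged as a warning).  An all-zero profile raises
    :class:`UnassignableProfileError`; a tie surviving the IQR rule with
    no match scores supplied is an error.
    """
    med = np.asarray(profile, dtype=float)
    if med.shape != (N_CATEGORIES,):
        raise ValidationError(f"profile must have length {N_CATEGORIES}")
    if np.all(med == 0):
        raise UnassignableProfileError(
            f"stimulus {stimulus_id!r}: all-zero profile"
        )
    top = med.max()
    tied = np.flatnonzero(med == top)
    if len(tied) == 1:
        idx, level = int(tied[0]), "median"
    else:
        iqr = np.asarray(per_category_iqr, dtype=float)
        if iqr.shape != (N_CATEGORIES,):
            raise ValidationError("per_category_iqr must have length 13")
        best_iqr = iqr[tied].min()
        tied = tied[iqr[tied] == best_iqr]
        if len(tied) == 1:
            idx, level = int(tied[0]), "iqr"
        else:
            if pose_match_scores is None:
                raise ValidationError(
                    f"stimulus {stimulus_id!r}: tie persists past IQR and no "
                    "pose match scores were supplied"
                )
            ms = np.asarray(pose_match_scores, dtype=float)
            best_m = ms[tied].max()
            tied = tied[ms[tied] == best_m]
            if len(tied) == 1:
                idx, level = int(tied[0]), "match_score"
            else:
                idx, level = int(tied[0]), "category_order"
                log.warning(
                    "stimulus %r: tie through all rules among %s; fixed "
                    "category order used", stimulus_id,
                    [CATEGORIES[i] for i in tied],
                )
    return CategoryAssignment(
        stimulus_id=str(stimulus_id),
        category=CATEGORIES[idx],
        median_rating=float(med[idx]),
        iqr=float(np.asarray(per_category_iqr, dtype=float)[idx]),
        tiebreak_level=level,
    )


def assign_all(
    profiles: pd.DataFrame,
    iqrs: pd.DataFrame,
    match_scores: Optional[pd.DataFrame] = None,
    skip_unassignable: bool = True,
) -> Dict[str, CategoryAssignment]:
    """Assign every stimulus in a profile frame; returns id -> assignment."""
    out: Dict[str, CategoryAssignment] = {}
    for stim in profiles.index:
        ms = None
        if match_scores is not None and stim in match_scores.index:
            ms = match_scores.loc[stim, list(CATEGORIES)].to_numpy()
        try:
            out[str(stim)] = assign_category(
                profiles.loc[stim, list(CATEGORIES)].to_numpy(),
                iqrs.loc[stim, list(CATEGORIES)].to_numpy(),
                pose_match_scores=ms,
                stimulus_id=str(stim),
            )
        except UnassignableProfileError:
            if not skip_unassignable:
                raise
            log.info("stimulus %s unassignable (all-zero profile)", stim)
    return out


def high_intensity_subset(
    assignments: Mapping[str, CategoryAssignment],
    threshold: float = 3.0,
) -> List[str]:
    """Stimuli whose assigned-category median rating is >= threshold.

    The default threshold 3 ("strongly") selects the high-intensity
    scenarios used for the intensity contrast.
    """
    if not (0.0 <= threshold <= 4.0):
        raise ValueError("threshold must be in [0, 4]")
    return sorted(
        sid for sid, a in assignments.items() if a.median_rating >= threshold
    )


@dataclass(frozen=True)
class ComplexityScore:
    """Fraction of the 13 categories a stimulus evokes (median >= 1)."""

    stimulus_id: str
    condition: str
    value: float


def complexity_index(profile: Sequence[float], stimulus_id: str = "",
                     condition: str = "") -> ComplexityScore:
    """Proportion of categories with median rating >= 1 (slightly)."""
    med = np.asarray(profile, dtype=float)
    if med.shape != (N_CATEGORIES,):
        raise ValidationError(f"profile must have length {N_CATEGORIES}")
    return ComplexityScore(
        stimulus_id=str(stimulus_id), condition=condition,
        value=float(np.count_nonzero(med >= 1.0)) / N_CATEGORIES,
    )


def complexity_frame(profiles: pd.DataFrame, condition: str = "") -> pd.Series:
    """Complexity index for every stimulus in a profile frame."""
    return (profiles[list(CATEGORIES)] >= 1.0).sum(axis=1) / N_CATEGORIES
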