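"""Contextual variation in emotion perception.

Quantifies how much of the emotional meaning of a face-in-context is
carried by the scenario versus the face: per-stimulus correlations
between condition profiles, a semi-partial/partial regression
decomposition of the face+scenario ratings onto both predictor blocks,
and a complexity contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import CATEGORIES, N_CATEGORIES, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ConditionCorrelations:
    """Per-stimulus Pearson r between two conditions' 13-entry profiles."""

    per_stimulus: pd.Series
    median_r: float
    mean_r: float
    excluded: List[str]


def profile_correlations(profiles_a: pd.DataFrame,
                         profiles_b: pd.DataFrame) -> ConditionCorrelations:
    """Correlate two conditions' emotion profiles stimulus by stimulus.

    For each stimulus present in both frames, Pearson r over the 13
    paired category medians; stimuli with a constant profile in either
    condition are excluded with a log entry (r undefined).
    """
    common = profiles_a.index.intersection(profiles_b.index)
    if len(common) == 0:
        raise ValidationError("no common stimuli between the two conditions")
    if set(profiles_a.index) != set(profiles_b.index):
        raise ValidationError("conditions cover different stimulus sets")
    A = profiles_a.loc[common, list(CATEGORIES)].to_numpy(dtype=float)
    B = profiles_b.loc[common, list(CATEGORIES)].to_numpy(dtype=float)
    rs: Dict[str, float] = {}
    excluded: List[str] = []
    for sid, a, b in zip(common, A, B):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            excluded.append(str(sid))
            log.info("stimulus %s has a constant profile; r undefined", sid)
            continue
        rs[str(sid)] = float(np.corrcoef(a, b)[0, 1])
    if not rs:
        raise ValidationError("all profiles constant; no correlations defined")
    series = pd.Series(rs, name="r").sort_index()
    return ConditionCorrelations(
        per_stimulus=series, median_r=float(series.median()),
        mean_r=float(series.mean()), excluded=sorted(excluded),
    )


@dataclass
class VarianceDecomposition:
    """OLS decomposition of one target category's face+scenario ratings.

    Signed coefficients: semi-partial = sign(b) * sqrt(unique variance /
    total variance); partial = sign(b) * sqrt(unique variance /
    (unique + unexplained)).  For any predictor, semi-partial^2 <=
    partial^2.
    """

    target: str
    semi_partial_scenario: pd.Series   # indexed by predictor category
    semi_partial_face: pd.Series
    partial_scenario: pd.Series
    partial_face: pd.Series
    r_squared: float


def _signed_sqrt(x: np.ndarray, sign: np.ndarray) -> np.ndarray:
    return np.sign(sign) * np.sqrt(np.clip(x, 0.0, None))


def decompose_variance(
    targets: pd.DataFrame,
    scenario_preds: pd.DataFrame,
    face_preds: pd.DataFrame,
    condition_limit: float = 1e10,
) -> Dict[str, VarianceDecomposition]:
    """Regress each face+scenario category on both 13-column blocks.

    One OLS model per target category with all 26 predictors (13
    scenario-alone + 13 face-alone medians across stimuli).  Semi-partial
    coefficients are computed from the t statistics:
    sr_j^2 = t_j^2 (1 - R^2) / df_resid, pr_j^2 = t_j^2 / (t_j^2 +
    df_resid); both reported signed by the OLS coefficient.
    """
    idx = targets.index
    if len(idx) < 30:
        raise ValidationError("need at least 30 stimuli for the decomposition")
    if not (scenario_preds.index.equals(idx) and face_preds.index.equals(idx)):
        scenario_preds = scenario_preds.loc[idx]
        face_preds = face_preds.loc[idx]
    X = np.column_stack([
        scenario_preds[list(CATEGORIES)].to_numpy(dtype=float),
        face_preds[list(CATEGORIES)].to_numpy(dtype=float),
    ])
    names = ([f"scenario:{c}" for c in CATEGORIES]
             + [f"face:{c}" for c in CATEGORIES])
    cond = np.linalg.cond(np.column_stack([np.ones(len(X)), X]))
    if cond > condition_limit or np.linalg.matrix_rank(X) < X.shape[1]:
        # Name the offending (most collinear) columns for the error.
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValidationError(
            f"rank-deficient design (condition number {cond:.3g}); most "
            f"collinear columns: {names[i]} and {names[j]}"
        )
    Xc = sm.add_constant(X)

    out: Dict[str, VarianceDecomposition] = {}
    for cat in CATEGORIES:
        y = targets[cat].to_numpy(dtype=float)
        fit = sm.OLS(y, Xc).fit()
        t = fit.tvalues[1:]
        b = fit.params[1:]
        df = fit.df_resid
        r2 = float(fit.rsquared)
        sr2 = t ** 2 * (1.0 - r2) / df
        pr2 = t ** 2 / (t ** 2 + df)
        sr = _signed_sqrt(sr2, b)
        pr = _signed_sqrt(pr2, b)
        cats = list(CATEGORIES)
        out[cat] = VarianceDecomposition(
            target=cat,
            semi_partial_scenario=pd.Series(sr[:N_CATEGORIES], index=cats),
            semi_partial_face=pd.Series(sr[N_CATEGORIES:], index=cats),
            partial_scenario=pd.Series(pr[:N_CATEGORIES], index=cats),
            partial_face=pd.Series(pr[N_CATEGORIES:], index=cats),
            r_squared=r2,
        )
    return out


def semi_partial_matrices(
    decomp: Dict[str, VarianceDecomposition]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stack the per-target semi-partials into two 13x13 matrices.

    Rows are target (face+scenario) categories, columns predictor
    categories; left matrix = scenario-alone block, right = face-alone.
    """
    cats = list(CATEGORIES)
    scen = pd.DataFrame(
        {c: decomp[c].semi_partial_scenario for c in cats}).T.loc[cats, cats]
    face = pd.DataFrame(
        {c: decomp[c].semi_partial_face for c in cats}).T.loc[cats, cats]
    return scen, face


@dataclass
class ComplexityComparison:
    """Two-sample (Welch) or paired t comparison of complexity scores."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: float
    p_value: float
    ci: Tuple[float, float]
    cohen_d: float
    paired: bool


def compare_complexity(scores_a: Sequence[float], scores_b: Sequence[float],
                       paired: bool = False, ci_level: float = 0.95
                       ) -> ComplexityComparison:
    """Compare two samples of complexity (or any [0,1]) scores.

    Unpaired uses Welch's t (equal variances not assumed) with Cohen's d
    on the pooled SD; paired uses the paired t with d = mean(diff) /
    sd(diff).  The CI is for the mean difference (a - b).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length samples")
        diff = a - b
        res = stats.ttest_rel(a, b)
        df = a.size - 1
        sd_d = diff.std(ddof=1)
        d = float(diff.mean() / sd_d) if sd_d > 0 else 0.0
        se = sd_d / np.sqrt(a.size)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
        sp = np.sqrt(((a.size - 1) * a.var(ddof=1)
                      + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
        d = float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    delta = float(a.mean() - b.mean())
    if se > 0:
        tcrit = stats.t.ppf(0.5 + ci_level / 2, df)
        ci = (delta - tcrit * se, delta + tcrit * se)
    else:
        ci = (delta, delta)
    return ComplexityComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t=float(res.statistic), df=float(df), p_value=float(res.pvalue),
        ci=(float(ci[0]), float(ci[1])), cohen_d=d, paired=paired,
    )
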