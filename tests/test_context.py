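"""Condition correlations, variance decomposition, complexity contrast."""

import numpy as np
import pandas as pd
import pytest

from emofacs.core import CATEGORIES, ValidationError
from emofacs.context import (compare_complexity, decompose_variance,
                             profile_correlations, semi_partial_matrices)

N = len(CATEGORIES)


def _frame(X, ids=None):
    ids = ids or [f"s{i}" for i in range(len(X))]
    return pd.DataFrame(np.asarray(X, dtype=float), index=ids,
                        columns=list(CATEGORIES))


def _random_profiles(rng, n):
    return _frame(np.clip(rng.normal(2, 1, (n, N)), 0, 4))


class TestProfileCorrelations:
    def test_identical_sets_give_r_one(self):
        rng = np.random.default_rng(0)
        prof = _random_profiles(rng, 10)
        res = profile_correlations(prof, prof.copy())
        assert np.allclose(res.per_stimulus.values, 1.0)

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(1)
        prof = _random_profiles(rng, 8)
        res = profile_correlations(prof, prof * 0.5 + 1.0)
        assert np.allclose(res.per_stimulus.values, 1.0)

    def test_constant_profile_excluded(self):
        rng = np.random.default_rng(2)
        prof = _random_profiles(rng, 5)
        other = prof.copy()
        other.iloc[0] = 2.0  # constant row
        res = profile_correlations(prof, other)
        assert res.excluded == [str(prof.index[0])]
        assert len(res.per_stimulus) == 4

    def test_reordering_invariance(self):
        rng = np.random.default_rng(3)
        a, b = _random_profiles(rng, 9), _random_profiles(rng, 9)
        res1 = profile_correlations(a, b)
        perm = a.sample(frac=1.0, random_state=5).index
        res2 = profile_correlations(a.loc[perm], b.loc[perm])
        assert res1.median_r == pytest.approx(res2.median_r)

    def test_mismatched_stimuli_rejected(self):
        rng = np.random.default_rng(4)
        a = _random_profiles(rng, 5)
        b = _random_profiles(rng, 5)
        b.index = [f"t{i}" for i in range(5)]
        with pytest.raises(ValidationError):
            profile_correlations(a, b)


class TestDecomposeVariance:
    def _predictors(self, rng, n):
        scen = _frame(rng.normal(2, 1, (n, N)))
        face = _frame(rng.normal(2, 1, (n, N)))
        return scen, face

    def test_near_perfect_predictor_dominates(self):
        # n large enough that the 25 irrelevant predictors absorb little
        # variance by chance, so the true predictor's unique share ~ 1.
        rng = np.random.default_rng(10)
        n = 400
        scen, face = self._predictors(rng, n)
        noise = rng.normal(0, 0.05, n)
        y = np.clip(scen["anger"].to_numpy() + noise, 0, 4)
        targets = _frame(np.tile(y[:, None], (1, N)), ids=list(scen.index))
        decomp = decompose_variance(targets, scen, face)
        d = decomp["fear"]
        assert abs(d.semi_partial_scenario["anger"]) > 0.9
        others = d.semi_partial_scenario.drop("anger").abs()
        assert (others < 0.1).all()

    def test_independent_noise_target_near_zero(self):
        rng = np.random.default_rng(11)
        scen, face = self._predictors(rng, 200)
        targets = _frame(rng.normal(0, 1, (200, N)), ids=list(scen.index))
        decomp = decompose_variance(targets, scen, face)
        sr = decomp["anger"].semi_partial_scenario.abs()
        assert (sr < 0.25).all()

    def test_sum_of_squared_semipartials_bounded_by_r2(self):
        rng = np.random.default_rng(12)
        scen, face = self._predictors(rng, 120)
        targets = _frame(
            0.5 * scen.to_numpy() + 0.2 * face.to_numpy()
            + rng.normal(0, 0.5, (120, N)), ids=list(scen.index))
        decomp = decompose_variance(targets, scen, face)
        for d in decomp.values():
            total = (d.semi_partial_scenario ** 2).sum() \
                + (d.semi_partial_face ** 2).sum()
            assert total <= d.r_squared + 1e-9
            assert d.r_squared <= 1.0

    def test_semipartial_le_partial_and_orthogonal_case(self):
        rng = np.random.default_rng(13)
        # Orthogonal design: Haar-orthogonalized predictor columns.
        n = 100
        M = np.linalg.qr(rng.normal(size=(n, 2 * N)))[0]
        scen, face = _frame(M[:, :N]), _frame(M[:, N:])
        face.index = scen.index
        targets = _frame(M[:, :N] @ rng.normal(size=(N, N)) * 0.3
                         + rng.normal(0, 0.3, (n, N)), ids=list(scen.index))
        decomp = decompose_variance(targets, scen, face)
        for d in decomp.values():
            assert (d.semi_partial_scenario.abs()
                    <= d.partial_scenario.abs() + 1e-12).all()

    def test_known_unique_shares_recovered(self):
        rng = np.random.default_rng(14)
        n = 3000
        M = np.linalg.qr(rng.normal(size=(n, 2 * N)))[0] * np.sqrt(n)
        scen, face = _frame(M[:, :N]), _frame(M[:, N:])
        face.index = scen.index
        # target = a*scen_anger + b*face_anger + noise with known shares
        a, b, s = 0.6, 0.3, 0.74  # variance: .36+.09+.5476 ~ 1
        y = (a * M[:, CATEGORIES.index("anger")]
             + b * M[:, N + CATEGORIES.index("anger")]
             + rng.normal(0, s, n))
        targets = _frame(np.tile(y[:, None], (1, N)), ids=list(scen.index))
        d = decompose_variance(targets, scen, face)["anger"]
        var_y = y.var()
        assert d.semi_partial_scenario["anger"] ** 2 == pytest.approx(
            a ** 2 / var_y, abs=0.03)
        assert d.semi_partial_face["anger"] ** 2 == pytest.approx(
            b ** 2 / var_y, abs=0.03)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(15)
        scen, face = self._predictors(rng, 60)
        face["anger"] = scen["anger"]  # duplicate predictor
        targets = _frame(rng.normal(size=(60, N)), ids=list(scen.index))
        with pytest.raises(ValidationError, match="anger"):
            decompose_variance(targets, scen, face, condition_limit=1e6)

    def test_too_few_stimuli_rejected(self):
        rng = np.random.default_rng(16)
        scen, face = self._predictors(rng, 10)
        with pytest.raises(ValidationError):
            decompose_variance(scen, scen, face)

    def test_matrix_export_shape(self):
        rng = np.random.default_rng(17)
        scen, face = self._predictors(rng, 60)
        targets = _frame(rng.normal(size=(60, N)), ids=list(scen.index))
        sm_, fm_ = semi_partial_matrices(decompose_variance(targets, scen, face))
        assert sm_.shape == fm_.shape == (N, N)


class TestCompareComplexity:
    def test_identical_samples(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        res = compare_complexity(a, a.copy())
        assert res.t == pytest.approx(0.0)
        assert res.cohen_d == pytest.approx(0.0)

    def test_constant_shift_effect_size(self):
        rng = np.random.default_rng(20)
        a = rng.normal(0.3, 0.1, 500)
        delta = 0.05
        res = compare_complexity(a + delta, a)
        # equal variances: d = delta / pooled sd
        assert res.cohen_d == pytest.approx(delta / a.std(ddof=1), rel=0.01)

    def test_paired_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(21)
        a = rng.normal(0.3, 0.1, 40)
        b = a + rng.normal(0.02, 0.05, 40)
        res = compare_complexity(a, b, paired=True)
        ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic)
        assert res.df == 39

    def test_rejection_rate_near_nominal_power(self):
        # Known-effect simulation against the closed-form power of the
        # two-sample t test.
        from statsmodels.stats.power import TTestIndPower
        rng = np.random.default_rng(22)
        n, d = 30, 0.8
        power = TTestIndPower().power(effect_size=d, nobs1=n, alpha=0.05)
        reject = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(d, 1.0, n)
            b = rng.normal(0.0, 1.0, n)
            if compare_complexity(a, b).p_value < 0.05:
                reject += 1
        se = np.sqrt(power * (1 - power) / reps)
        assert reject / reps == pytest.approx(power, abs=4 * se)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_complexity([0.1], [0.2, 0.3])
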