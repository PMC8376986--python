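"""Bayesian reliability tests, false-positive-rate specificity, multiverse grid."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from emofacs.core import AUCoding, CATEGORIES
from emofacs.ratings import CategoryAssignment
from emofacs.reliability import (DEFAULT_HYPOTHESES, ReliabilityOptions,
                                 bayes_reliability, category_reliability,
                                 false_positive_rate, jeffreys_interval,
                                 run_multiverse)
from emofacs.synthetic import synthetic_registry


def _numeric_marginal(k, n, a, b):
    """Independent numerical-integration oracle for one interval."""
    def integrand(th):
        return stats.binom.pmf(k, n, th) / (b - a)
    val, _ = integrate.quad(integrand, a, b, limit=200)
    return val


class TestBayesReliability:
    @pytest.mark.parametrize("k,n,expected_best", [
        (0, 100, "null"),
        (80, 100, "high"),
        (55, 100, "moderate"),
    ])
    def test_best_hypothesis(self, k, n, expected_best):
        assert bayes_reliability(k, n).best == expected_best

    @pytest.mark.parametrize("k,n", [(0, 100), (80, 100), (5, 9), (1, 1)])
    def test_marginals_match_numerical_integration(self, k, n):
        res = bayes_reliability(k, n)
        for name, (a, b) in DEFAULT_HYPOTHESES.items():
            assert res.marginal_likelihoods[name] == pytest.approx(
                _numeric_marginal(k, n, a, b), rel=1e-6)

    def test_single_trial_all_marginals_positive(self):
        res = bayes_reliability(1, 1)
        assert all(v > 0 for v in res.marginal_likelihoods.values())

    def test_k0_strongly_favors_null(self):
        res = bayes_reliability(0, 100)
        assert res.bayes_factors["moderate"] < 1e-6

    def test_width_weighted_marginals_conserve_flat_evidence(self):
        # Sum of interval marginals weighted by interval widths equals the
        # Beta-binomial evidence under a flat prior on [0, 1].
        k, n = 13, 40
        res = bayes_reliability(k, n)
        weighted = sum(res.marginal_likelihoods[h] * (b - a)
                       for h, (a, b) in res.hypotheses.items())
        flat = (special.comb(n, k)
                * special.beta(k + 1, n - k + 1))
        assert weighted == pytest.approx(flat, rel=1e-9)

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            bayes_reliability(1, 10, {"a": (0.0, 0.5), "b": (0.6, 1.0)})

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            bayes_reliability(0, 0)


class TestJeffreysInterval:
    @pytest.mark.parametrize("k,n", [(1, 20), (3, 20), (10, 20), (19, 20)])
    def test_matches_statsmodels(self, k, n):
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = jeffreys_interval(k, n)
        slo, shi = proportion_confint(k, n, alpha=0.05, method="jeffreys")
        assert (lo, hi) == pytest.approx((slo, shi), abs=1e-9)

    def test_boundary_counts_pinned(self):
        # Zero (or all) successes pin the corresponding bound exactly.
        assert jeffreys_interval(0, 20)[0] == 0.0
        assert jeffreys_interval(20, 20)[1] == 1.0


def _world(registry, specs):
    """specs: list of (sid, target_cat, pose_aus, profile_overrides)."""
    poses, assignments, rows = {}, {}, []
    for sid, cat, aus, overrides in specs:
        poses[sid] = AUCoding(sid, "c", {au: 4 for au in aus})
        assignments[sid] = CategoryAssignment(sid, cat, 3.0, 0.5, "median")
        vec = {c: 0.0 for c in CATEGORIES}
        vec.update(overrides)
        rows.append(pd.Series(vec, name=sid))
    profiles = pd.DataFrame(rows)[list(CATEGORIES)]
    return poses, assignments, profiles


class TestCategoryReliability:
    def test_perfect_poses_score_one(self):
        reg = synthetic_registry()
        anger_aus = sorted(reg["anger"][0].au_set)
        poses, assignments, _ = _world(reg, [
            (f"s{i}", "anger", anger_aus, {"anger": 3}) for i in range(4)])
        rel = category_reliability(assignments, poses, reg, base_rate=0.0)
        assert rel["anger"].median_m == 1.0
        assert rel["anger"].band == "high"
        assert not rel["anger"].simulated

    def test_simulated_flag_and_zero_base_rate(self, registry):
        poses, assignments, _ = _world(registry, [
            ("s0", "pride", [12, 17], {"pride": 3})])
        rel = category_reliability(assignments, poses, registry,
                                   base_rate=0.0)
        assert rel["pride"].simulated
        # base rate 0: identical to scoring with the dynamic AUs absent.
        from emofacs.matching import pose_vs_category
        assert rel["pride"].match_scores["s0"] == pose_vs_category(
            poses["s0"], "pride", registry)

    def test_empty_category_logged_not_fatal(self, registry):
        poses, assignments, _ = _world(registry, [
            ("s0", "anger", [4, 5, 7, 23], {"anger": 3})])
        rel = category_reliability(assignments, poses, registry,
                                   base_rate=0.1)
        assert len(rel["fear"].match_scores) == 0


class TestFalsePositiveRate:
    def _anger_world(self):
        reg = synthetic_registry()
        anger_aus = sorted(reg["anger"][0].au_set)
        other_aus = sorted(reg["interest"][0].au_set)
        specs = [
            # two on-target matches
            ("s0", "anger", anger_aus, {"anger": 3.0}),
            ("s1", "anger", anger_aus, {"anger": 3.5}),
            # one false positive: scowl for a sadness-rated scenario
            ("s2", "sadness", anger_aus, {"anger": 1.0, "sadness": 3.0}),
            # non-matching pose, irrelevant
            ("s3", "interest", other_aus, {"interest": 3.0}),
        ]
        return (reg,) + _world(reg, specs)

    def test_hand_counts(self):
        reg, poses, _, profiles = self._anger_world()
        res = false_positive_rate("anger", poses, reg, profiles)
        assert (res.k_e, res.n_e) == (1, 3)
        assert res.p_hat_e == pytest.approx(1 / 3)
        assert res.specificity == pytest.approx(2 / 3)

    def test_all_on_target_specificity_one(self):
        reg = synthetic_registry()
        anger_aus = sorted(reg["anger"][0].au_set)
        poses, _, profiles = _world(reg, [
            (f"s{i}", "anger", anger_aus, {"anger": 3.0}) for i in range(3)])
        res = false_positive_rate("anger", poses, reg, profiles)
        assert res.p_hat_e == 0.0
        assert res.specificity == 1.0

    def test_posterior_tail_matches_beta_cdf(self):
        reg, poses, _, profiles = self._anger_world()
        res = false_positive_rate("anger", poses, reg, profiles)
        # Jeffreys posterior Beta(k+1/2, n-k+1/2) upper tail at 1/9.
        expected = 1.0 - stats.beta.cdf(1 / 9, 1.5, 2.5)
        assert res.posterior_prob_exceeds_chance == pytest.approx(expected)

    def test_simulation_required_category_rejected(self, registry):
        with pytest.raises(ValueError, match="pride"):
            false_positive_rate("pride", {}, registry,
                                pd.DataFrame(columns=list(CATEGORIES)))

    def test_no_matching_pose_undefined(self):
        reg = synthetic_registry()
        other = sorted(reg["interest"][0].au_set)
        poses, _, profiles = _world(reg, [
            ("s0", "interest", other, {"interest": 3.0})])
        with pytest.raises(ValueError, match="anger"):
            false_positive_rate("anger", poses, reg, profiles)


class TestMultiverse:
    def _inputs(self):
        reg = synthetic_registry()
        specs = []
        for i, cat in enumerate(["anger", "fear", "happiness"] * 4):
            aus = sorted(reg[cat][0].au_set)
            if i % 3 == 0:  # some non-adherent poses
                aus = sorted(reg["surprise"][0].au_set)
            specs.append((f"s{i}", cat, aus, {cat: 3.0}))
        poses, assignments, profiles = _world(reg, specs)
        return reg, poses, assignments, profiles

    def test_degenerate_grid_equals_single_run(self):
        reg, poses, assignments, profiles = self._inputs()
        single = category_reliability(assignments, poses, reg, base_rate=0.0)
        summary = run_multiverse(assignments, poses, reg, profiles,
                                 axes={"aggregation": ["median"]},
                                 base_rate=0.0)
        cell = summary.cells[0]
        for cat, med in cell.reliability_medians.items():
            if np.isfinite(med) and np.isfinite(single[cat].median_m):
                assert med == single[cat].median_m

    def test_max_dominates_median_per_category(self):
        reg, poses, assignments, profiles = self._inputs()
        summary = run_multiverse(assignments, poses, reg, profiles,
                                 axes={"aggregation": ["median", "max"]},
                                 base_rate=0.0)
        by_agg = {c.choices["aggregation"]: c for c in summary.cells}
        for cat, med in by_agg["median"].reliability_medians.items():
            maxed = by_agg["max"].reliability_medians.get(cat)
            if maxed is not None and np.isfinite(med) and np.isfinite(maxed):
                assert maxed >= med

    def test_factorial_cell_count(self):
        reg, poses, assignments, profiles = self._inputs()
        summary = run_multiverse(
            assignments, poses, reg, profiles,
            axes={"aggregation": ["median", "max", "min"],
                  "intensity_floor": [None, 3]},
            base_rate=0.0)
        assert len(summary.cells) == 6
        assert len(summary.table) == 6
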