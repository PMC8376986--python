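"""Supervised reliability and specificity on a synthetic study.

Generates a world where actors pose the hypothesized configuration of
their scenario's emotion category with probability 0.5, runs the
assignment + match-scoring pipeline, and prints per-category reliability
bands, Bayesian band selection, and false-positive-rate specificity.
"""

import numpy as np

from emofacs import (WorldSpec, assign_all, build_profiles,
                     category_reliability, false_positive_rate, generate,
                     median_base_rate, profile_iqrs,
                     reliability_bayes_tests)

bundle = generate(WorldSpec(n_scenarios=117, raters_per_stimulus=20,
                            prototype_adherence=0.5, seed=11))
ratings, registry = bundle.ratings, bundle.registry
poses = bundle.consolidated_poses()

profiles = build_profiles(ratings, "scenario_alone")
assignments = assign_all(profiles, profile_iqrs(ratings, "scenario_alone"))
rate = median_base_rate(list(poses.values()))
print(f"median AU base rate: {rate:.3f} (imputation rate for dynamic AUs)")

rel = category_reliability(assignments, poses, registry, base_rate=rate)
bayes = reliability_bayes_tests(rel)
print("\ncategory        n   median m  band      Bayes-selected band")
for cat, r in rel.items():
    if not len(r.match_scores):
        continue
    best = bayes[cat].best if cat in bayes else "-"
    print(f"{cat:<14} {len(r.match_scores):>3}   {r.median_m:.3f}    "
          f"{r.band:<9} {best}")

print("\nspecificity (1 - false positive rate), testable categories:")
for cat in registry.categories:
    if registry.is_simulation_required(cat):
        continue
    try:
        res = false_positive_rate(cat, poses, registry, profiles)
    except ValueError:
        continue
    lo, hi = res.credibility_interval
    print(f"{cat:<14} k={res.k_e:>3} n={res.n_e:>3}  "
          f"specificity={res.specificity:.2f}  95% CI on FPR "
          f"[{lo:.2f}, {hi:.2f}]")
print("\nWith adherence 0.5 roughly half the poses match their own "
      "category at m >= 0.4.  Specificity is lower wherever hypothesized "
      "configurations overlap (fear, awe and surprise all build on "
      "1+2+5): a pose matching one of them also matches the others, and "
      "counts as a false positive for categories its scenario was not "
      "rated as evoking.")
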