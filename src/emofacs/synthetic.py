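"""Synthetic worlds with known ground truth.

Generates the three tables the pipeline consumes — rating panels for the
three presentation conditions, multi-coder AU codings, and a
configuration registry — from a latent world whose parameters
(prototype adherence, cluster repertoires, leakage, mixing weights) are
recorded in a ground-truth manifest, so every pipeline stage can be
tested as a parameter-recovery problem.

Regimes
-------
``prototype``
    Each scenario has a latent emotion category; with probability
    ``prototype_adherence`` its actor poses one of the category's
    hypothesized variants, otherwise a configuration disjoint from all of
    that category's variants.
``mixed``
    As ``prototype``, plus profile leakage: with probability
    ``leakage_rate`` an adherent scenario's rating profile is swapped to
    be dominated by a different category (target median < 2, other
    median > 2), planting a known false-positive rate.
``context_sensitive``
    Scenarios belong to latent clusters with cluster-specific AU
    repertoires; with probability ``pose_fidelity`` a pose equals its
    cluster repertoire exactly, otherwise one repertoire AU is swapped
    for an off-repertoire AU.  Profiles are cluster-specific, so
    profile clustering should recover the repertoire structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (AUCoding, CATEGORIES, CODABLE_AUS, ConfigurationRegistry,
                   ConfigurationVariant, EmotionProfile, N_CATEGORIES,
                   default_registry)
from .matching import consolidate_coders
from .ratings import build_profiles

_CODABLE_SORTED = sorted(CODABLE_AUS)


def synthetic_registry() -> ConfigurationRegistry:
    """A registry of 13 mutually disjoint two-AU configurations.

    Synthetic stand-in for the hypothesized-configuration registry with
    no overlap between categories and no dynamic AUs, so that
    cross-category match scores are exactly zero.  Used by
    parameter-recovery tests where overlap between real prototypes
    (e.g., fear/awe/surprise) would confound the planted rates.
    """
    variants = {
        cat: [ConfigurationVariant(cat, frozenset(_CODABLE_SORTED[2 * i:2 * i + 2]))]
        for i, cat in enumerate(CATEGORIES)
    }
    return ConfigurationRegistry(variants=variants)


@dataclass
class WorldSpec:
    """Parameters of a synthetic study world.

    Defaults mirror the study design: 604 scenarios, 13 categories, 40
    raters per stimulus and condition, 3 FACS coders.  Latent intensities
    live on the same 0-4 scale as ratings; the face+scenario condition is
    an explicit convex combination of the scenario- and face-driven
    latents with weight ``context_weight`` on the scenario.
    """

    n_scenarios: int = 604
    raters_per_stimulus: int = 40
    n_coders: int = 3
    regime: str = "prototype"            # prototype | mixed | context_sensitive
    prototype_adherence: float = 0.5
    leakage_rate: float = 0.0            # mixed regime only
    n_clusters: int = 5                  # context_sensitive regime
    repertoire_size: int = 5
    pose_fidelity: float = 0.8
    coder_flip_prob: float = 0.05        # per-AU presence flip per coder
    rater_threshold: float = 0.5         # yes/no response threshold
    rater_slope: float = 4.0
    rater_value_sd: float = 0.5          # intensity jitter around latent
    scenario_secondary_rate: float = 2.8  # mean secondary categories/scenario
    face_secondary_rate: float = 0.43
    face_scenario_corr: float = 0.3      # P(face latent copies scenario latent)
    context_weight: float = 0.8          # scenario weight in face+scenario
    dynamic_au_rate: float = 0.104       # latent rate of uncodable AUs
    categories: Optional[Sequence[str]] = None  # latent categories to use
    registry: Optional[ConfigurationRegistry] = None
    seed: int = 0

    def __post_init__(self):
        for name in ("prototype_adherence", "leakage_rate", "pose_fidelity",
                     "coder_flip_prob", "face_scenario_corr",
                     "context_weight", "dynamic_au_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.regime not in ("prototype", "mixed", "context_sensitive"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_scenarios < 1 or self.raters_per_stimulus < 1:
            raise ValueError("need at least one scenario and one rater")
        if self.n_coders < 1:
            raise ValueError("need at least one coder")
        if self.regime == "context_sensitive":
            if self.n_clusters < 2:
                raise ValueError("context regime needs >= 2 clusters")
            if self.n_clusters * self.repertoire_size > len(CODABLE_AUS):
                raise ValueError(
                    "disjoint repertoires need n_clusters * repertoire_size "
                    f"<= {len(CODABLE_AUS)}"
                )


@dataclass
class SyntheticBundle:
    """Everything :func:`generate` emits for one world."""

    ratings: pd.DataFrame            # long table, all three conditions
    codings: List[AUCoding]          # one entry per pose x coder
    registry: ConfigurationRegistry
    ground_truth: dict
    spec: WorldSpec

    def profiles(self, condition: str = "scenario_alone") -> pd.DataFrame:
        return build_profiles(self.ratings, condition)

    def consolidated_poses(self) -> Dict[str, AUCoding]:
        """One consensus coding per pose (majority presence across coders)."""
        by_pose: Dict[str, List[AUCoding]] = {}
        for c in self.codings:
            by_pose.setdefault(c.pose_id, []).append(c)
        return {pid: consolidate_coders(group) for pid, group in by_pose.items()}

    def to_dir(self, path) -> None:
        """Write the bundle as the documented CSV/YAML/JSON files."""
        from . import io as io_mod
        import os

        os.makedirs(path, exist_ok=True)
        io_mod.write_ratings_csv(self.ratings, os.path.join(path, "ratings.csv"))
        io_mod.write_codings_csv(self.codings, os.path.join(path, "codings.csv"))
        self.registry.to_yaml(os.path.join(path, "registry.yaml"))
        with open(os.path.join(path, "ground_truth.json"), "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)


def _secondary_categories(rng, exclude: Sequence[int], rate: float
                          ) -> Dict[int, int]:
    """Sparse secondary latent intensities: Poisson count, values 1-2."""
    pool = [i for i in range(N_CATEGORIES) if i not in exclude]
    k = min(int(rng.poisson(rate)), len(pool))
    chosen = rng.choice(len(pool), size=k, replace=False) if k else []
    return {pool[int(i)]: int(rng.integers(1, 3)) for i in chosen}


def _rate_panel(rng, latent: np.ndarray, n_raters: int, spec: WorldSpec
                ) -> np.ndarray:
    """Simulate one rater panel: (n_raters, 13) integer values 0-4.

    Presence is Bernoulli in a logistic function of the latent intensity;
    given presence, the value is the latent plus Gaussian jitter, rounded
    and clipped to 1-4.
    """
    p_yes = 1.0 / (1.0 + np.exp(-spec.rater_slope *
                                (latent - spec.rater_threshold)))
    present = rng.random((n_raters, N_CATEGORIES)) < p_yes
    vals = np.rint(latent + rng.normal(0.0, spec.rater_value_sd,
                                       (n_raters, N_CATEGORIES)))
    vals = np.clip(vals, 1, 4)
    return np.where(present, vals, 0).astype(int)


def _code_pose(rng, pose_id: str, intended: FrozenSet[int], spec: WorldSpec
               ) -> List[AUCoding]:
    """Code one pose by ``n_coders`` noisy coders.

    Intended AUs get intensities 3-5 (so they survive the moderate-
    intensity filter); each coder independently drops present AUs and
    adds spurious low-intensity AUs with ``coder_flip_prob``, and jitters
    kept intensities by +/- 1.
    """
    base_intensity = {au: int(rng.integers(3, 6)) for au in sorted(intended)}
    codings = []
    for ci in range(spec.n_coders):
        intensity: Dict[int, int] = {}
        for au in _CODABLE_SORTED:
            if au in base_intensity:
                if rng.random() < spec.coder_flip_prob:
                    continue  # missed
                jitter = int(rng.integers(-1, 2))
                intensity[au] = int(np.clip(base_intensity[au] + jitter, 1, 5))
            elif rng.random() < spec.coder_flip_prob:
                intensity[au] = int(rng.integers(1, 3))  # spurious, weak
        if not intensity:  # a pose is never coded fully blank
            au = min(base_intensity) if base_intensity else _CODABLE_SORTED[0]
            intensity[au] = base_intensity.get(au, 1)
        codings.append(AUCoding(pose_id=pose_id, coder_id=f"coder{ci}",
                                intensity=intensity))
    return codings


def generate(spec: WorldSpec) -> SyntheticBundle:
    """Generate a reproducible synthetic study bundle from a world spec."""
    rng = np.random.default_rng(spec.seed)
    registry = spec.registry if spec.registry is not None else default_registry()

    if spec.categories is not None:
        cats = list(spec.categories)
    elif spec.regime == "context_sensitive":
        cats = list(registry.categories)[: spec.n_clusters]
    else:
        cats = [c for c in registry.categories
                if not registry.is_simulation_required(c)]
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}

    # Disjoint cluster repertoires for the context regime.  The number of
    # degraded (one-AU-swapped) poses per cluster is fixed at
    # round((1 - fidelity) * size) — fidelity is a composition of the
    # cluster, not an independent coin per pose — so the within-cluster
    # share of identical-pose pairs is a design constant, not a sample.
    repertoire_map: Dict[int, FrozenSet[int]] = {}
    degraded_flags: Dict[int, bool] = {}
    if spec.regime == "context_sensitive":
        for g in range(spec.n_clusters):
            lo = g * spec.repertoire_size
            repertoire_map[g] = frozenset(
                _CODABLE_SORTED[lo: lo + spec.repertoire_size])
        member_idx: Dict[int, List[int]] = {}
        for i in range(spec.n_scenarios):
            member_idx.setdefault(i % spec.n_clusters, []).append(i)
        for g, members in member_idx.items():
            n_deg = int(round((1.0 - spec.pose_fidelity) * len(members)))
            which = rng.choice(len(members), size=n_deg, replace=False)
            chosen = {members[int(j)] for j in which}
            for i in members:
                degraded_flags[i] = i in chosen

    sids = [f"s{i:04d}" for i in range(spec.n_scenarios)]
    manifest_scen: Dict[str, dict] = {}
    codings: List[AUCoding] = []
    rows_rater, rows_stim, rows_cond, rows_cat, rows_val = [], [], [], [], []

    for i, sid in enumerate(sids):
        # ----- latent scenario profile and pose ------------------------
        leaked = False
        cluster: Optional[int] = None
        if spec.regime == "context_sensitive":
            cluster = i % spec.n_clusters
            target = cats[cluster]
            lam_s = np.zeros(N_CATEGORIES)
            lam_s[cat_index[target]] = 4.0
            partner = list(registry.categories)[
                (cluster + spec.n_clusters) % N_CATEGORIES]
            lam_s[cat_index[partner]] = 2.0
            rep = repertoire_map[cluster]
            if not degraded_flags[i]:
                intended = rep
                adherent = True
            else:
                dropped = int(rng.choice(sorted(rep)))
                pool = sorted(CODABLE_AUS - rep)
                added = int(pool[int(rng.integers(len(pool)))])
                intended = (rep - {dropped}) | {added}
                adherent = False
        else:
            target = cats[i % len(cats)]
            lam_s = np.zeros(N_CATEGORIES)
            lam_s[cat_index[target]] = float(rng.integers(3, 5))
            for j, v in _secondary_categories(
                    rng, [cat_index[target]],
                    spec.scenario_secondary_rate).items():
                lam_s[j] = v
            union = frozenset().union(
                *(v.au_set for v in registry[target])) & CODABLE_AUS
            adherent = rng.random() < spec.prototype_adherence
            if adherent:
                variant = registry[target][
                    int(rng.integers(len(registry[target])))]
                intended = variant.au_set & CODABLE_AUS
                if not intended:  # fully dynamic configuration: pose the
                    adherent = False  # alternative instead (uncodable truth)
            if not adherent:
                pool = sorted(CODABLE_AUS - union)
                pick = rng.choice(len(pool), size=min(4, len(pool)),
                                  replace=False)
                intended = frozenset(pool[int(k)] for k in pick)
            if (spec.regime == "mixed" and adherent
                    and rng.random() < spec.leakage_rate):
                leaked = True
                lam_s[cat_index[target]] = 1.0
                others = [c for c in CATEGORIES if c != target]
                other = others[(cat_index[target] + 1) % len(others)]
                lam_s[cat_index[other]] = float(rng.integers(3, 5))

        # ----- latent face profile and the mixed condition --------------
        if rng.random() < spec.face_scenario_corr:
            lam_f = lam_s.copy()
        else:
            fcat = int(rng.integers(N_CATEGORIES))
            lam_f = np.zeros(N_CATEGORIES)
            lam_f[fcat] = float(rng.integers(3, 5))
            for j, v in _secondary_categories(
                    rng, [fcat], spec.face_secondary_rate).items():
                lam_f[j] = v
        lam_fs = np.clip(spec.context_weight * lam_s
                         + (1.0 - spec.context_weight) * lam_f, 0.0, 4.0)

        # ----- rater panels ---------------------------------------------
        for cond, lam in (("scenario_alone", lam_s), ("face_alone", lam_f),
                          ("face_plus_scenario", lam_fs)):
            panel = _rate_panel(rng, lam, spec.raters_per_stimulus, spec)
            for r in range(spec.raters_per_stimulus):
                rid = f"{cond}:{sid}:r{r:02d}"
                rows_rater.extend([rid] * N_CATEGORIES)
                rows_stim.extend([sid] * N_CATEGORIES)
                rows_cond.extend([cond] * N_CATEGORIES)
                rows_cat.extend(CATEGORIES)
                rows_val.extend(panel[r].tolist())

        codings.extend(_code_pose(rng, sid, intended, spec))
        manifest_scen[sid] = {
            "category": target,
            "cluster": cluster,
            "adherent": bool(adherent),
            "leaked": bool(leaked),
            "pose_aus": sorted(intended),
            "latent_scenario": lam_s.tolist(),
            "latent_face": lam_f.tolist(),
        }

    ratings = pd.DataFrame({
        "rater_id": rows_rater,
        "stimulus_id": rows_stim,
        "condition": rows_cond,
        "category": rows_cat,
        "value": rows_val,
    })
    params = asdict(replace(spec, registry=None))
    params.pop("registry", None)
    ground_truth = {
        "params": params,
        "repertoires": {str(g): sorted(r) for g, r in repertoire_map.items()},
        "scenarios": manifest_scen,
    }
    return SyntheticBundle(ratings=ratings, codings=codings,
                           registry=registry, ground_truth=ground_truth,
                           spec=spec)


# ---------------------------------------------------------------------------
# Worked fixture: a tiny noiseless bundle anchored to hand-computable values.
# ---------------------------------------------------------------------------

_FIXTURE_PLAN = [
    # (stimulus, latent {category: value}, pose AUs)
    ("a01", {"happiness": 3, "amusement": 2}, (6, 7, 12)),
    ("a02", {"happiness": 3, "amusement": 2}, (6, 7, 12)),
    ("a03", {"happiness": 3, "amusement": 2}, (6, 7, 12)),
    ("a04", {"happiness": 3, "amusement": 2}, (6, 7, 12)),
    ("b01", {"fear": 3, "surprise": 2}, (1, 2, 25)),
    ("b02", {"fear": 3, "surprise": 2}, (1, 2, 25)),
    ("b03", {"fear": 3, "surprise": 2}, (1, 2, 25)),
    ("b04", {"fear": 3, "surprise": 2}, (1, 2, 25)),
    ("f01", {"anger": 4}, (4, 5, 7, 23)),
    ("f02", {"sadness": 4}, (1, 4, 15)),
    ("f03", {"disgust": 3}, (9, 15, 16)),
    ("f04", {"contempt": 3}, (14,)),
]


def worked_fixture(n_raters: int = 8, n_coders: int = 2) -> SyntheticBundle:
    """A 12-scenario noiseless bundle for documentation and oracle tests.

    Contains one cluster of poses sharing AUs {6, 7, 12} (happiness-like
    profiles), one sharing {1, 2, 25} (fear-like profiles), and four
    fillers with distinct categories and prototypical poses.  All raters
    agree exactly with the latent profile and all coders agree exactly on
    the poses, so every downstream quantity is hand-computable.
    Regeneration is deterministic (byte-identical files).
    """
    registry = default_registry()
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    rows = []
    codings: List[AUCoding] = []
    manifest: Dict[str, dict] = {}
    for sid, latent, aus in _FIXTURE_PLAN:
        lam = np.zeros(N_CATEGORIES)
        for cat, v in latent.items():
            lam[cat_index[cat]] = v
        for cond in ("scenario_alone", "face_alone", "face_plus_scenario"):
            for r in range(n_raters):
                rid = f"{cond}:{sid}:r{r:02d}"
                for cat in CATEGORIES:
                    rows.append((rid, sid, cond, cat,
                                 int(lam[cat_index[cat]])))
        intensity = {au: 4 for au in aus}
        for ci in range(n_coders):
            codings.append(AUCoding(pose_id=sid, coder_id=f"coder{ci}",
                                    intensity=intensity))
        manifest[sid] = {
            "category": max(latent, key=latent.get),
            "cluster": sid[0] if sid[0] in "ab" else None,
            "adherent": True, "leaked": False,
            "pose_aus": sorted(aus),
            "latent_scenario": lam.tolist(),
            "latent_face": lam.tolist(),
        }
    ratings = pd.DataFrame(
        rows, columns=["rater_id", "stimulus_id", "condition", "category",
                       "value"])
    spec = WorldSpec(n_scenarios=len(_FIXTURE_PLAN),
                     raters_per_stimulus=n_raters, n_coders=n_coders,
                     coder_flip_prob=0.0, seed=0)
    params = asdict(replace(spec, registry=None))
    params.pop("registry", None)
    return SyntheticBundle(
        ratings=ratings, codings=codings, registry=registry,
        ground_truth={"params": params, "repertoires": {},
                      "scenarios": manifest},
        spec=spec,
    )
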