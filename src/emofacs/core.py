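"""Core domain types: emotion categories, AU codings, emotion profiles,
the hypothesized-configuration registry, and the reliability band scale.

The study design is fixed at 13 emotion categories, each with one or more
hypothesized facial configurations expressed as sets of FACS action units
(AUs).  Static photographs can only be coded for AU1-AU27 (there is no
AU3); head- and eye-movement AUs (identifiers above 27) are "dynamic" and
must be imputed rather than coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence

import yaml

#: The 13 study categories, in the fixed (alphabetical) order used for all
#: profile vectors.  Profiles are ordered vectors; this order is the contract.
CATEGORIES: tuple = (
    "amusement",
    "anger",
    "awe",
    "contempt",
    "disgust",
    "embarrassment",
    "fear",
    "happiness",
    "interest",
    "pride",
    "sadness",
    "shame",
    "surprise",
)

N_CATEGORIES = len(CATEGORIES)

#: AUs codable from a static photograph: AU1-AU27, excluding AU3 (which does
#: not exist in FACS).
CODABLE_AUS: FrozenSet[int] = frozenset(range(1, 28)) - {3}

#: Conditions under which stimuli are rated.
CONDITIONS = ("scenario_alone", "face_alone", "face_plus_scenario")

#: Reliability bands: left-closed intervals partitioning [0, 1].
RELIABILITY_BANDS = (
    ("none", 0.0, 0.2),
    ("weak", 0.2, 0.4),
    ("moderate", 0.4, 0.7),
    ("high", 0.7, 1.0),
)


class ValidationError(ValueError):
    """Raised when an input table or registry violates its schema."""


def band_of(value: float) -> str:
    """Classify a match score or proportion into a reliability band.

    Bands are ``none`` [0, 0.2), ``weak`` [0.2, 0.4), ``moderate``
    [0.4, 0.7) and ``high`` [0.7, 1].  Boundaries are closed on the left
    ("at or above 0.4" is moderate); 1.0 is high.
    """
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"band_of requires a value in [0, 1], got {value!r}")
    for name, lo, hi in RELIABILITY_BANDS:
        if lo <= value < hi:
            return name
    return "high"  # value == 1.0


@dataclass(frozen=True)
class AUCoding:
    """One coder's FACS coding of one facial pose.

    ``intensity`` maps each present AU to its intensity 1-5 (FACS A-E);
    an AU is present iff it has an intensity entry.  Unilateral codes are
    not represented (they are dropped on ingest).
    """

    pose_id: str
    coder_id: str
    intensity: Mapping[int, int]

    def __post_init__(self):
        for au, level in self.intensity.items():
            if au == 3 or not isinstance(au, int) or au < 1:
                raise ValidationError(
                    f"pose {self.pose_id}: invalid AU identifier {au!r}"
                )
            if not 1 <= int(level) <= 5:
                raise ValidationError(
                    f"pose {self.pose_id}: AU{au} intensity {level!r} outside 1-5"
                )

    def activated(self, intensity_floor: Optional[int] = None) -> FrozenSet[int]:
        """Set of activated AUs, optionally restricted to intensity >= floor."""
        if intensity_floor is None:
            return frozenset(self.intensity)
        return frozenset(
            au for au, level in self.intensity.items() if level >= intensity_floor
        )


@dataclass(frozen=True)
class ConfigurationVariant:
    """One hypothesized AU configuration for an emotion category.

    ``dynamic_aus`` are the members of ``au_set`` that cannot be coded from
    a static photograph (head/eye AUs, identifiers above 27).
    """

    category: str
    au_set: FrozenSet[int]
    dynamic_aus: FrozenSet[int] = frozenset()

    def __post_init__(self):
        if not self.au_set:
            raise ValidationError(f"{self.category}: empty AU variant")
        if not self.dynamic_aus <= self.au_set:
            raise ValidationError(
                f"{self.category}: dynamic AUs {set(self.dynamic_aus)} not a "
                f"subset of the variant {set(self.au_set)}"
            )

    @property
    def static_aus(self) -> FrozenSet[int]:
        return self.au_set - self.dynamic_aus


@dataclass
class ConfigurationRegistry:
    """Hypothesized facial configurations, per category, in file order.

    A category whose every variant contains at least one dynamic AU cannot
    be scored from static codings alone and is flagged *simulation
    required*: its reliability is estimated by base-rate imputation of the
    dynamic AUs, and its specificity cannot be assessed.
    """

    variants: Dict[str, List[ConfigurationVariant]] = field(default_factory=dict)
    categories: Sequence[str] = CATEGORIES

    def __post_init__(self):
        missing = [c for c in self.categories if not self.variants.get(c)]
        if missing:
            raise ValidationError(f"registry missing categories: {missing}")
        extra = [c for c in self.variants if c not in self.categories]
        if extra:
            raise ValidationError(f"registry has unknown categories: {extra}")

    def __getitem__(self, category: str) -> List[ConfigurationVariant]:
        return self.variants[category]

    def is_simulation_required(self, category: str) -> bool:
        return all(v.dynamic_aus for v in self.variants[category])

    @property
    def simulation_required(self) -> List[str]:
        return [c for c in self.categories if self.is_simulation_required(c)]

    def dynamic_aus(self, category: str) -> FrozenSet[int]:
        out: FrozenSet[int] = frozenset()
        for v in self.variants[category]:
            out |= v.dynamic_aus
        return out

    def to_dict(self) -> dict:
        return {
            c: [
                {"aus": sorted(v.au_set), "dynamic": sorted(v.dynamic_aus)}
                for v in self.variants[c]
            ]
            for c in self.categories
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _parse_variant(category: str, entry) -> ConfigurationVariant:
    if isinstance(entry, dict):
        aus = entry.get("aus")
        dynamic = entry.get("dynamic", [])
    else:  # bare list of AU ids
        aus, dynamic = entry, []
    if not aus:
        raise ValidationError(f"{category}: variant with no AUs")
    for au in list(aus) + list(dynamic):
        if not isinstance(au, int) or au < 1:
            raise ValidationError(f"{category}: malformed AU id {au!r}")
    au_set = frozenset(aus)
    # AUs above 27 are head/eye movements, uncodable from stills.
    dyn = frozenset(dynamic) | frozenset(a for a in au_set if a > 27)
    return ConfigurationVariant(category, au_set, dyn)


def registry_from_dict(data: Mapping, categories: Sequence[str] = CATEGORIES
                       ) -> ConfigurationRegistry:
    variants = {
        str(cat): [_parse_variant(str(cat), entry) for entry in entries or []]
        for cat, entries in data.items()
    }
    return ConfigurationRegistry(variants=variants, categories=categories)


def load_registry(path, categories: Sequence[str] = CATEGORIES
                  ) -> ConfigurationRegistry:
    """Load a configuration registry from a YAML/JSON file.

    Schema: ``category -> list of {aus: [ints], dynamic: [ints]}``; a bare
    list of ints is accepted as shorthand for a variant with no dynamic
    AUs.  AU ids above 27 are always flagged dynamic.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValidationError(f"registry file {path} is not a mapping")
    return registry_from_dict(data, categories)


def default_registry() -> ConfigurationRegistry:
    """The packaged registry of hypothesized configurations (data file)."""
    ref = resources.files("emofacs.data").joinpath(
        "hypothesized_configurations.yaml"
    )
    with ref.open() as fh:
        return registry_from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class EmotionProfile:
    """A stimulus's vector of 13 per-category median ratings on [0, 4]."""

    stimulus_id: str
    condition: str
    medians: tuple  # length 13, ordered per CATEGORIES

    def __post_init__(self):
        if len(self.medians) != N_CATEGORIES:
            raise ValidationError(
                f"profile for {self.stimulus_id} has length "
                f"{len(self.medians)}, expected {N_CATEGORIES}"
            )
        if any(not (0.0 <= m <= 4.0) for m in self.medians):
            raise ValidationError(
                f"profile for {self.stimulus_id} has entries outside [0, 4]"
            )

    def __getitem__(self, category: str) -> float:
        return self.medians[CATEGORIES.index(category)]
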