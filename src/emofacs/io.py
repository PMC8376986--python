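"""Table ingestion, serialization and validation.

Fixed CSV dialect throughout: UTF-8, comma separated, header row, '.'
decimal, so that write -> read round-trips are exact.

Ratings table (long): rater_id, stimulus_id, condition, category,
present (0/1), intensity (blank or 1-4).  On ingest, present=0 maps to
value 0 and present=1 to the intensity, giving the single 0-4 value the
analyses use.

AU coding table (wide): pose_id, coder_id, then AU<k>_present (0/1) and
AU<k>_intensity (blank or 1-5) for each codable AU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (AUCoding, CATEGORIES, CODABLE_AUS, CONDITIONS,
                   ValidationError)
from .ratings import RATING_COLUMNS

log = logging.getLogger(__name__)

_AU_ORDER = sorted(CODABLE_AUS)


def write_ratings_csv(ratings: pd.DataFrame, path) -> None:
    """Write the long ratings table in the documented present/intensity form."""
    df = ratings[RATING_COLUMNS].copy()
    df["present"] = (df["value"] > 0).astype(int)
    df["intensity"] = df["value"].where(df["value"] > 0, other=pd.NA)
    df.drop(columns="value").to_csv(path, index=False)


def read_ratings_csv(path) -> pd.DataFrame:
    """Read a ratings CSV; returns the long table with a 0-4 ``value``."""
    df = pd.read_csv(path, dtype={"rater_id": str, "stimulus_id": str,
                                  "condition": str, "category": str})
    required = ["rater_id", "stimulus_id", "condition", "category", "present"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"ratings file missing columns: {missing}")
    present = df["present"].astype(int)
    intensity = pd.to_numeric(df.get("intensity"), errors="coerce")
    value = np.where(present == 1, intensity, 0.0)
    if np.isnan(value).any():
        bad = int(np.flatnonzero(np.isnan(value))[0]) + 2  # 1-based + header
        raise ValidationError(
            f"present=1 with blank intensity near line {bad} of {path}")
    df["value"] = value.astype(int)
    return df[RATING_COLUMNS]


def write_codings_csv(codings: Sequence[AUCoding], path) -> None:
    """Write AU codings as paired presence/intensity columns."""
    rows = []
    for c in codings:
        row: Dict[str, object] = {"pose_id": c.pose_id, "coder_id": c.coder_id}
        for au in _AU_ORDER:
            row[f"AU{au}_present"] = int(au in c.intensity)
            row[f"AU{au}_intensity"] = c.intensity.get(au, pd.NA)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codings_csv(path) -> List[AUCoding]:
    """Read an AU coding CSV into one :class:`AUCoding` per row."""
    df = pd.read_csv(path, dtype={"pose_id": str, "coder_id": str})
    for col in ("pose_id", "coder_id"):
        if col not in df.columns:
            raise ValidationError(f"coding file missing column {col!r}")
    codings = []
    for _, row in df.iterrows():
        intensity: Dict[int, int] = {}
        for au in _AU_ORDER:
            pcol, icol = f"AU{au}_present", f"AU{au}_intensity"
            if pcol not in df.columns:
                raise ValidationError(f"coding file missing column {pcol!r}")
            if int(row[pcol]) == 1:
                level = row[icol]
                if pd.isna(level):
                    raise ValidationError(
                        f"pose {row['pose_id']}: AU{au} present without "
                        "intensity")
                intensity[au] = int(level)
        codings.append(AUCoding(pose_id=row["pose_id"],
                                coder_id=row["coder_id"],
                                intensity=intensity))
    return codings


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    def error(self, msg: str) -> None:
        self.issues.append(ValidationIssue("error", msg))

    def warn(self, msg: str) -> None:
        self.issues.append(ValidationIssue("warning", msg))

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def __str__(self) -> str:
        if not self.issues:
            return "OK: no issues found"
        return "\n".join(f"[{i.severity}] {i.message}" for i in self.issues)


def validate_tables(ratings_path: Optional[str] = None,
                    codings_path: Optional[str] = None) -> ValidationReport:
    """Schema and referential checks over the input tables.

    Violations are collected rather than raised, so one pass reports
    every problem; pose ids referenced by no rated stimulus are warnings
    (orphans), not errors.
    """
    report = ValidationReport()
    ratings = None
    stim_ids: set = set()
    if ratings_path is not None:
        try:
            raw = pd.read_csv(ratings_path)
        except Exception as exc:
            report.error(f"cannot read ratings file: {exc}")
            raw = None
        if raw is not None:
            for col in ("rater_id", "stimulus_id", "condition", "category",
                        "present"):
                if col not in raw.columns:
                    report.error(f"ratings: missing column {col!r}")
            if report.ok:
                bad_cond = set(raw["condition"]) - set(CONDITIONS)
                if bad_cond:
                    report.error(f"ratings: unknown conditions {sorted(bad_cond)}")
                bad_cat = set(raw["category"]) - set(CATEGORIES)
                if bad_cat:
                    report.error(f"ratings: unknown categories {sorted(bad_cat)}")
                if not raw["present"].isin([0, 1]).all():
                    rows = raw.index[~raw["present"].isin([0, 1])][:5] + 2
                    report.error(f"ratings: present not 0/1 at lines {list(rows)}")
                inten = pd.to_numeric(raw.get("intensity"), errors="coerce")
                bad = (raw["present"] == 1) & (~inten.isin([1, 2, 3, 4]))
                if bad.any():
                    rows = (raw.index[bad][:5] + 2).tolist()
                    report.error(
                        f"ratings: intensity outside 1-4 at lines {rows}")
                stim_ids = set(raw["stimulus_id"].astype(str))
                report.warn(f"ratings: {len(raw)} rows, "
                            f"{len(stim_ids)} stimuli")
    if codings_path is not None:
        try:
            raw = pd.read_csv(codings_path)
        except Exception as exc:
            report.error(f"cannot read codings file: {exc}")
            raw = None
        if raw is not None:
            for col in ("pose_id", "coder_id"):
                if col not in raw.columns:
                    report.error(f"codings: missing column {col!r}")
            for au in _AU_ORDER:
                pcol, icol = f"AU{au}_present", f"AU{au}_intensity"
                if pcol not in raw.columns or icol not in raw.columns:
                    report.error(f"codings: missing columns for AU{au}")
                    continue
                if not raw[pcol].isin([0, 1]).all():
                    report.error(f"codings: {pcol} not 0/1")
                inten = pd.to_numeric(raw[icol], errors="coerce")
                bad = (raw[pcol] == 1) & (~inten.isin([1, 2, 3, 4, 5]))
                if bad.any():
                    rows = (raw.index[bad][:5] + 2).tolist()
                    report.error(
                        f"codings: AU{au} intensity outside 1-5 at lines {rows}")
            if "AU3_present" in raw.columns:
                report.error("codings: AU3 column present (no AU3 in FACS)")
            if "pose_id" in raw.columns and stim_ids:
                poses = set(raw["pose_id"].astype(str))
                orphans = sorted(poses - stim_ids)
                if orphans:
                    report.warn(
                        f"codings: {len(orphans)} pose(s) referenced by no "
                        f"rated stimulus, e.g. {orphans[:5]}")
                unposed = sorted(stim_ids - poses)
                if unposed:
                    report.error(
                        f"{len(unposed)} rated stimulus(-i) without a coded "
                        f"pose, e.g. {unposed[:5]}")
    return report
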