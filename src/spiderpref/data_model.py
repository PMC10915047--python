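"""Canonical data model for spider-customization preference experiments.

A cohort consists of a participant table (one row per volunteer, with a
Spider Phobia Questionnaire score, SPQ, on the 0--30 scale) and a trial
table (one row per customization trial).  On each trial the participant
tuned three perceptual features of a virtual spider -- hairiness, body/leg
proportions and locomotion pattern -- on a 10-level grid, under one of two
instructions ("make it as dangerous as possible" / "as harmless as
possible") while the spider moved in one of three orientations.

Feature axes are fixed:

=============  ===================  ===================
feature        value 0              value 1
=============  ===================  ===================
hairiness      hairy                hairless
bodyleg        thick, stubby legs   slim, long legs
locomotion     butterfly-like       spider-like
=============  ===================  ===================

Files store the raw integer levels 0..9; in memory every feature value is
the grid point ``level / 9`` so that both extremes (0 and 1) are attainable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "INSTRUCTIONS",
    "ORIENTATIONS",
    "FEATURE_POLES",
    "GRID_LEVELS",
    "TRIALS_PER_PARTICIPANT",
    "TRIALS_PER_INSTRUCTION",
    "TRIALS_PER_ORIENTATION",
    "CohortError",
    "SchemaError",
    "GridRangeError",
    "IntegrityError",
    "CohortTable",
    "ValidationReport",
    "load_cohort",
    "save_cohort",
    "validate_design",
    "level_to_value",
    "value_to_level",
]

FEATURES = ("hairiness", "bodyleg", "locomotion")
INSTRUCTIONS = ("dangerous", "harmless")
ORIENTATIONS = ("approaching", "withdrawing", "lateral")

#: Label of the 0 pole and the 1 pole of each feature axis.
FEATURE_POLES: Mapping[str, tuple[str, str]] = {
    "hairiness": ("hairy", "hairless"),
    "bodyleg": ("thick", "slim"),
    "locomotion": ("butterfly-like", "spider-like"),
}

GRID_LEVELS = 10  # two extremes plus eight intermediate steps
TRIALS_PER_PARTICIPANT = 24
TRIALS_PER_INSTRUCTION = 12
TRIALS_PER_ORIENTATION = 8

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "instruction",
    "orientation",
    "hairiness_level",
    "bodyleg_level",
    "locomotion_level",
]
PARTICIPANT_COLUMNS = ["participant_id", "spq", "included", "age", "sex"]

SPQ_MAX = 30


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A required column is missing or a categorical value is unknown."""


class GridRangeError(CohortError):
    """A feature level or score lies outside its permitted range."""


class IntegrityError(CohortError):
    """A trial references a participant that does not exist."""


def level_to_value(level: np.ndarray | int) -> np.ndarray | float:
    """Map integer grid levels 0..9 to unit-interval values k/9."""
    return np.asarray(level, dtype=float) / (GRID_LEVELS - 1)


def value_to_level(value: np.ndarray | float) -> np.ndarray | int:
    """Map unit-interval values to the nearest integer grid level 0..9."""
    return np.rint(np.asarray(value, dtype=float) * (GRID_LEVELS - 1)).astype(int)


@dataclass
class CohortTable:
    """Validated cohort: participant and trial tables.

    ``participants`` has columns ``participant_id, spq, included, age, sex``;
    ``trials`` has columns ``participant_id, trial_index, instruction,
    orientation, hairiness, bodyleg, locomotion`` with feature values on the
    grid {k/9 : k=0..9}.
    """

    participants: pd.DataFrame
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p, t = self.participants, self.trials
        for col in ("participant_id", "spq", "included"):
            if col not in p.columns:
                raise SchemaError(f"participants table missing column {col!r}")
        for col in ("participant_id", "trial_index", "instruction", "orientation", *FEATURES):
            if col not in t.columns:
                raise SchemaError(f"trials table missing column {col!r}")
        if p["participant_id"].duplicated().any():
            dup = p.loc[p["participant_id"].duplicated(), "participant_id"].iloc[0]
            raise IntegrityError(f"duplicate participant_id {dup!r}")
        spq = p["spq"].to_numpy()
        if len(spq) and ((spq < 0) | (spq > SPQ_MAX)).any():
            bad = p.loc[(p["spq"] < 0) | (p["spq"] > SPQ_MAX)].iloc[0]
            raise GridRangeError(
                f"SPQ score {bad['spq']} of participant {bad['participant_id']!r} "
                f"outside 0..{SPQ_MAX}"
            )
        known = set(p["participant_id"])
        orphan = ~t["participant_id"].isin(known)
        if orphan.any():
            row = int(np.flatnonzero(orphan.to_numpy())[0])
            raise IntegrityError(
                f"trial row {row} references unknown participant "
                f"{t['participant_id'].iloc[row]!r}"
            )
        bad_instr = ~t["instruction"].isin(INSTRUCTIONS)
        if bad_instr.any():
            row = int(np.flatnonzero(bad_instr.to_numpy())[0])
            raise SchemaError(
                f"trial row {row}: unknown instruction {t['instruction'].iloc[row]!r}"
            )
        bad_orient = ~t["orientation"].isin(ORIENTATIONS)
        if bad_orient.any():
            row = int(np.flatnonzero(bad_orient.to_numpy())[0])
            raise SchemaError(
                f"trial row {row}: unknown orientation {t['orientation'].iloc[row]!r}"
            )
        for feat in FEATURES:
            v = t[feat].to_numpy(dtype=float)
            levels = v * (GRID_LEVELS - 1)
            off = ~np.isclose(levels, np.rint(levels)) | (v < 0) | (v > 1)
            if off.any():
                row = int(np.flatnonzero(off)[0])
                raise GridRangeError(
                    f"trial row {row}: {feat} value {v[row]!r} is not on the "
                    f"grid {{k/{GRID_LEVELS - 1}}}"
                )

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_of(self, participant_id: str) -> pd.DataFrame:
        return self.trials[self.trials["participant_id"] == participant_id]


@dataclass
class ValidationReport:
    """Per-participant design bookkeeping against the 24/12/8 layout."""

    per_participant: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "ok": self.ok,
                "flags": self.flags,
                "per_participant": self.per_participant.to_dict(orient="records"),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _read_csv(path: str | Path, required: list[str], table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} file {path} missing column(s) {missing}")
    return df


def load_cohort(trials_path: str | Path, participants_path: str | Path) -> CohortTable:
    """Read the canonical trial/participant CSVs into a validated cohort.

    Integer feature levels 0..9 in the file are mapped to grid values k/9.
    Raises :class:`SchemaError`, :class:`GridRangeError` or
    :class:`IntegrityError` on malformed input, naming the offending
    column or row.
    """
    level_cols = [f"{f}_level" for f in FEATURES]
    raw_t = _read_csv(trials_path, ["participant_id", "trial_index", "instruction",
                                    "orientation", *level_cols], "trials")
    raw_p = _read_csv(participants_path, ["participant_id", "spq", "included"],
                      "participants")

    for feat, col in zip(FEATURES, level_cols):
        lv = raw_t[col].to_numpy()
        bad = (lv < 0) | (lv > GRID_LEVELS - 1) | (lv != np.floor(lv))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise GridRangeError(
                f"trials row {row + 2} (file line): {col}={lv[row]!r} outside 0..9"
            )

    trials = raw_t[["participant_id", "trial_index", "instruction", "orientation"]].copy()
    for feat, col in zip(FEATURES, level_cols):
        trials[feat] = level_to_value(raw_t[col].to_numpy())

    participants = raw_p.copy()
    for col in ("age", "sex"):
        if col not in participants.columns:
            participants[col] = pd.NA
    participants = participants[PARTICIPANT_COLUMNS]
    participants["included"] = participants["included"].astype(bool)

    return CohortTable(participants=participants, trials=trials)


def save_cohort(cohort: CohortTable,
                trials_path: str | Path,
                participants_path: str | Path) -> None:
    """Write a cohort to the canonical CSVs (integer levels 0..9)."""
    out = cohort.trials[["participant_id", "trial_index", "instruction", "orientation"]].copy()
    for feat in FEATURES:
        out[f"{feat}_level"] = value_to_level(cohort.trials[feat].to_numpy())
    out.to_csv(trials_path, index=False)

    p = cohort.participants.copy()
    p.to_csv(participants_path, index=False)


def validate_design(cohort: CohortTable) -> ValidationReport:
    """Check every participant against the 24-trial balanced design.

    The full session comprises 24 trials: 12 per instruction and 8 per
    orientation (hence 4 per instruction x orientation cell).  Deviations
    are reported, never raised -- incomplete participants stay usable.
    """
    rows = []
    flags: list[str] = []
    for pid, grp in cohort.trials.groupby("participant_id", sort=True):
        n = len(grp)
        instr = grp["instruction"].value_counts().to_dict()
        orient = grp["orientation"].value_counts().to_dict()
        rec = {
            "participant_id": pid,
            "n_trials": n,
            **{f"n_{i}": int(instr.get(i, 0)) for i in INSTRUCTIONS},
            **{f"n_{o}": int(orient.get(o, 0)) for o in ORIENTATIONS},
        }
        rows.append(rec)
        if n != TRIALS_PER_PARTICIPANT:
            flags.append(f"{pid}: expected {TRIALS_PER_PARTICIPANT} trials, observed {n}")
        for i in INSTRUCTIONS:
            if instr.get(i, 0) != TRIALS_PER_INSTRUCTION:
                flags.append(
                    f"{pid}: expected {TRIALS_PER_INSTRUCTION} {i} trials, "
                    f"observed {instr.get(i, 0)}"
                )
        for o in ORIENTATIONS:
            if orient.get(o, 0) != TRIALS_PER_ORIENTATION:
                flags.append(
                    f"{pid}: expected {TRIALS_PER_ORIENTATION} {o} trials, "
                    f"observed {orient.get(o, 0)}"
                )
    listed = set(cohort.trials["participant_id"])
    for pid in cohort.participants["participant_id"]:
        if pid not in listed:
            rows.append({"participant_id": pid, "n_trials": 0,
                         **{f"n_{i}": 0 for i in INSTRUCTIONS},
                         **{f"n_{o}": 0 for o in ORIENTATIONS}})
            flags.append(f"{pid}: no trials recorded")
    report = pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)
    return ValidationReport(per_participant=report, flags=flags)
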