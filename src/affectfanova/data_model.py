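"""Domain types and file I/O for continuous emotion-rating studies.

The core objects mirror how two-dimensional emotion-space (2DES) rating
experiments are organised: each participant produces one rating curve per
stimulus and per affect dimension (valence or arousal), sampled on a uniform
1 Hz grid and normalized to [-1, 1] with 0 as the neutral point.  A
:class:`StudyDataset` bundles the rating curves with stimulus metadata and
participant covariates; grouping factors dichotomize participants for the
functional tests.

On disk the canonical format is a long (tidy) ratings CSV with columns
``participant, stimulus, dimension, time_s, value`` plus a companion
covariates CSV.  Battery results serialize to a TSV with a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("affectfanova")

DIMENSIONS = ("valence", "arousal")
MODALITIES = ("music", "speech")
QUADRANTS = ("Q1", "Q2", "Q3", "Q4")
EXCLUSION_FLAGS = ("measurement_error", "non_native")

#: typical stimulus grid lengths (seconds at 1 Hz) in 2DES listening studies
GRID_LENGTH_RANGE = (45, 156)

DEFAULT_SCHEMA = {
    "participant": "participant",
    "stimulus": "stimulus",
    "dimension": "dimension",
    "time_s": "time_s",
    "value": "value",
}


class SchemaError(ValueError):
    """A required column or configuration entry is missing or malformed."""


class StructuralError(ValueError):
    """The data violate a structural contract (grids, duplicates, shapes)."""


class DuplicateKeyError(StructuralError):
    """Two rows claim the same (participant, stimulus, dimension, time)."""


class ValidationError(ValueError):
    """A value is outside its documented range."""


class GridLengthWarning(UserWarning):
    """A rating grid is shorter/longer than typical study stimuli."""


def load_schema(path) -> dict:
    """Read a YAML column-name mapping and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_SCHEMA)
    if unknown:
        raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
    return {**DEFAULT_SCHEMA, **user}


@dataclass
class RatingSeries:
    """One participant's rating of one stimulus on one affect dimension.

    ``values`` live on a uniform 1 Hz grid ``t`` starting at 0 s; the value
    at time t is the rating prevailing during the second [t, t+1).
    """

    participant_id: str
    stimulus_id: str
    dimension: str
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.dimension not in DIMENSIONS:
            raise ValidationError(
                f"dimension must be one of {DIMENSIONS}, got {self.dimension!r}"
            )
        if self.t.ndim != 1 or self.values.ndim != 1:
            raise StructuralError("t and values must be 1-D")
        if len(self.t) != len(self.values):
            raise StructuralError(
                f"t and values length mismatch: {len(self.t)} != {len(self.values)}"
            )
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, 1.0):
                raise StructuralError(
                    f"grid must be uniform 1 Hz for participant={self.participant_id} "
                    f"stimulus={self.stimulus_id}"
                )
        if len(self.t) and self.t[0] != 0:
            raise StructuralError("grid must start at 0 s")
        if np.any(self.values < -1 - 1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValidationError(
                f"values outside [-1, 1] for participant={self.participant_id} "
                f"stimulus={self.stimulus_id} dimension={self.dimension}"
            )
        lo, hi = GRID_LENGTH_RANGE
        if not lo <= len(self.t) <= hi:
            warnings.warn(
                f"grid length {len(self.t)} outside typical range {GRID_LENGTH_RANGE} "
                f"(stimulus={self.stimulus_id})",
                GridLengthWarning,
                stacklevel=2,
            )

    @property
    def duration(self) -> int:
        return len(self.t)

    def __eq__(self, other):
        if not isinstance(other, RatingSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.stimulus_id == other.stimulus_id
            and self.dimension == other.dimension
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class StimulusInfo:
    """Metadata for one music piece or speech sample."""

    stimulus_id: str
    modality: str
    duration: float
    expected_quadrants: tuple = ()

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        bad = set(self.expected_quadrants) - set(QUADRANTS)
        if bad:
            raise ValidationError(f"unknown quadrants: {sorted(bad)}")


@dataclass
class ParticipantRecord:
    """Covariates for one participant.

    Questionnaire items use 7-point scales (1..7); the six mood items use a
    semantic-differential scale (-3..3), three valence then three arousal.
    """

    participant_id: str
    age: float | None = None
    gender: str | None = None
    training_category: str | None = None
    tipi_items: tuple | None = None
    teique_items: tuple | None = None
    mood_pre: tuple | None = None
    mood_post: tuple | None = None
    exclusion_flags: frozenset = frozenset()

    def __post_init__(self):
        if self.age is not None and self.age < 0:
            raise ValidationError(f"age must be non-negative, got {self.age}")
        for name, items, n, lo, hi in (
            ("tipi_items", self.tipi_items, 10, 1, 7),
            ("teique_items", self.teique_items, 30, 1, 7),
            ("mood_pre", self.mood_pre, 6, -3, 3),
            ("mood_post", self.mood_post, 6, -3, 3),
        ):
            if items is None:
                continue
            items = tuple(items)
            setattr(self, name, items)
            if len(items) != n:
                raise ValidationError(f"{name} must have {n} entries, got {len(items)}")
            for i, v in enumerate(items):
                if not lo <= v <= hi:
                    raise ValidationError(
                        f"{name}[{i}] = {v} outside [{lo}, {hi}] "
                        f"(participant {self.participant_id})"
                    )
        self.exclusion_flags = frozenset(self.exclusion_flags)
        bad = self.exclusion_flags - set(EXCLUSION_FLAGS)
        if bad:
            raise ValidationError(f"unknown exclusion flags: {sorted(bad)}")


@dataclass
class GroupingFactor:
    """A named dichotomization of participants into two levels.

    ``assignment`` maps every participant id to one of the two labels in
    ``levels`` or to ``"excluded"`` (e.g. the middle musical-training band).
    """

    name: str
    levels: tuple
    assignment: dict

    def __post_init__(self):
        if len(self.levels) != 2 or self.levels[0] == self.levels[1]:
            raise ValidationError("a grouping factor needs two distinct levels")
        allowed = set(self.levels) | {"excluded"}
        for pid, label in self.assignment.items():
            if label not in allowed:
                raise ValidationError(
                    f"participant {pid} assigned unknown label {label!r} "
                    f"for factor {self.name}"
                )

    def members(self, level) -> list:
        return sorted(p for p, lab in self.assignment.items() if lab == level)

    def group_ids(self):
        """(level_a members, level_b members), excluded dropped."""
        return self.members(self.levels[0]), self.members(self.levels[1])

    def swap_levels(self) -> "GroupingFactor":
        return GroupingFactor(self.name, (self.levels[1], self.levels[0]), dict(self.assignment))


@dataclass
class FanovaResult:
    """Outcome of one bootstrap functional ANOVA."""

    statistic: float
    p_value: float
    n_bootstrap: int
    bandwidth: float
    seed: object
    group_sizes: tuple

    def __post_init__(self):
        if self.statistic < 0:
            raise ValidationError("statistic must be non-negative")
        min_p = 1.0 / (self.n_bootstrap + 1)
        if not (min_p - 1e-12 <= self.p_value <= 1 + 1e-12):
            raise ValidationError(
                f"p-value {self.p_value} outside [1/(B+1), 1] = [{min_p}, 1]"
            )

    @property
    def n_a(self):
        return self.group_sizes[0]

    @property
    def n_b(self):
        return self.group_sizes[1]


BATTERY_COLUMNS = [
    "test_index",
    "modality",
    "stimulus_id",
    "dimension",
    "factor",
    "n_a",
    "n_b",
    "statistic",
    "bandwidth",
    "p_raw",
    "p_adjusted",
    "significant",
    "excluded_for_reliability",
    "error",
]


@dataclass
class BatteryResult:
    """Table of per-test outcomes for a full stimulus x dimension x factor battery."""

    table: pd.DataFrame
    config: dict = field(default_factory=dict)
    seed: object = None

    def __post_init__(self):
        missing = [c for c in BATTERY_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"battery table missing columns: {missing}")
        ok = self.table["p_raw"].notna()
        if (self.table.loc[ok, "p_adjusted"] < self.table.loc[ok, "p_raw"] - 1e-12).any():
            raise ValidationError("adjusted p-values must be >= raw p-values")
        bad = self.table["significant"].fillna(False) & self.table["excluded_for_reliability"]
        if bad.any():
            raise ValidationError("a reliability-excluded test cannot be significant")


# ---------------------------------------------------------------------------
# Study container


@dataclass
class StudyDataset:
    """Ratings + stimulus metadata + participant covariates for one experiment."""

    ratings: list
    stimuli: dict
    participants: dict

    def __post_init__(self):
        self._index = {}
        for s in self.ratings:
            key = (s.stimulus_id, s.dimension)
            self._index.setdefault(key, []).append(s)

    @property
    def participant_ids(self):
        return sorted(self.participants) if self.participants else sorted(
            {s.participant_id for s in self.ratings}
        )

    @property
    def stimulus_ids(self):
        return list(self.stimuli) if self.stimuli else sorted(
            {s.stimulus_id for s in self.ratings}
        )

    def series(self, stimulus_id, dimension):
        return list(self._index.get((stimulus_id, dimension), []))

    def curve_matrix(self, stimulus_id, dimension, participant_ids=None):
        """Return (t, matrix, participant_ids) with one curve per row.

        Raises :class:`StructuralError` if the participants' grids disagree.
        """
        series = self.series(stimulus_id, dimension)
        if not series:
            raise StructuralError(f"no ratings for {stimulus_id}/{dimension}")
        by_pid = {s.participant_id: s for s in series}
        if participant_ids is None:
            participant_ids = sorted(by_pid)
        missing = [p for p in participant_ids if p not in by_pid]
        if missing:
            raise StructuralError(
                f"participants without ratings for {stimulus_id}/{dimension}: {missing}"
            )
        lengths = {len(by_pid[p].t) for p in participant_ids}
        if len(lengths) != 1:
            raise StructuralError(
                f"non-uniform grids for {stimulus_id}/{dimension}: lengths {sorted(lengths)}"
            )
        t = by_pid[participant_ids[0]].t
        mat = np.vstack([by_pid[p].values for p in participant_ids])
        return t, mat, list(participant_ids)

    def apply_participant_exclusions(self, flags=EXCLUSION_FLAGS) -> "StudyDataset":
        """Drop participants carrying any of the given exclusion flags."""
        retained = apply_participant_exclusions(self.participants, flags)
        keep = set(retained)
        return StudyDataset(
            ratings=[s for s in self.ratings if s.participant_id in keep],
            stimuli=dict(self.stimuli),
            participants=retained,
        )


def apply_participant_exclusions(participants: Mapping, flags=EXCLUSION_FLAGS) -> dict:
    """Return the sub-roster of participants with none of the given flags set."""
    flags = set(flags)
    return {
        pid: rec
        for pid, rec in participants.items()
        if not (rec.exclusion_flags & flags)
    }


# ---------------------------------------------------------------------------
# Ratings / covariates CSV I/O

_COV_COLUMNS = (
    ["participant", "age", "gender", "training", "exclusions"]
    + [f"tipi_{i}" for i in range(1, 11)]
    + [f"teique_{i}" for i in range(1, 31)]
    + [f"mood_pre_{i}" for i in range(1, 7)]
    + [f"mood_post_{i}" for i in range(1, 7)]
)


def read_ratings_csv(path, covariates_path=None, schema=None, stimuli=None) -> StudyDataset:
    """Read a long-format ratings CSV (plus optional covariates CSV).

    Missing seconds inside a participant's series are filled by
    last-observation-carried-forward (the rating device's position persists
    between movements); a leading gap is filled with 0 (neutral start).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    missing = [v for v in schema.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"ratings file missing required column(s): {missing}")
    df = df.rename(columns={v: k for k, v in schema.items()})
    df["participant"] = df["participant"].astype(str)
    df["stimulus"] = df["stimulus"].astype(str)

    key_cols = ["participant", "stimulus", "dimension", "time_s"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        rows = df.loc[dup, key_cols].head(5).to_dict("records")
        raise DuplicateKeyError(f"duplicated rating keys, e.g. {rows}")

    n_missing = int(df["value"].isna().sum())
    if n_missing:
        logger.warning("ratings file has %d missing values; dropped then LOCF-filled", n_missing)
        df = df.dropna(subset=["value"])

    times = df["time_s"].to_numpy(dtype=float)
    if np.any(times < 0) or np.any(times != np.round(times)):
        bad = df.loc[(times < 0) | (times != np.round(times)), key_cols].head(5)
        raise StructuralError(
            f"time_s must be non-negative whole seconds; offending rows: {bad.to_dict('records')}"
        )
    df["time_s"] = df["time_s"].astype(int)

    # common per-stimulus grid: 0 .. max observed second across participants
    stim_len = df.groupby("stimulus")["time_s"].max().to_dict()
    ratings = []
    for (pid, stim, dim), grp in df.groupby(["participant", "stimulus", "dimension"], sort=True):
        T = stim_len[stim] + 1
        vals = np.full(T, np.nan)
        vals[grp["time_s"].to_numpy()] = grp["value"].to_numpy()
        vals = pd.Series(vals).ffill().fillna(0.0).to_numpy()
        ratings.append(RatingSeries(pid, stim, dim, np.arange(T, dtype=float), vals))

    participants = {}
    if covariates_path is not None:
        participants = read_covariates_csv(covariates_path)
    if stimuli is None:
        stimuli = {}
    return StudyDataset(ratings=ratings, stimuli=stimuli, participants=participants)


def write_ratings_csv(dataset: StudyDataset, path, covariates_path=None, schema=None):
    """Write a StudyDataset back to the canonical long CSV layout."""
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    frames = []
    for s in dataset.ratings:
        frames.append(
            pd.DataFrame(
                {
                    schema["participant"]: s.participant_id,
                    schema["stimulus"]: s.stimulus_id,
                    schema["dimension"]: s.dimension,
                    schema["time_s"]: s.t.astype(int),
                    schema["value"]: s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if covariates_path is not None and dataset.participants:
        write_covariates_csv(dataset.participants, covariates_path)


def write_stimuli_csv(stimuli: Mapping, path):
    rows = [
        {
            "stimulus_id": s.stimulus_id,
            "modality": s.modality,
            "duration": s.duration,
            "expected_quadrants": ";".join(s.expected_quadrants),
        }
        for s in stimuli.values()
    ]
    pd.DataFrame(rows, columns=["stimulus_id", "modality", "duration", "expected_quadrants"]).to_csv(
        path, index=False
    )


def read_stimuli_csv(path) -> dict:
    df = pd.read_csv(path)
    required = {"stimulus_id", "modality", "duration"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"stimuli file missing required column(s): {missing}")
    out = {}
    for _, row in df.iterrows():
        quads = ()
        if "expected_quadrants" in df.columns and isinstance(row.get("expected_quadrants"), str):
            quads = tuple(q for q in row["expected_quadrants"].split(";") if q)
        out[str(row["stimulus_id"])] = StimulusInfo(
            str(row["stimulus_id"]), str(row["modality"]), float(row["duration"]), quads
        )
    return out


def read_covariates_csv(path) -> dict:
    df = pd.read_csv(path)
    if "participant" not in df.columns:
        raise SchemaError("covariates file missing required column: participant")
    participants = {}
    for _, row in df.iterrows():
        pid = str(row["participant"])

        def _items(prefix, n, cast=float):
            cols = [f"{prefix}_{i}" for i in range(1, n + 1)]
            if not all(c in df.columns for c in cols):
                return None
            vals = [row[c] for c in cols]
            if any(pd.isna(v) for v in vals):
                return None
            return tuple(cast(v) for v in vals)

        flags = ()
        if "exclusions" in df.columns and isinstance(row.get("exclusions"), str):
            flags = tuple(f for f in row["exclusions"].split(";") if f)
        participants[pid] = ParticipantRecord(
            participant_id=pid,
            age=None if "age" not in df.columns or pd.isna(row.get("age")) else float(row["age"]),
            gender=None if "gender" not in df.columns or pd.isna(row.get("gender")) else str(row["gender"]),
            training_category=None
            if "training" not in df.columns or pd.isna(row.get("training"))
            else str(row["training"]),
            tipi_items=_items("tipi", 10),
            teique_items=_items("teique", 30),
            mood_pre=_items("mood_pre", 6),
            mood_post=_items("mood_post", 6),
            exclusion_flags=frozenset(flags),
        )
    return participants


def write_covariates_csv(participants: Mapping, path):
    rows = []
    for pid in sorted(participants):
        rec = participants[pid]
        row = {
            "participant": pid,
            "age": rec.age,
            "gender": rec.gender,
            "training": rec.training_category,
            "exclusions": ";".join(sorted(rec.exclusion_flags)),
        }
        for prefix, items, n in (
            ("tipi", rec.tipi_items, 10),
            ("teique", rec.teique_items, 30),
            ("mood_pre", rec.mood_pre, 6),
            ("mood_post", rec.mood_post, 6),
        ):
            for i in range(1, n + 1):
                row[f"{prefix}_{i}"] = None if items is None else items[i - 1]
        rows.append(row)
    pd.DataFrame(rows, columns=_COV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Battery result I/O

from . import __about__  # noqa: E402  (version constant, avoids circular import)


def write_battery_results(result: BatteryResult, path):
    """Write a battery table as TSV plus a JSON sidecar (config, seed, version)."""
    path = str(path)
    result.table.to_csv(path, sep="\t", index=False, columns=BATTERY_COLUMNS)
    sidecar = {
        "config": result.config,
        "seed": result.seed,
        "software": {"package": "affectfanova", "version": __about__.__version__},
        "n_tests": int(len(result.table)),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def read_battery_results(path) -> BatteryResult:
    path = str(path)
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"stimulus_id": str, "factor": str, "error": str},
    )
    for col in ("significant", "excluded_for_reliability"):
        table[col] = table[col].astype(bool)
    with open(_sidecar_path(path)) as fh:
        sidecar = json.load(fh)
    return BatteryResult(table=table, config=sidecar.get("config", {}), seed=sidecar.get("seed"))


def _sidecar_path(path: str) -> str:
    base = path[: -len(".tsv")] if path.endswith(".tsv") else path
    return base + ".json"
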