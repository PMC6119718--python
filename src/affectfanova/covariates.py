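"""Questionnaire scoring and construction of dichotomous grouping factors.

Personality is scored from the Ten-Item Personality Inventory (TIPI): each of
the Big-Five dimensions is the mean of one direct and one reverse-keyed item
(recoded as 8 - x).  Trait emotional intelligence (EI) is the mean of the 30
TEIQue-SF items after reverse-keying.  Both instruments use 7-point scales.

Nine grouping factors drive the test battery: mean splits (sign of the
within-sample z-score) on the five personality dimensions and EI, the
recorded gender, a musical-training contrast (>= 10 years vs < 1 year, the
middle band excluded), and an age split at > 40 years.
"""

from __future__ import annotations

import numpy as np

from .data_model import GroupingFactor, ValidationError

# Standard TIPI key: dimension -> (direct item, reverse-keyed item), 1-based.
DEFAULT_TIPI_KEY = {
    "Extroversion": (1, 6),
    "Agreeableness": (7, 2),
    "Conscientiousness": (3, 8),
    "EmotionalStability": (9, 4),
    "Openness": (5, 10),
}

# Standard TEIQue-SF reverse-keyed items (1-based).
DEFAULT_TEIQUE_REVERSE = (2, 4, 5, 7, 8, 10, 12, 13, 14, 16, 18, 22, 25, 26, 28)

TRAIT_NAMES = tuple(DEFAULT_TIPI_KEY) + ("EI",)
FACTOR_NAMES = TRAIT_NAMES + ("Gender", "MusicalTraining", "Age")

TRAINING_UNTRAINED = "<1 yr"
TRAINING_MIDDLE = "1-10 yr"
TRAINING_TRAINED = ">10 yr"
_TRAINING_ALIASES = {
    TRAINING_UNTRAINED: TRAINING_UNTRAINED,
    "<1 year": TRAINING_UNTRAINED,
    TRAINING_MIDDLE: TRAINING_MIDDLE,
    "1–10 yr": TRAINING_MIDDLE,
    "1-10 years": TRAINING_MIDDLE,
    TRAINING_TRAINED: TRAINING_TRAINED,
    ">10 years": TRAINING_TRAINED,
}

AGE_SPLIT_YEARS = 40


class ConfigError(ValueError):
    """A scoring key or factor configuration is malformed."""


class DegenerateFactorError(ValueError):
    """All scores identical: a mean split is undefined."""


def _check_items(items, n, lo, hi, what):
    items = tuple(float(v) for v in items)
    if len(items) != n:
        raise ValidationError(f"{what} needs {n} responses, got {len(items)}")
    for i, v in enumerate(items):
        if not lo <= v <= hi:
            raise ValidationError(f"{what} item {i + 1} = {v} outside [{lo}, {hi}]")
    return items


def score_tipi(items_10, key=None) -> dict:
    """Big-Five dimension scores from the 10 TIPI responses.

    Each dimension is the mean of its direct item and its reverse-keyed item
    recoded as 8 - x; a response of 4 is the fixed point of the reversal.
    """
    items = _check_items(items_10, 10, 1, 7, "TIPI")
    key = key or DEFAULT_TIPI_KEY
    scores = {}
    for dim, (direct, reversed_) in key.items():
        if not (1 <= direct <= 10 and 1 <= reversed_ <= 10):
            raise ConfigError(f"TIPI key for {dim} references items outside 1..10")
        scores[dim] = (items[direct - 1] + (8.0 - items[reversed_ - 1])) / 2.0
    return scores


def score_teique(items_30, reverse_key=DEFAULT_TEIQUE_REVERSE) -> float:
    """Global trait-EI score: mean of the 30 items after reverse-keying.

    ``reverse_key`` is either a sequence of 1-based item indices to reverse
    (recode as 8 - x) or a boolean mask of length 30.
    """
    items = np.array(_check_items(items_30, 30, 1, 7, "TEIQue-SF"))
    mask = np.zeros(30, dtype=bool)
    reverse_key = tuple(reverse_key)
    if reverse_key and all(isinstance(v, (bool, np.bool_)) for v in reverse_key):
        if len(reverse_key) != 30:
            raise ConfigError(f"boolean reverse key must have length 30, got {len(reverse_key)}")
        mask = np.array(reverse_key, dtype=bool)
    else:
        for idx in reverse_key:
            if not (isinstance(idx, (int, np.integer)) and 1 <= idx <= 30):
                raise ConfigError(f"reverse-key index {idx!r} outside 1..30")
            mask[int(idx) - 1] = True
    items = np.where(mask, 8.0 - items, items)
    return float(items.mean())


def trait_scores(participants: dict, tipi_key=None, teique_reverse=DEFAULT_TEIQUE_REVERSE) -> dict:
    """Per-participant E/A/C/ES/O and EI scores for a roster."""
    out = {}
    for pid, rec in participants.items():
        if rec.tipi_items is None or rec.teique_items is None:
            raise ValidationError(f"participant {pid} lacks questionnaire items")
        scores = score_tipi(rec.tipi_items, key=tipi_key)
        scores["EI"] = score_teique(rec.teique_items, reverse_key=teique_reverse)
        out[pid] = scores
    return out


def dichotomize_by_mean(scores: dict, name: str, tie_level: str = "low") -> GroupingFactor:
    """Split participants at the sample mean (sign of the z-score).

    z > 0 -> "high", z < 0 -> "low"; an exact tie at the mean goes to
    ``tie_level`` ("low" by default) for determinism.  The split is invariant
    under any positive affine transform of the scores.
    """
    if tie_level not in ("low", "high"):
        raise ConfigError("tie_level must be 'low' or 'high'")
    pids = sorted(scores)
    if len(pids) < 4:
        raise ValidationError("mean split needs at least 4 participants")
    vals = np.array([scores[p] for p in pids], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("scores must be finite")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DegenerateFactorError(f"all {name} scores identical: split undefined")
    z = (vals - vals.mean()) / sd
    assignment = {}
    for pid, zi in zip(pids, z):
        if zi > 0:
            assignment[pid] = "high"
        elif zi < 0:
            assignment[pid] = "low"
        else:
            assignment[pid] = tie_level
    return GroupingFactor(name=name, levels=("low", "high"), assignment=assignment)


def categorize_training(training_category: str) -> str:
    """Map an ordinal training band to trained / untrained / excluded.

    Ten or more years of formal training counts as "trained", under one year
    as "untrained"; the middle band is excluded from this factor only.
    """
    if training_category is None:
        raise ValidationError("missing training category")
    canon = _TRAINING_ALIASES.get(str(training_category))
    if canon is None:
        raise ValidationError(f"unknown training category {training_category!r}")
    if canon == TRAINING_TRAINED:
        return "trained"
    if canon == TRAINING_UNTRAINED:
        return "untrained"
    return "excluded"


def categorize_age(age: float) -> str:
    """Age split: strictly over 40 years -> "old", otherwise "young"."""
    if age is None or age < 0:
        raise ValidationError(f"invalid age {age!r}")
    return "old" if age > AGE_SPLIT_YEARS else "young"


def mood_scores(mood_items_6, valence_items=(0, 1, 2), arousal_items=(3, 4, 5)):
    """(valence_mood, arousal_mood): means of the 3 items per dimension."""
    items = _check_items(mood_items_6, 6, -3, 3, "mood")
    v = float(np.mean([items[i] for i in valence_items]))
    a = float(np.mean([items[i] for i in arousal_items]))
    return v, a


def mood_change(pre_items, post_items):
    """Post-minus-pre difference in (valence_mood, arousal_mood)."""
    v0, a0 = mood_scores(pre_items)
    v1, a1 = mood_scores(post_items)
    return v1 - v0, a1 - a0


def build_grouping_factors(
    participants: dict,
    tipi_key=None,
    teique_reverse=DEFAULT_TEIQUE_REVERSE,
    tie_level="low",
) -> dict:
    """The nine grouping factors keyed by name.

    Mean splits on the five personality dimensions and EI; gender from the
    recorded variable; trained-vs-untrained musical training; young/old age.
    """
    traits = trait_scores(participants, tipi_key=tipi_key, teique_reverse=teique_reverse)
    factors = {}
    for name in TRAIT_NAMES:
        scores = {pid: traits[pid][name] for pid in traits}
        factors[name] = dichotomize_by_mean(scores, name, tie_level=tie_level)

    genders = sorted({rec.gender for rec in participants.values() if rec.gender is not None})
    if len(genders) != 2:
        raise ValidationError(f"gender factor needs exactly 2 recorded levels, got {genders}")
    factors["Gender"] = GroupingFactor(
        name="Gender",
        levels=tuple(genders),
        assignment={pid: rec.gender for pid, rec in participants.items()},
    )

    factors["MusicalTraining"] = GroupingFactor(
        name="MusicalTraining",
        levels=("untrained", "trained"),
        assignment={
            pid: categorize_training(rec.training_category)
            for pid, rec in participants.items()
        },
    )

    factors["Age"] = GroupingFactor(
        name="Age",
        levels=("young", "old"),
        assignment={pid: categorize_age(rec.age) for pid, rec in participants.items()},
    )
    return factors
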