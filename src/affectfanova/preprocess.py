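"""Normalization, mean curves, quadrant labels, and reliability screening.

Continuous 2DES ratings arrive on an arbitrary device scale and are mapped
affinely onto [-1, 1] with 0 as neutral.  Panel reliability of the per-second
rating curves is measured with Cronbach's alpha, treating participants as the
"items" and time points as the cases; stimulus x dimension pairs whose alpha
falls below a threshold are excluded from downstream testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import (
    DIMENSIONS,
    RatingSeries,
    StructuralError,
    StudyDataset,
    ValidationError,
)

#: default keep/drop cut for panel reliability; chosen so that alphas in the
#: high 0.7s are retained while mid-0.7s and below are dropped
DEFAULT_RELIABILITY_THRESHOLD = 0.75


class ReliabilityError(ValueError):
    """Cronbach's alpha is undefined for the given matrix."""


def normalize(values, raw_min: float, raw_max: float) -> np.ndarray:
    """Affinely map ``values`` from [raw_min, raw_max] onto [-1, 1].

    The midpoint of the raw range maps to 0 (neutral); the endpoints map to
    -1 and +1.  Order-preserving by construction.
    """
    if raw_max == raw_min:
        raise ValidationError("degenerate raw range: raw_max == raw_min")
    if raw_max < raw_min:
        raise ValidationError("raw_max must exceed raw_min")
    values = np.asarray(values, dtype=float)
    if np.any(values < raw_min) or np.any(values > raw_max):
        raise ValidationError("values outside the declared raw range")
    return 2.0 * (values - raw_min) / (raw_max - raw_min) - 1.0


def denormalize(values, raw_min: float, raw_max: float) -> np.ndarray:
    """Inverse of :func:`normalize`."""
    values = np.asarray(values, dtype=float)
    return (values + 1.0) * (raw_max - raw_min) / 2.0 + raw_min


def mean_curve(series_list) -> RatingSeries:
    """Pointwise arithmetic mean of rating curves sharing one grid.

    All series must refer to the same stimulus and dimension; the result is
    the panel mean curve (participant_id ``"mean"``).
    """
    if not series_list:
        raise StructuralError("mean_curve needs at least one series")
    first = series_list[0]
    for s in series_list[1:]:
        if s.stimulus_id != first.stimulus_id or s.dimension != first.dimension:
            raise StructuralError("series mix stimuli or dimensions")
        if len(s.t) != len(first.t) or not np.array_equal(s.t, first.t):
            raise StructuralError(
                f"grid mismatch between participants {first.participant_id} "
                f"and {s.participant_id}"
            )
    mat = np.vstack([s.values for s in series_list])
    return RatingSeries(
        participant_id="mean",
        stimulus_id=first.stimulus_id,
        dimension=first.dimension,
        t=first.t.copy(),
        values=mat.mean(axis=0),
    )


def classify_quadrant(valence: float, arousal: float) -> str:
    """Label a 2DES point by its quadrant.

    Q1: +valence/+arousal, Q2: -valence/+arousal, Q3: -valence/-arousal,
    Q4: +valence/-arousal.  Points on either axis are ``"neutral"``; they are
    never silently assigned to a quadrant.
    """
    if not (-1 <= valence <= 1 and -1 <= arousal <= 1):
        raise ValidationError("valence and arousal must lie in [-1, 1]")
    if valence == 0 or arousal == 0:
        return "neutral"
    if valence > 0:
        return "Q1" if arousal > 0 else "Q4"
    return "Q2" if arousal > 0 else "Q3"


def classify_quadrant_curve(valence_values, arousal_values) -> list:
    """Vector version of :func:`classify_quadrant` over paired curves."""
    return [classify_quadrant(v, a) for v, a in zip(valence_values, arousal_values, strict=True)]


def cronbach_alpha(rating_matrix) -> float:
    """Cronbach's alpha of a time-points x raters matrix.

    alpha = k/(k-1) * (1 - sum_i Var(column_i) / Var(row sums)), with sample
    variances (denominator T-1).  Raters are the "items"; the T per-second
    ratings are the cases.  May be negative when raters disagree
    systematically; negative values are reported as-is.
    """
    X = np.asarray(rating_matrix, dtype=float)
    if X.ndim != 2:
        raise ReliabilityError("rating matrix must be 2-D (time x raters)")
    T, k = X.shape
    if k < 2:
        raise ReliabilityError(f"need at least 2 raters, got {k}")
    if T < 3:
        raise ReliabilityError(f"need at least 3 time points, got {T}")
    if np.isnan(X).any():
        raise ReliabilityError("rating matrix contains missing values")
    total_var = X.sum(axis=1).var(ddof=1)
    item_var = X.var(axis=0, ddof=1).sum()
    # exact disagreement (e.g. perfect mirror raters) collapses the row sums
    # to a constant: the ratio, and hence alpha, is undefined
    if total_var <= 1e-12 * max(item_var, 1e-300):
        raise ReliabilityError("zero total variance: reliability undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def reliability_table(dataset: StudyDataset, threshold: float = DEFAULT_RELIABILITY_THRESHOLD) -> pd.DataFrame:
    """Cronbach's alpha per stimulus x dimension over all participants.

    Returns a frame with columns (stimulus_id, dimension, alpha, retained),
    one row per stimulus x dimension present in the dataset.
    """
    rows = []
    for stim in dataset.stimulus_ids:
        for dim in DIMENSIONS:
            if not dataset.series(stim, dim):
                continue
            _, mat, _ = dataset.curve_matrix(stim, dim)
            alpha = cronbach_alpha(mat.T)  # raters become columns
            rows.append(
                {
                    "stimulus_id": stim,
                    "dimension": dim,
                    "alpha": alpha,
                    "retained": bool(alpha >= threshold),
                }
            )
    return pd.DataFrame(rows, columns=["stimulus_id", "dimension", "alpha", "retained"])


def pooled_reliability(dataset: StudyDataset) -> dict:
    """Overall alpha per dimension from the stimulus-concatenated series."""
    out = {}
    for dim in DIMENSIONS:
        blocks = []
        for stim in dataset.stimulus_ids:
            if not dataset.series(stim, dim):
                continue
            _, mat, pids = dataset.curve_matrix(stim, dim)
            blocks.append(mat)
        if blocks:
            out[dim] = cronbach_alpha(np.hstack(blocks).T)
    return out


def apply_reliability_filter(table: pd.DataFrame, threshold: float = DEFAULT_RELIABILITY_THRESHOLD):
    """Split stimulus x dimension pairs into retained and excluded sets.

    Pairs with alpha below ``threshold`` are excluded; the test battery skips
    them while still counting them in its enumeration.

    Returns ``(retained, excluded)``: a set and a sorted list of
    (stimulus_id, dimension) tuples.
    """
    retained, excluded = set(), []
    for _, row in table.iterrows():
        key = (row["stimulus_id"], row["dimension"])
        if row["alpha"] < threshold:
            excluded.append(key)
        else:
            retained.add(key)
    return retained, sorted(excluded)


def write_reliability_report(table: pd.DataFrame, path, threshold: float = DEFAULT_RELIABILITY_THRESHOLD):
    """TSV report: one row per stimulus, arousal/valence alphas + retained flags."""
    wide = table.pivot(index="stimulus_id", columns="dimension", values="alpha")
    out = pd.DataFrame(index=wide.index)
    for dim in DIMENSIONS:
        if dim in wide:
            out[f"alpha_{dim}"] = wide[dim].round(4)
            out[f"retained_{dim}"] = wide[dim] >= threshold
    out.reset_index().to_csv(path, sep="\t", index=False)
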