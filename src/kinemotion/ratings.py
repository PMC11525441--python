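"""Observer-experiment computations: confusion matrices, recognition
summaries, and chance-level goodness-of-fit tests."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EMOTIONS",
    "PRESENTATIONS",
    "RATINGS_COLUMNS",
    "ChanceTestResult",
    "load_ratings",
    "validate_ratings",
    "confusion_matrix",
    "chance_level",
    "chance_test",
    "recognition_summary",
]

EMOTIONS = ("anger", "contentment", "fear", "joy", "neutrality", "sadness")
PRESENTATIONS = ("avatar", "FLD", "PLD", "silhouette")

RATINGS_COLUMNS = (
    "participant",
    "stimulus",
    "sequence",
    "presentation",
    "intended",
    "decoded",
    "beauty",
)


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, emotion categories and beauty range."""
    missing = set(RATINGS_COLUMNS) - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table is missing columns: {sorted(missing)}")
    for col in ("intended", "decoded"):
        bad = set(ratings[col].unique()) - set(EMOTIONS)
        if bad:
            raise ValueError(f"column {col!r} contains unknown emotions: {sorted(bad)}")
    if ((ratings["beauty"] < 0) | (ratings["beauty"] > 100)).any():
        raise ValueError("beauty scores must be in [0, 100]")
    return ratings


def load_ratings(path) -> pd.DataFrame:
    return validate_ratings(pd.read_csv(path))


def _matrix(block: pd.DataFrame, row_key: str) -> pd.DataFrame:
    """Row-normalized percent confusion matrix with correct/incorrect margins."""
    counts = pd.crosstab(block[row_key], block["decoded"])
    counts = counts.reindex(columns=list(EMOTIONS), fill_value=0)
    if row_key == "intended":
        counts = counts.reindex(
            index=[e for e in EMOTIONS if e in counts.index], fill_value=0
        )
    totals = counts.sum(axis=1)
    matrix = counts.div(totals, axis=0) * 100.0
    intended = block.groupby(row_key)["intended"].first() if row_key != "intended" else None
    correct = []
    for row in matrix.index:
        target = row if row_key == "intended" else intended.loc[row]
        correct.append(matrix.loc[row, target])
    matrix["correct"] = correct
    matrix["incorrect"] = 100.0 - matrix["correct"]
    matrix.index.name = row_key
    return matrix


def confusion_matrix(ratings: pd.DataFrame, group_by: str = "emotion"):
    """Observer judgments as row-normalized percentages.

    ``group_by="emotion"`` pools all responses into one matrix with one
    row per intended emotion.  ``"presentation"`` returns a dict of such
    matrices, one per visual presentation.  ``"stimulus"`` returns a
    single matrix with one row per stimulus id.  Responses are pooled
    before normalization; empty groups are omitted with a warning.
    Columns are the six decoded emotions plus correct/incorrect margins;
    the six emotion cells of each row sum to 100%.
    """
    validate_ratings(ratings)
    if group_by == "emotion":
        return _matrix(ratings, "intended")
    if group_by == "stimulus":
        return _matrix(ratings, "stimulus")
    if group_by == "presentation":
        matrices = {}
        for presentation in PRESENTATIONS:
            block = ratings[ratings["presentation"] == presentation]
            if block.empty:
                warnings.warn(f"no ratings for presentation {presentation!r}: row omitted")
                continue
            matrices[presentation] = _matrix(block, "intended")
        return matrices
    raise ValueError(f"unknown group_by {group_by!r}")


def chance_level(categories: int = 6) -> float:
    """Expected percent correct under uniform guessing: 100 / categories."""
    if categories < 2:
        raise ValueError(f"need at least 2 categories, got {categories}")
    return 100.0 / categories


@dataclass(frozen=True)
class ChanceTestResult:
    statistic: float
    p_value: float
    df: int
    expected_correct: float


def chance_test(correct_count: int, total: int, categories: int = 6) -> ChanceTestResult:
    """Chi-square goodness of fit of correct/incorrect counts vs chance.

    Tests the observed (correct, incorrect) split against the expected
    proportions (1/categories, 1 - 1/categories); df = 1.
    """
    if total <= 0:
        raise ValueError(f"total must be > 0, got {total}")
    if categories < 2:
        raise ValueError(f"need at least 2 categories, got {categories}")
    if not (0 <= correct_count <= total):
        raise ValueError(f"correct_count {correct_count} outside [0, {total}]")
    expected_correct = total / categories
    observed = np.array([correct_count, total - correct_count], dtype=float)
    expected = np.array([expected_correct, total - expected_correct])
    result = stats.chisquare(observed, f_exp=expected)
    return ChanceTestResult(
        statistic=float(result.statistic),
        p_value=float(result.pvalue),
        df=1,
        expected_correct=expected_correct,
    )


def recognition_summary(ratings: pd.DataFrame) -> pd.DataFrame:
    """Mean percent-correct (and SE) by presentation and by intended emotion.

    Percent correct is computed per participant within each group, then
    averaged; SE is the standard error of the participant means.
    """
    validate_ratings(ratings)
    df = ratings.copy()
    df["correct"] = (df["intended"] == df["decoded"]).astype(float) * 100.0
    rows = []
    for group_col in ("presentation", "intended"):
        per_participant = df.groupby([group_col, "participant"])["correct"].mean()
        for level, values in per_participant.groupby(level=0):
            v = values.to_numpy()
            se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
            rows.append(
                {
                    "grouping": "presentation" if group_col == "presentation" else "emotion",
                    "level": level,
                    "mean_percent_correct": float(v.mean()),
                    "se": se,
                    "n_participants": int(v.size),
                }
            )
    return pd.DataFrame(rows)
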