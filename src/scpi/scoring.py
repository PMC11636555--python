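"""Scoring of the six-item self-care questionnaire into the SCPI.

The questionnaire offers six non-exclusive checkbox options, three worded
positively (good self-care: 1a, 1b, 1c) and three negatively (self-care
needs enhancement: 2a, 2b, 2c).  Each option carries a fixed integer weight;
the Self-Care Preparedness Index (SCPI) is the sum of the weights of the
endorsed options, so under the default weights it ranges from -5 (all three
negative options endorsed, no positive ones) to +5 (the converse).  Fixed
cut-points classify the score into low / moderate / high preparedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_CODES",
    "ITEM_WORDING",
    "ITEM_POLARITY",
    "ScoringScheme",
    "LevelBounds",
    "LEVELS",
    "score_response",
    "classify_level",
    "attainable_scores",
    "score_cohort",
    "item_columns",
]

#: Canonical item order used everywhere (columns, matrices, profiles).
ITEM_CODES: tuple[str, ...] = ("1a", "1b", "1c", "2a", "2b", "2c")

ITEM_WORDING: dict[str, str] = {
    "1a": "I have enough knowledge about my diseases, treatment goals and treatment options.",
    "1b": "I want to treat myself.",
    "1c": "I monitor my health and follow my care plan.",
    "2a": "I need more information about my diseases and more support with self-care.",
    "2b": "I want to treat myself, but my inner resources are insufficient.",
    "2c": ("For the most part, my self-monitoring measurements do not meet the "
           "treatment goals and I do not know how to improve my self-care."),
}

#: 'positive' = describes good self-care, 'negative' = describes a deficit.
ITEM_POLARITY: dict[str, str] = {
    "1a": "positive", "1b": "positive", "1c": "positive",
    "2a": "negative", "2b": "negative", "2c": "negative",
}

LEVELS: tuple[str, str, str] = ("low", "moderate", "high")


def item_columns(prefix: str = "item_") -> list[str]:
    """Column names for the six items in canonical order."""
    return [prefix + code for code in ITEM_CODES]


@dataclass(frozen=True)
class ScoringScheme:
    """Integer weight per questionnaire option.

    The default weights give +2/+1/+2 points to the positive options and
    -1/-2/-2 to the negative ones, so the positive weights sum to +5 and the
    negative weights to -5.
    """

    points: Mapping[str, int] = field(
        default_factory=lambda: {"1a": 2, "1b": 1, "1c": 2, "2a": -1, "2b": -2, "2c": -2}
    )

    def __post_init__(self) -> None:
        keys = set(self.points)
        if keys != set(ITEM_CODES):
            raise ValueError(
                f"scoring scheme must define exactly the items {ITEM_CODES}, got {sorted(keys)}"
            )
        for code, pts in self.points.items():
            if int(pts) != pts:
                raise ValueError(f"non-integer points for item {code!r}: {pts!r}")
        object.__setattr__(self, "points", dict(self.points))

    @property
    def weights(self) -> np.ndarray:
        """Weights as an int array in canonical item order."""
        return np.array([self.points[c] for c in ITEM_CODES], dtype=int)

    def min_score(self) -> int:
        return sum(p for p in self.points.values() if p < 0)

    def max_score(self) -> int:
        return sum(p for p in self.points.values() if p > 0)


@dataclass(frozen=True)
class LevelBounds:
    """Closed-interval cut-points for the three preparedness levels.

    Defaults follow the index definition: low for scores up to 0, moderate
    for 1-3, high above that (4-5 under the default scheme).  The paperless
    way to read them: ``score <= low_max`` is low, ``score <= moderate_max``
    is moderate, anything higher is high.
    """

    low_max: int = 0
    moderate_max: int = 3

    def __post_init__(self) -> None:
        if self.moderate_max <= self.low_max:
            raise ValueError("moderate_max must exceed low_max")

    def validate_partition(self, scheme: ScoringScheme) -> None:
        """Check the three intervals cover the attainable range without gaps."""
        lo, hi = scheme.min_score(), scheme.max_score()
        if not (lo <= self.low_max < self.moderate_max < hi):
            raise ValueError(
                f"bounds ({self.low_max}, {self.moderate_max}] do not partition "
                f"the attainable range [{lo}, {hi}] into three non-empty levels"
            )


def _as_endorsed_set(pattern: Mapping[str, object] | Iterable[str]) -> frozenset[str]:
    if isinstance(pattern, Mapping):
        unknown = set(pattern) - set(ITEM_CODES)
        if unknown:
            raise KeyError(f"unknown item key(s) in response pattern: {sorted(unknown)}")
        missing = set(ITEM_CODES) - set(pattern)
        if missing:
            raise KeyError(f"response pattern missing item(s): {sorted(missing)}")
        return frozenset(k for k, v in pattern.items() if bool(v))
    endorsed = frozenset(pattern)
    unknown = endorsed - set(ITEM_CODES)
    if unknown:
        raise KeyError(f"unknown item key(s) in response pattern: {sorted(unknown)}")
    return endorsed


def score_response(
    pattern: Mapping[str, object] | Iterable[str],
    scheme: ScoringScheme | None = None,
) -> int:
    """Sum the weights of the endorsed options.

    ``pattern`` is either a mapping {item code -> bool} defined on all six
    items, or an iterable of the endorsed item codes (any subset, including
    the empty one).
    """
    scheme = scheme or ScoringScheme()
    endorsed = _as_endorsed_set(pattern)
    return int(sum(scheme.points[k] for k in endorsed))


def classify_level(
    score: int,
    bounds: LevelBounds | None = None,
    scheme: ScoringScheme | None = None,
) -> str:
    """Map an SCPI score to 'low' / 'moderate' / 'high'."""
    bounds = bounds or LevelBounds()
    scheme = scheme or ScoringScheme()
    if not scheme.min_score() <= score <= scheme.max_score():
        raise ValueError(
            f"score {score} outside attainable range "
            f"[{scheme.min_score()}, {scheme.max_score()}]"
        )
    if score <= bounds.low_max:
        return "low"
    if score <= bounds.moderate_max:
        return "moderate"
    return "high"


def attainable_scores(scheme: ScoringScheme | None = None) -> frozenset[int]:
    """Exact set of sums over all 2^6 endorsement patterns."""
    scheme = scheme or ScoringScheme()
    pts = [scheme.points[c] for c in ITEM_CODES]
    out: set[int] = set()
    for r in range(len(pts) + 1):
        for combo in combinations(pts, r):
            out.add(sum(combo))
    return frozenset(out)


def score_cohort(
    table: pd.DataFrame,
    scheme: ScoringScheme | None = None,
    bounds: LevelBounds | None = None,
    item_prefix: str = "item_",
) -> pd.DataFrame:
    """Append ``scpi``, ``scpi_level`` and flag columns to a cohort table.

    Items must be coded 0/1; NaN marks a missing answer.  Rows with any
    missing item keep their place but get a null score and level and are
    flagged ``scpi_complete = False`` so downstream statistics can exclude
    them.  Rows endorsing no option at all are valid (score 0, level low)
    but flagged ``scpi_none_endorsed`` for transparency.
    """
    scheme = scheme or ScoringScheme()
    bounds = bounds or LevelBounds()
    bounds.validate_partition(scheme)

    cols = item_columns(item_prefix)
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing item column(s): {missing_cols}")

    items = table[cols].to_numpy(dtype=float, copy=True)
    complete = ~np.isnan(items).any(axis=1)
    observed = items[~np.isnan(items)]
    bad = ~np.isin(observed, (0.0, 1.0))
    if bad.any():
        rows = np.unique(np.where(~np.isin(np.nan_to_num(items, nan=0.0), (0.0, 1.0)))[0])
        raise ValueError(f"non-binary item value(s) at row index(es) {rows.tolist()[:10]}")

    out = table.copy()
    raw = np.nan_to_num(items, nan=0.0) @ scheme.weights
    scores = pd.array(np.round(raw).astype(int), dtype="Int64")
    scores[~complete] = pd.NA
    out["scpi"] = scores
    out["scpi_level"] = [
        classify_level(int(s), bounds, scheme) if ok else pd.NA
        for s, ok in zip(np.nan_to_num(raw).astype(int), complete)
    ]
    out["scpi_complete"] = complete
    out["scpi_none_endorsed"] = complete & (np.nan_to_num(items, nan=1.0).sum(axis=1) == 0)
    return out
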