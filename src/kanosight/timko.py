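"""Better/Worse satisfaction indices and importance weighting.

From an attribute's category counts, the satisfaction index ("Better") and
dissatisfaction index ("Worse") are

    Better =  (A + P) / (A + P + M + I)        0 <= Better <= 1
    Worse  = -(P + M) / (A + P + M + I)       -1 <= Worse  <= 0

Reverse (R) and questionable (Q) answers are excluded.  Better measures the
relative gain in satisfaction from meeting a requirement; Worse the relative
cost of not meeting it.  Both may additionally be scaled by the attribute's
mean self-stated importance to spread out attributes that sit close together
in the Better-Worse plane.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, replace
from typing import NamedTuple

from .exceptions import KanosightError, UndefinedIndexError
from .kano import CategoryCounts, _as_counts
from .levels import RELEVANCE_LEVELS

#: Default relevance-level -> importance weight mapping: a uniform linear
#: grid on [0, 1].  The mapping is configurable; this default reproduces the
#: 0.68-0.94 importance magnitudes seen in physician panels.
DEFAULT_RELEVANCE_WEIGHTS: dict[str, float] = {
    "very_important": 1.0,
    "important": 0.75,
    "neutral": 0.5,
    "less_important": 0.25,
    "unimportant": 0.0,
}


class Coordinate(NamedTuple):
    """A point in the (signed) Worse-Better plane.

    ``worse`` lies in [-1, 0] and ``better`` in [0, 1].  Plots conventionally
    show |Worse| on the x-axis; the sign flip is purely presentational.
    """

    worse: float
    better: float


@dataclass(frozen=True)
class TimkoIndices:
    """Satisfaction/dissatisfaction indices for one attribute."""

    attribute_id: str
    better: float
    worse: float
    importance: float | None = None
    better_weighted: float | None = None
    worse_weighted: float | None = None

    @property
    def coordinate(self) -> Coordinate:
        return Coordinate(self.worse, self.better)

    @property
    def weighted_coordinate(self) -> Coordinate:
        if self.worse_weighted is None or self.better_weighted is None:
            raise KanosightError(f"{self.attribute_id}: indices are not weighted")
        return Coordinate(self.worse_weighted, self.better_weighted)


def _denominator(counts: CategoryCounts | Mapping[str, int]) -> tuple[dict[str, int], int]:
    c = _as_counts(counts)
    denom = c["A"] + c["P"] + c["M"] + c["I"]
    if denom == 0:
        raise UndefinedIndexError(
            "Better/Worse undefined: no A, P, M or I answers (only R/Q or empty)"
        )
    return c, denom


def better_index(counts: CategoryCounts | Mapping[str, int]) -> float:
    """(A+P)/(A+P+M+I); R and Q are ignored."""
    c, denom = _denominator(counts)
    return (c["A"] + c["P"]) / denom


def worse_index(counts: CategoryCounts | Mapping[str, int]) -> float:
    """-(P+M)/(A+P+M+I); R and Q are ignored."""
    c, denom = _denominator(counts)
    return -(c["P"] + c["M"]) / denom


def importance_score(data, attribute: str,
                     weights: Mapping[str, float] | None = None) -> float:
    """Mean stated importance of an attribute, on [0, 1].

    Averages the respondents' relevance answers under ``weights`` (default
    :data:`DEFAULT_RELEVANCE_WEIGHTS`); absent answers are excluded.
    """
    weights = dict(weights or DEFAULT_RELEVANCE_WEIGHTS)
    unknown = set(weights) - set(RELEVANCE_LEVELS)
    if unknown:
        raise KanosightError(f"weights for unknown relevance levels: {sorted(unknown)}")
    answers = [a for a in data.for_attribute(attribute)["relevance"] if a is not None]
    if not answers:
        raise KanosightError(f"attribute {attribute!r} has no relevance answers")
    return sum(weights[a] for a in answers) / len(answers)


def weight_by_importance(indices: TimkoIndices, importance: float) -> TimkoIndices:
    """Scale Better and Worse by a scalar importance in [0, 1]."""
    if not 0 <= importance <= 1:
        raise KanosightError(f"importance must be in [0, 1], got {importance}")
    return replace(
        indices,
        importance=importance,
        better_weighted=indices.better * importance,
        worse_weighted=indices.worse * importance,
    )


def indices_from_counts(counts: CategoryCounts | Mapping[str, int],
                        importance: float | None = None,
                        attribute_id: str | None = None) -> TimkoIndices:
    """Build (optionally importance-weighted) indices from category counts."""
    if attribute_id is None:
        attribute_id = counts.attribute_id if isinstance(counts, CategoryCounts) else ""
    out = TimkoIndices(attribute_id, better_index(counts), worse_index(counts))
    if importance is not None:
        out = weight_by_importance(out, importance)
    return out


def compute_indices(data, attribute: str,
                    weights: Mapping[str, float] | None = None) -> TimkoIndices:
    """Full per-attribute index computation from raw survey data."""
    from .kano import tabulate

    counts = tabulate(data, attribute)
    return indices_from_counts(counts, importance_score(data, attribute, weights))
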