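"""Per-pair Kano categorization and the classical category-assignment rules.

Each functional/dysfunctional answer pair maps to one of six Kano categories:

* ``A`` — attractive: presence delights, absence is not penalized
* ``P`` — one-dimensional / performance (alias ``O``): satisfaction tracks
  fulfillment in both directions
* ``M`` — must-be: taken for granted; absence causes strong dissatisfaction
* ``I`` — indifferent: affects neither satisfaction nor dissatisfaction
* ``R`` — reverse: presence dissatisfies
* ``Q`` — questionable: contradictory answer pair

An attribute's category is then assigned from the tally of its pairs, either
by the plain mode rule or by the if-then rule, which first decides whether
the "functional" side (P+A+M) or the "non-functional" side (I+R+Q) dominates
and takes the argmax within the winning side.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

from .exceptions import KanosightError
from .levels import DYSFUNCTIONAL_LEVELS, FUNCTIONAL_LEVELS

CATEGORIES: tuple[str, ...] = ("M", "P", "A", "I", "R", "Q")

#: Argmax tie precedence used by both assignment rules: essentials first.
DEFAULT_PRECEDENCE: tuple[str, ...] = ("M", "P", "A", "I", "R", "Q")

# Categorization grid: rows are functional answers, columns dysfunctional,
# both ordered delighted, expected, neutral, tolerated, dislike.
_GRID = (
    ("Q", "A", "A", "A", "P"),
    ("R", "Q", "I", "I", "M"),
    ("R", "I", "I", "I", "M"),
    ("R", "I", "I", "Q", "M"),
    ("R", "R", "R", "R", "Q"),
)

CATEGORY_MATRIX: dict[tuple[str, str], str] = {
    (f, d): _GRID[i][j]
    for i, f in enumerate(FUNCTIONAL_LEVELS)
    for j, d in enumerate(DYSFUNCTIONAL_LEVELS)
}


def _normalize_category(category: str) -> str:
    cat = category.upper()
    if cat == "O":  # "one-dimensional" alias for performance
        cat = "P"
    if cat not in CATEGORIES:
        raise ValueError(f"unknown Kano category {category!r}")
    return cat


def categorize_pair(functional: str | None, dysfunctional: str | None) -> str | None:
    """Categorize one answer pair; ``None`` if either answer is absent.

    Total over the 5x5 grid plus absent states; raises only on tokens that
    are not valid answer levels.
    """
    if functional is None or dysfunctional is None:
        return None
    try:
        return CATEGORY_MATRIX[(functional, dysfunctional)]
    except KeyError:
        raise ValueError(
            f"invalid answer pair ({functional!r}, {dysfunctional!r})"
        ) from None


@dataclass
class CategoryCounts:
    """Per-attribute tally over the six Kano categories.

    ``n_complete`` counts answer pairs with both halves present (equals the
    sum of the six category counts); ``n_missing`` counts pairs with at least
    one absent half.
    """

    attribute_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_missing: int = 0

    def __post_init__(self) -> None:
        normalized = {c: 0 for c in CATEGORIES}
        for cat, n in self.counts.items():
            cat = _normalize_category(cat)
            if n < 0:
                raise ValueError(f"negative count for category {cat}")
            normalized[cat] += int(n)
        self.counts = normalized
        if self.n_missing < 0:
            raise ValueError("n_missing must be non-negative")

    @classmethod
    def from_values(cls, attribute_id: str, *, M: int = 0, P: int = 0, A: int = 0,
                    I: int = 0, R: int = 0, Q: int = 0,  # noqa: E741 - Kano letters
                    n_missing: int = 0) -> "CategoryCounts":
        return cls(attribute_id, {"M": M, "P": P, "A": A, "I": I, "R": R, "Q": Q},
                   n_missing=n_missing)

    @property
    def n_complete(self) -> int:
        return sum(self.counts.values())

    @property
    def n_records(self) -> int:
        return self.n_complete + self.n_missing

    def __getitem__(self, category: str) -> int:
        return self.counts[_normalize_category(category)]


def _as_counts(counts: CategoryCounts | Mapping[str, int]) -> dict[str, int]:
    if isinstance(counts, CategoryCounts):
        return counts.counts
    out = {c: 0 for c in CATEGORIES}
    for cat, n in counts.items():
        out[_normalize_category(cat)] += int(n)
    return out


def _argmax(counts: Mapping[str, int], candidates: tuple[str, ...],
            precedence: tuple[str, ...]) -> str:
    best = max(counts[c] for c in candidates)
    for cat in precedence:
        if cat in candidates and counts[cat] == best:
            return cat
    raise AssertionError("unreachable")  # pragma: no cover


def tabulate(data, attribute: str) -> CategoryCounts:
    """Tally Kano categories for one attribute of a survey dataset.

    ``data`` is a :class:`~kanosight.survey.SurveyDataset` (or anything with
    its ``for_attribute`` method returning a frame with ``functional`` and
    ``dysfunctional`` columns).  Pairs with either half absent are counted in
    ``n_missing`` and excluded from the category tally.
    """
    frame = data.for_attribute(attribute)
    if len(frame) == 0:
        raise KanosightError(f"attribute {attribute!r} has no records")
    counts = {c: 0 for c in CATEGORIES}
    n_missing = 0
    for functional, dysfunctional in zip(frame["functional"], frame["dysfunctional"]):
        cat = categorize_pair(functional, dysfunctional)
        if cat is None:
            n_missing += 1
        else:
            counts[cat] += 1
    return CategoryCounts(attribute, counts, n_missing=n_missing)


def assign_mode(counts: CategoryCounts | Mapping[str, int],
                precedence: tuple[str, ...] = DEFAULT_PRECEDENCE) -> str:
    """Assign the category with the greatest frequency.

    Ties are broken by ``precedence`` (default M > P > A > I > R > Q, an
    essentials-first ordering; the choice is a documented convention — the
    aggregation rule itself says nothing about ties).
    """
    c = _as_counts(counts)
    if sum(c.values()) == 0:
        raise KanosightError("cannot assign a category from zero complete pairs")
    return _argmax(c, CATEGORIES, precedence)


def assign_ifthen(counts: CategoryCounts | Mapping[str, int],
                  precedence: tuple[str, ...] = DEFAULT_PRECEDENCE) -> str:
    """Assign a category with the if-then rule.

    If P+A+M > I+R+Q the argmax over {P, A, M} is used; if P+A+M < I+R+Q the
    argmax over {I, R, Q}.  The rule is stated only for strict inequalities;
    on equality this implementation falls back to the global argmax with the
    same tie precedence.
    """
    c = _as_counts(counts)
    if sum(c.values()) == 0:
        raise KanosightError("cannot assign a category from zero complete pairs")
    functional = c["P"] + c["A"] + c["M"]
    nonfunctional = c["I"] + c["R"] + c["Q"]
    if functional > nonfunctional:
        return _argmax(c, ("P", "A", "M"), precedence)
    if functional < nonfunctional:
        return _argmax(c, ("I", "R", "Q"), precedence)
    return _argmax(c, CATEGORIES, precedence)
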