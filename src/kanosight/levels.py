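"""Canonical answer levels for Kano-style surveys.

A Kano item asks the same question twice — positively worded (functional:
"what if the feature is present?") and negatively worded (dysfunctional:
"what if it is absent?") — on a 5-level scale, plus a separate 5-level
self-stated relevance question.  Survey wording is locale-dependent, so the
package stores answers as short stable tokens and maps raw export strings to
them at the reading boundary.

Functional/dysfunctional tokens (ordered from enthusiasm to rejection):

==========  =============================
token       typical survey wording
==========  =============================
delighted   "I would be very pleased"
expected    "I'd expect this"
neutral     "I don't care"
tolerated   "I could accept that"
dislike     "That would really bother me"
==========  =============================

Relevance tokens: ``very_important``, ``important``, ``neutral``,
``less_important``, ``unimportant``.

A missing answer is represented as ``None`` ("absent"); empty cells and the
usual NA sentinels map to it.  No imputation is ever performed — an answer
pair with a missing half is simply not categorizable.
"""

from __future__ import annotations

from .exceptions import ParseError

FUNCTIONAL_LEVELS: tuple[str, ...] = (
    "delighted",
    "expected",
    "neutral",
    "tolerated",
    "dislike",
)
# The dysfunctional question uses the same answer scale.
DYSFUNCTIONAL_LEVELS: tuple[str, ...] = FUNCTIONAL_LEVELS

RELEVANCE_LEVELS: tuple[str, ...] = (
    "very_important",
    "important",
    "neutral",
    "less_important",
    "unimportant",
)

#: Raw survey wordings accepted in addition to the canonical tokens.
FUNCTIONAL_LABELS: dict[str, str] = {
    "i would be very pleased": "delighted",
    "i'd expect this": "expected",
    "i would expect this": "expected",
    "i don't care": "neutral",
    "i could accept that": "tolerated",
    "that would really bother me": "dislike",
}

RELEVANCE_LABELS: dict[str, str] = {
    "very important": "very_important",
    "important": "important",
    "neutral": "neutral",
    "less important": "less_important",
    "unimportant": "unimportant",
}

#: Cell contents treated as "no answer given" (case-insensitive).
NA_SENTINELS: frozenset[str] = frozenset({"", "na", "n/a", "none", "-", "--"})


def _canonicalize(
    value: object,
    levels: tuple[str, ...],
    labels: dict[str, str],
    extra_labels: dict[str, str] | None = None,
    row: int | None = None,
) -> str | None:
    if value is None:
        return None
    if not isinstance(value, str):
        # pandas represents empty CSV cells as float NaN
        if value != value:  # NaN check without importing numpy
            return None
        value = str(value)
    raw = value.strip()
    if raw.lower() in NA_SENTINELS:
        return None
    if raw in levels:
        return raw
    key = raw.lower()
    if extra_labels:
        lowered = {k.strip().lower(): v for k, v in extra_labels.items()}
        if key in lowered:
            return lowered[key]
    if key in labels:
        return labels[key]
    raise ParseError(f"unrecognized answer value {raw!r}", row=row)


def canonical_functional(value: object, extra_labels: dict[str, str] | None = None,
                         row: int | None = None) -> str | None:
    """Map a raw functional/dysfunctional answer to its token (None if absent)."""
    return _canonicalize(value, FUNCTIONAL_LEVELS, FUNCTIONAL_LABELS, extra_labels, row)


def canonical_relevance(value: object, extra_labels: dict[str, str] | None = None,
                        row: int | None = None) -> str | None:
    """Map a raw relevance answer to its token (None if absent)."""
    return _canonicalize(value, RELEVANCE_LEVELS, RELEVANCE_LABELS, extra_labels, row)
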