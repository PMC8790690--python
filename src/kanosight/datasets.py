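"""Bundled reference tables from a published physician Kano survey.

The reference study surveyed members of two German orthopedic professional
societies (382 complete responses out of 9503 invited) on nine health-app
quality principles, randomly split the panel into a test group (A, n=191)
and a validation group (B, n=191), and published the aggregated Kano
category counts, mean importance values, demographic contingency tables and
the in-line-of-sight ranking tables.  Those aggregates are reproduced here
as machine-readable inputs for worked examples, calibration of synthetic
panels, and regression checks.  No respondent-level data were published;
only these aggregates ship with the package.
"""

from __future__ import annotations

import pandas as pd

from .kano import CategoryCounts

#: The nine health-app quality principles, in published table order.
QUALITY_PRINCIPLES: tuple[str, ...] = (
    "practicality",
    "risk_adequacy",
    "ethical_soundness",
    "legal_conformity",
    "content_validity",
    "technical_adequacy",
    "usability",
    "resource_efficiency",
    "transparency",
)

#: Group sizes of the reference study's test/validation split.
GROUP_SIZE = 191
N_RESPONDENTS = 382

# Kano category counts per principle, order (M, P, A, I, R, Q).
_COUNTS = {
    "A": {
        "practicality":        (127, 42, 10, 7, 2, 3),
        "risk_adequacy":       (127, 48, 2, 9, 1, 4),
        "ethical_soundness":   (120, 40, 8, 19, 1, 3),
        "legal_conformity":    (148, 27, 2, 13, 0, 1),
        "content_validity":    (139, 42, 1, 7, 0, 2),
        "technical_adequacy":  (83, 68, 20, 18, 2, 0),
        "usability":           (103, 49, 20, 17, 0, 2),
        "resource_efficiency": (63, 40, 45, 40, 1, 2),
        "transparency":        (103, 43, 18, 23, 3, 1),
    },
    "B": {
        "practicality":        (122, 48, 4, 12, 2, 3),
        "risk_adequacy":       (127, 46, 0, 7, 3, 8),
        "ethical_soundness":   (123, 33, 7, 23, 0, 5),
        "legal_conformity":    (146, 20, 5, 15, 1, 4),
        "content_validity":    (140, 38, 5, 6, 0, 2),
        "technical_adequacy":  (89, 59, 24, 16, 1, 2),
        "usability":           (105, 50, 16, 15, 0, 5),
        "resource_efficiency": (69, 37, 34, 40, 6, 5),
        "transparency":        (89, 45, 22, 27, 1, 7),
    },
}

# Published mean importance (relevance-weighted) per principle.
_IMPORTANCE = {
    "A": {
        "practicality": 0.88, "risk_adequacy": 0.87, "ethical_soundness": 0.85,
        "legal_conformity": 0.89, "content_validity": 0.91,
        "technical_adequacy": 0.82, "usability": 0.84,
        "resource_efficiency": 0.68, "transparency": 0.79,
    },
    "B": {
        "practicality": 0.88, "risk_adequacy": 0.88, "ethical_soundness": 0.83,
        "legal_conformity": 0.86, "content_validity": 0.94,
        "technical_adequacy": 0.83, "usability": 0.84,
        "resource_efficiency": 0.71, "transparency": 0.79,
    },
}


def _check_group(group: str) -> str:
    group = group.upper()
    if group not in ("A", "B"):
        raise ValueError("group must be 'A' (test) or 'B' (validation)")
    return group


def reference_counts(group: str = "A") -> dict[str, CategoryCounts]:
    """Published Kano category counts per principle for one group.

    Pairs with a missing half are not part of the published tally; each
    group's complete pairs per principle sum to at most the group size.
    """
    group = _check_group(group)
    out = {}
    for attr, (m, p, a, i, r, q) in _COUNTS[group].items():
        n_complete = m + p + a + i + r + q
        out[attr] = CategoryCounts.from_values(
            attr, M=m, P=p, A=a, I=i, R=r, Q=q,
            n_missing=GROUP_SIZE - n_complete,
        )
    return out


def reference_importance(group: str = "A") -> dict[str, float]:
    """Published mean importance per principle for one group."""
    return dict(_IMPORTANCE[_check_group(group)])


#: Published in-line-of-sight inputs/outputs for the gender and interest
#: stratifications of the full panel (strata sizes: female 54 / male 328;
#: interested 360 / uninterested 22).  Columns: printed distance d, angle
#: alpha (degrees), ranking coefficient f and rank from the must-be POV.
STRATUM_RANKINGS: dict[str, pd.DataFrame] = {
    name: pd.DataFrame(rows, columns=["d", "alpha", "f", "rank"],
                       index=list(QUALITY_PRINCIPLES))
    for name, rows in {
        "female": [
            (0.37, 60, 0.41, 5), (0.28, 69, 0.34, 3), (0.31, 52, 0.35, 4),
            (0.23, 56, 0.28, 2), (0.19, 70, 0.24, 1), (0.57, 48, 0.61, 8),
            (0.48, 47, 0.52, 6), (0.68, 38, 0.71, 9), (0.53, 42, 0.57, 7),
        ],
        "male": [
            (0.31, 50, 0.35, 4), (0.29, 52, 0.33, 3), (0.36, 32, 0.39, 5),
            (0.25, 28, 0.27, 1), (0.25, 59, 0.30, 2), (0.50, 47, 0.54, 8),
            (0.43, 43, 0.46, 6), (0.67, 24, 0.69, 9), (0.48, 33, 0.51, 7),
        ],
        "interested": [
            (0.31, 57, 0.36, 4), (0.28, 60, 0.33, 3), (0.34, 38, 0.37, 5),
            (0.23, 36, 0.26, 1), (0.24, 67, 0.30, 2), (0.51, 50, 0.55, 8),
            (0.42, 48, 0.46, 6), (0.66, 27, 0.68, 9), (0.48, 37, 0.51, 7),
        ],
        "uninterested": [
            (0.57, 5.9, 0.57, 4), (0.52, 6.6, 0.53, 3), (0.61, 7.8, 0.62, 5),
            (0.52, 0.0, 0.52, 2), (0.49, 3.8, 0.49, 1), (0.62, 16.3, 0.63, 6),
            (0.76, 9.6, 0.77, 8), (0.81, 19.4, 0.82, 9), (0.64, 5.4, 0.65, 7),
        ],
    }.items()
}

#: Published demographic contingency tables (rows: categories, columns:
#: group A then group B counts), used to verify that the random split left
#: no significant demographic imbalance.
DEMOGRAPHICS: dict[str, pd.DataFrame] = {
    name: pd.DataFrame(rows, index=["A", "B"]).T
    for name, rows in {
        "age_group": {"21-30": (9, 7), "31-40": (34, 42), "41-50": (46, 44),
                      "51-60": (62, 59), ">60": (40, 39)},
        "gender": {"female": (24, 30), "male": (167, 161)},
        "interest": {"highly_interested": (76, 81), "interested": (84, 75),
                     "neutral": (19, 25), "less_interested": (8, 8),
                     "not_interested": (4, 2)},
        "uses_apps_private": {"yes": (69, 70), "no": (122, 121)},
        "uses_apps_work": {"yes": (63, 73), "no": (128, 118)},
        "asked_about_apps": {"yes": (43, 43), "no": (148, 148)},
    }.items()
}
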