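"""Group and stratum comparison utilities.

Test/validation splits are sanity-checked with Pearson chi-square tests on
demographic and answer contingency tables (no continuity correction, no
multiple-testing adjustment — raw p-values only), and the stability of the
prioritization is quantified by the Euclidean distance between the two
groups' weighted Better-Worse coordinates per attribute.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateTableError
from .line_of_sight import _check_bounds
from .timko import Coordinate


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-square test result for one observed-counts table."""

    statistic: float
    dof: int
    p_value: float
    table: np.ndarray
    expected: np.ndarray


def compare_counts(table) -> ContingencyResult:
    """Pearson chi-square test of homogeneity on an observed-counts matrix.

    No continuity correction is applied (the classical Pearson statistic).
    A warning is emitted when any expected cell count falls below 5, but the
    statistic is reported unchanged.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError(f"need at least a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise DegenerateTableError("observed counts must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    statistic, p_value, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell count(s) below 5; "
            "the chi-square approximation may be poor",
            stacklevel=2,
        )
    return ContingencyResult(float(statistic), int(dof), float(p_value), obs, expected)


def between_group_distance(a: Coordinate | tuple[float, float],
                           b: Coordinate | tuple[float, float]) -> float:
    """Euclidean distance between two Better-Worse coordinates.

    Used per attribute to compare a test group against a validation group; a
    replicated design should keep all such distances below 5% of the maximal
    in-square distance (0.05 * sqrt(2) ~ 0.0707).
    """
    pa, pb = _check_bounds(a), _check_bounds(b)
    return math.hypot(pa.worse - pb.worse, pa.better - pb.better)


def comparison_report(tables: Mapping[str, object]) -> pd.DataFrame:
    """Run :func:`compare_counts` over named tables; one row per comparison."""
    rows = []
    for name, table in tables.items():
        res = compare_counts(table)
        rows.append({"characteristic": name, "statistic": res.statistic,
                     "dof": res.dof, "p_value": res.p_value})
    return pd.DataFrame(rows).set_index("characteristic")


def strata_table(datasets: Mapping[str, object], label: str) -> pd.DataFrame:
    """Cross-tabulate a strata column across named survey datasets.

    Rows are the strata-column values, columns the dataset names; suitable
    input for :func:`compare_counts` after dropping empty rows.
    """
    cols = {}
    for name, data in datasets.items():
        per_resp = data.records.drop_duplicates("respondent_id")
        cols[name] = per_resp[label].value_counts()
    return pd.DataFrame(cols).fillna(0).astype(int)
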