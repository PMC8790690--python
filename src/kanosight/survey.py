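"""Survey response containers, ingestion, splitting and stratification.

The canonical in-memory and on-disk representation is *long* format: one row
per respondent x attribute with columns ``respondent_id``, ``attribute_id``,
``functional``, ``dysfunctional``, ``relevance`` plus any number of strata
columns (gender, stated interest, ...).  Real survey exports are usually
*wide* (one row per respondent, three columns per attribute); a converter is
provided.

Answers are stored as canonical tokens (see :mod:`kanosight.levels`); a
missing answer is ``None``.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from . import levels
from .exceptions import KanosightError, ParseError, SchemaError

CORE_COLUMNS = ("respondent_id", "attribute_id", "functional", "dysfunctional", "relevance")
ANSWER_COLUMNS = ("functional", "dysfunctional", "relevance")

#: Default column-name mapping for long-format files (identity).
DEFAULT_SCHEMA: dict[str, str] = {c: c for c in CORE_COLUMNS}


class SurveyDataset:
    """A validated panel of Kano survey responses.

    Parameters
    ----------
    records
        Long-format frame with the canonical columns; answer cells must hold
        canonical tokens or ``None``.  Extra columns are kept as strata.
    attributes
        Optional explicit attribute ordering.  Defaults to order of first
        appearance.  Every record's ``attribute_id`` must be listed.
    """

    def __init__(self, records: pd.DataFrame, attributes: Iterable[str] | None = None):
        missing = [c for c in CORE_COLUMNS if c not in records.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records = records.copy()
        for col in ANSWER_COLUMNS:
            records[col] = (
                records[col].astype(object).where(records[col].notna(), None)
            )
        records["respondent_id"] = records["respondent_id"].astype(str)
        records["attribute_id"] = records["attribute_id"].astype(str)
        dup = records.duplicated(subset=["respondent_id", "attribute_id"])
        if dup.any():
            pair = records.loc[dup.idxmax(), ["respondent_id", "attribute_id"]]
            raise KanosightError(
                "duplicate (respondent_id, attribute_id): "
                f"({pair['respondent_id']}, {pair['attribute_id']})"
            )
        seen = list(dict.fromkeys(records["attribute_id"]))
        if attributes is None:
            attributes = seen
        else:
            attributes = [str(a) for a in attributes]
            unknown = set(seen) - set(attributes)
            if unknown:
                raise KanosightError(
                    f"records reference attributes not in the attribute list: {sorted(unknown)}"
                )
        self.records = records.reset_index(drop=True)
        self.attributes: list[str] = list(attributes)

    # -- basic introspection -------------------------------------------------

    @property
    def respondents(self) -> list[str]:
        """Distinct respondent ids in order of first appearance."""
        return list(dict.fromkeys(self.records["respondent_id"]))

    @property
    def n_respondents(self) -> int:
        return self.records["respondent_id"].nunique()

    @property
    def strata_labels(self) -> list[str]:
        return [c for c in self.records.columns if c not in CORE_COLUMNS]

    def __len__(self) -> int:
        return len(self.records)

    def for_attribute(self, attribute: str) -> pd.DataFrame:
        if attribute not in self.attributes:
            raise KanosightError(f"unknown attribute {attribute!r}")
        return self.records[self.records["attribute_id"] == attribute]

    def subset_respondents(self, respondent_ids: Iterable[str]) -> "SurveyDataset":
        ids = set(map(str, respondent_ids))
        mask = self.records["respondent_id"].isin(ids)
        return SurveyDataset(self.records[mask], attributes=self.attributes)

    # -- IO -------------------------------------------------------------------

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        """Write the canonical long-format CSV (absent answers as empty cells)."""
        out = self.records.copy()
        for col in ANSWER_COLUMNS:
            out[col] = out[col].where(out[col].notna(), "")
        out.to_csv(path, index=False, sep=delimiter)


def _apply_schema(frame: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    mapping = dict(DEFAULT_SCHEMA)
    strata_map: dict[str, str] = {}
    if schema:
        for key, col in schema.items():
            if key == "strata":
                strata_map = dict(col)  # type: ignore[arg-type]
            elif key in CORE_COLUMNS:
                mapping[key] = col
            elif key == "levels":
                continue
            else:
                raise SchemaError(f"unknown schema key {key!r}")
    for canonical, col in {**mapping, **strata_map}.items():
        if col not in frame.columns:
            raise SchemaError(f"column {col!r} (for {canonical!r}) not found in file")
    renames = {col: canonical for canonical, col in mapping.items()}
    renames.update({col: label for label, col in strata_map.items()})
    keep = list(renames)
    return frame[keep].rename(columns=renames)


def read_survey(path: str | Path, schema: Mapping[str, str] | None = None,
                delimiter: str = ",") -> SurveyDataset:
    """Read a long-format survey CSV into a validated :class:`SurveyDataset`.

    ``schema`` maps canonical field names to file column names and may carry
    two nested mappings: ``"strata"`` (stratum label -> column) and
    ``"levels"`` (extra raw answer string -> canonical token).  Empty cells
    and NA sentinels become absent answers; any other unrecognized answer
    string raises :class:`~kanosight.exceptions.ParseError` with its row
    number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey file not found: {path}")
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    frame = _apply_schema(raw, schema)
    extra = dict(schema.get("levels", {})) if schema else None
    for col, canon in (("functional", levels.canonical_functional),
                       ("dysfunctional", levels.canonical_functional),
                       ("relevance", levels.canonical_relevance)):
        frame[col] = [
            canon(value, extra, row=i + 2)  # header is line 1
            for i, value in enumerate(frame[col])
        ]
    return SurveyDataset(frame)


def wide_to_long(frame: pd.DataFrame, attributes: Iterable[str],
                 respondent_column: str = "respondent_id",
                 pattern: str = "{attribute}_{field}",
                 strata: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Convert a wide survey export (one row per respondent) to long format.

    Each attribute contributes three columns named by ``pattern`` with
    ``field`` in ``functional``/``dysfunctional``/``relevance``.  A column
    missing entirely yields absent answers for that field.
    """
    if respondent_column not in frame.columns:
        raise SchemaError(f"column {respondent_column!r} not found")
    rows = []
    strata = dict(strata or {})
    for label, col in strata.items():
        if col not in frame.columns:
            raise SchemaError(f"column {col!r} (for stratum {label!r}) not found")
    for _, rec in frame.iterrows():
        for attr in attributes:
            row = {"respondent_id": rec[respondent_column], "attribute_id": attr}
            for f in ANSWER_COLUMNS:
                col = pattern.format(attribute=attr, field=f)
                row[f] = rec[col] if col in frame.columns else None
            for label, col in strata.items():
                row[label] = rec[col]
            rows.append(row)
    return pd.DataFrame(rows)


def read_survey_wide(path: str | Path, attributes: Iterable[str],
                     respondent_column: str = "respondent_id",
                     pattern: str = "{attribute}_{field}",
                     strata: Mapping[str, str] | None = None,
                     levels_map: Mapping[str, str] | None = None,
                     delimiter: str = ",") -> SurveyDataset:
    """Read a wide-format survey CSV (convenience over :func:`wide_to_long`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey file not found: {path}")
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    long = wide_to_long(raw, list(attributes), respondent_column, pattern, strata)
    extra = dict(levels_map) if levels_map else None
    for col, canon in (("functional", levels.canonical_functional),
                       ("dysfunctional", levels.canonical_functional),
                       ("relevance", levels.canonical_relevance)):
        long[col] = [canon(v, extra) for v in long[col]]
    return SurveyDataset(long, attributes=list(attributes))


def split_groups(data: SurveyDataset, fraction: float = 0.5,
                 seed: int | None = None) -> tuple[SurveyDataset, SurveyDataset]:
    """Randomly partition respondents into two groups (test/validation).

    Group A receives ``ceil(fraction * n)`` respondents and group B the rest;
    the same seed always yields the same partition.  With n=382 and
    fraction=0.5 this gives the 191/191 test/validation design.
    """
    if not 0 < fraction < 1:
        raise KanosightError(f"fraction must be in (0, 1), got {fraction}")
    respondents = sorted(set(data.records["respondent_id"]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(respondents))
    n_a = math.ceil(fraction * len(respondents))
    ids_a = {respondents[i] for i in order[:n_a]}
    ids_b = set(respondents) - ids_a
    return data.subset_respondents(ids_a), data.subset_respondents(ids_b)


def stratify(data: SurveyDataset, label: str,
             aggregation: Mapping[str, str] | None = None) -> dict[str, SurveyDataset]:
    """Partition respondents into strata by one strata column.

    ``aggregation`` maps raw column values to stratum names (e.g. collapsing
    a 5-level interest scale to interested/uninterested); values without a
    mapping fall into an explicit ``"unmapped"`` stratum.  Without an
    aggregation, each distinct raw value is its own stratum.
    """
    if label not in data.strata_labels:
        raise KeyError(f"stratum label {label!r} not in dataset (have {data.strata_labels})")
    per_respondent = data.records.drop_duplicates("respondent_id")[["respondent_id", label]]
    out: dict[str, set[str]] = {}
    for rid, value in zip(per_respondent["respondent_id"], per_respondent[label]):
        if aggregation is None:
            stratum = str(value)
        else:
            stratum = aggregation.get(str(value), "unmapped")
        out.setdefault(stratum, set()).add(rid)
    return {name: data.subset_respondents(ids) for name, ids in out.items()}
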