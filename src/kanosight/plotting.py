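"""Quadrant chart of Better/|Worse| coordinates with importance-shift arrows.

The chart shows |Worse| on the x-axis and Better on the y-axis (the sign of
Worse is flipped for presentation only), with quadrant boundaries at the
unit-square midlines x = 0.5 and y = 0.5:

* upper right  — one-dimensional (high Better, high |Worse|)
* upper left   — attractive
* lower right  — must-be
* lower left   — indifferent

Every plot gets a CSV data twin carrying the plotted numbers at full
precision, so any figure can be regenerated or re-ranked bit-for-bit.
"""

from __future__ import annotations

from collections.abc import Sequence
from pathlib import Path

import pandas as pd

from .timko import TimkoIndices

_BOUNDARY = 0.5
_TOL = 1e-9


def assign_quadrant(worse: float, better: float, boundary: float = _BOUNDARY) -> str:
    """Kano quadrant of a signed (worse, better) coordinate.

    Points within 1e-9 of a boundary midline are labeled ``"borderline"``.
    """
    x, y = abs(worse), better
    if abs(x - boundary) <= _TOL or abs(y - boundary) <= _TOL:
        return "borderline"
    if x > boundary:
        return "must-be" if y < boundary else "one-dimensional"
    return "indifferent" if y < boundary else "attractive"


def quadrant_data(indices: Sequence[TimkoIndices],
                  annotate_importance_shift: bool = True) -> pd.DataFrame:
    """Tabulate plot coordinates, quadrants and (optional) shift segments."""
    rows = []
    for idx in indices:
        row = {
            "attribute_id": idx.attribute_id,
            "worse_abs": abs(idx.worse),
            "better": idx.better,
            "quadrant": assign_quadrant(idx.worse, idx.better),
        }
        if idx.worse_weighted is not None:
            row["worse_weighted_abs"] = abs(idx.worse_weighted)
            row["better_weighted"] = idx.better_weighted
            row["quadrant_weighted"] = assign_quadrant(
                idx.worse_weighted, idx.better_weighted)
            if annotate_importance_shift:
                row["shift_dx"] = abs(idx.worse_weighted) - abs(idx.worse)
                row["shift_dy"] = idx.better_weighted - idx.better
        rows.append(row)
    return pd.DataFrame(rows).set_index("attribute_id")


def export_quadrant_plot(indices: Sequence[TimkoIndices],
                         path: str | Path | None = None,
                         data_path: str | Path | None = None,
                         annotate_importance_shift: bool = True,
                         title: str | None = None) -> pd.DataFrame:
    """Render the quadrant chart and write its CSV data twin.

    Returns the underlying data frame; writes an image when ``path`` is
    given (format from the suffix, e.g. ``.png``/``.svg``) and the CSV twin
    when ``data_path`` is given.  Arrows from the unweighted to the
    importance-weighted coordinate are drawn (and shift columns emitted)
    only when ``annotate_importance_shift`` is set.
    """
    frame = quadrant_data(indices, annotate_importance_shift)
    if data_path is not None:
        # %.17g round-trips doubles exactly: the data twin must re-rank
        # bit-for-bit
        frame.to_csv(data_path, float_format="%.17g")
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 7))
        ax.axvline(_BOUNDARY, color="0.7", lw=1)
        ax.axhline(_BOUNDARY, color="0.7", lw=1)
        weighted = "better_weighted" in frame.columns
        ax.scatter(frame["worse_abs"], frame["better"], marker="o",
                   color="tab:blue", label="unweighted")
        if weighted:
            ax.scatter(frame["worse_weighted_abs"], frame["better_weighted"],
                       marker="s", color="tab:orange", label="importance-weighted")
        for attr, row in frame.iterrows():
            ax.annotate(attr, (row["worse_abs"], row["better"]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
            if weighted and annotate_importance_shift:
                ax.annotate("", xy=(row["worse_weighted_abs"], row["better_weighted"]),
                            xytext=(row["worse_abs"], row["better"]),
                            arrowprops={"arrowstyle": "->", "color": "0.4", "lw": 0.8})
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_xlabel("|Worse| (dissatisfaction index)")
        ax.set_ylabel("Better (satisfaction index)")
        corner_labels = {(0.98, 0.02): "must-be", (0.98, 0.98): "one-dimensional",
                         (0.02, 0.98): "attractive", (0.02, 0.02): "indifferent"}
        for (x, y), name in corner_labels.items():
            ax.annotate(name, (x, y), color="0.6", fontsize=9,
                        ha="right" if x > 0.5 else "left",
                        va="top" if y > 0.5 else "bottom")
        if title:
            ax.set_title(title)
        ax.legend(loc="center right", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return frame
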