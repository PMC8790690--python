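"""Model/Results facade over the full Kano evaluation pipeline.

``KanoModel`` holds a survey dataset plus analysis settings; ``fit()``
runs categorization, index computation and in-line-of-sight ranking and
returns a ``KanoResults`` carrying the per-attribute tables, optional
bootstrap uncertainties, and a ``summary()``.

Example
-------
>>> from kanosight import KanoModel, datasets, synth
>>> profiles = synth.profiles_from_tables(datasets.reference_counts("A"),
...                                       datasets.reference_importance("A"))
>>> data = synth.generate_survey(profiles, n_respondents=191, seed=7)
>>> res = KanoModel(data, pov="must-be").fit()
>>> res.ranking_["rank"].idxmin()  # doctest: +SKIP
'legal_conformity'
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from . import kano, line_of_sight, timko
from .exceptions import KanosightError
from .kano import CATEGORIES, CategoryCounts
from .line_of_sight import CornerPOV
from .survey import SurveyDataset
from ._rounding import round_half_up


class KanoModel:
    """Kano survey evaluation bound to one dataset.

    Parameters
    ----------
    data
        A :class:`~kanosight.survey.SurveyDataset`.
    pov
        Quadrant corner for the in-line-of-sight ranking (name or
        :class:`~kanosight.line_of_sight.CornerPOV`); default ``"must-be"``.
    relevance_weights
        Relevance-level -> importance mapping; default linear grid.
    precedence
        Tie precedence for the category-assignment rules.
    """

    def __init__(self, data: SurveyDataset, pov: CornerPOV | str = "must-be",
                 relevance_weights: Mapping[str, float] | None = None,
                 precedence: tuple[str, ...] = kano.DEFAULT_PRECEDENCE):
        if not isinstance(data, SurveyDataset):
            raise KanosightError("data must be a SurveyDataset")
        self.data = data
        self.pov = pov if isinstance(pov, CornerPOV) else CornerPOV(pov)
        self.relevance_weights = dict(relevance_weights or timko.DEFAULT_RELEVANCE_WEIGHTS)
        self.precedence = tuple(precedence)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, attributes=None,
                       **kwargs) -> "KanoModel":
        """Build a model directly from a canonical long-format frame."""
        return cls(SurveyDataset(frame, attributes=attributes), **kwargs)

    # -- fitting --------------------------------------------------------------

    def _tables(self, data: SurveyDataset) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        counts_rows, indices_rows, coords = {}, {}, {}
        for attr in data.attributes:
            counts = kano.tabulate(data, attr)
            idx = timko.indices_from_counts(
                counts, timko.importance_score(data, attr, self.relevance_weights))
            counts_rows[attr] = {
                **{c: counts[c] for c in CATEGORIES},
                "n_complete": counts.n_complete,
                "n_missing": counts.n_missing,
                "category_mode": kano.assign_mode(counts, self.precedence),
                "category_ifthen": kano.assign_ifthen(counts, self.precedence),
            }
            indices_rows[attr] = {
                "better": idx.better, "worse": idx.worse,
                "importance": idx.importance,
                "better_weighted": idx.better_weighted,
                "worse_weighted": idx.worse_weighted,
            }
            coords[attr] = idx.weighted_coordinate
        ranking = line_of_sight.rank_attributes(coords, self.pov)
        ranking_rows = {
            r.attribute_id: {"distance": r.distance, "angle": r.angle,
                             "coefficient": r.coefficient, "rank": r.rank,
                             "tied": r.tied}
            for r in ranking
        }
        return (pd.DataFrame.from_dict(counts_rows, orient="index"),
                pd.DataFrame.from_dict(indices_rows, orient="index"),
                pd.DataFrame.from_dict(ranking_rows, orient="index"))

    def fit(self, n_boot: int = 0, boot_seed: int | None = None) -> "KanoResults":
        """Run the pipeline; optionally bootstrap respondents for uncertainty.

        With ``n_boot > 0``, respondents are resampled with replacement
        ``n_boot`` times; the results then carry 95% percentile intervals
        for the weighted coordinates and the frequency with which each
        attribute attains each rank.
        """
        counts, indices, ranking = self._tables(self.data)
        boot_ci = rank_freq = None
        if n_boot > 0:
            rng = np.random.default_rng(boot_seed)
            respondents = np.asarray(self.data.respondents, dtype=object)
            boot_b, boot_w, boot_rank = [], [], []
            for _ in range(n_boot):
                sample = rng.choice(respondents, size=len(respondents), replace=True)
                frames = []
                for k, rid in enumerate(sample):
                    sub = self.data.records[self.data.records["respondent_id"] == rid]
                    sub = sub.copy()
                    sub["respondent_id"] = f"b{k}"
                    frames.append(sub)
                bdata = SurveyDataset(pd.concat(frames, ignore_index=True),
                                      attributes=self.data.attributes)
                _, bidx, brank = self._tables(bdata)
                boot_b.append(bidx["better_weighted"])
                boot_w.append(bidx["worse_weighted"])
                boot_rank.append(brank["rank"])
            bb, bw = pd.concat(boot_b, axis=1), pd.concat(boot_w, axis=1)
            boot_ci = pd.DataFrame({
                "better_weighted_lo": bb.quantile(0.025, axis=1),
                "better_weighted_hi": bb.quantile(0.975, axis=1),
                "worse_weighted_lo": bw.quantile(0.025, axis=1),
                "worse_weighted_hi": bw.quantile(0.975, axis=1),
            })
            br = pd.concat(boot_rank, axis=1)
            rank_freq = pd.DataFrame(
                {k: (br == k).mean(axis=1) for k in range(1, len(br) + 1)})
        return KanoResults(self, counts, indices, ranking,
                           boot_ci=boot_ci, rank_frequency=rank_freq)


class KanoResults:
    """Fitted Kano evaluation: per-attribute tables and reporting helpers.

    Attributes
    ----------
    counts_ : DataFrame
        Category counts (M, P, A, I, R, Q), completeness bookkeeping and the
        mode/if-then category assignments.
    indices_ : DataFrame
        Better/Worse, importance and the importance-weighted values, at full
        precision.
    ranking_ : DataFrame
        In-line-of-sight distance, angle, coefficient, rank, tie flag.
    boot_ci_ : DataFrame or None
        95% bootstrap intervals for the weighted coordinates.
    rank_frequency_ : DataFrame or None
        Bootstrap frequency of each attribute attaining each rank.
    """

    def __init__(self, model: KanoModel, counts: pd.DataFrame,
                 indices: pd.DataFrame, ranking: pd.DataFrame,
                 boot_ci: pd.DataFrame | None = None,
                 rank_frequency: pd.DataFrame | None = None):
        self.model = model
        self.counts_ = counts
        self.indices_ = indices
        self.ranking_ = ranking
        self.boot_ci_ = boot_ci
        self.rank_frequency_ = rank_frequency

    @property
    def attributes(self) -> list[str]:
        return list(self.counts_.index)

    @property
    def weighted_coordinates(self) -> dict[str, timko.Coordinate]:
        return {attr: timko.Coordinate(row["worse_weighted"], row["better_weighted"])
                for attr, row in self.indices_.iterrows()}

    def counts_for(self, attribute: str) -> CategoryCounts:
        row = self.counts_.loc[attribute]
        return CategoryCounts.from_values(
            attribute, **{c: int(row[c]) for c in CATEGORIES},
            n_missing=int(row["n_missing"]))

    def rounded_indices(self, ndigits: int = 2) -> pd.DataFrame:
        """Reporting view of ``indices_`` with half-up rounding."""
        return self.indices_.map(lambda x: round_half_up(x, ndigits))

    def rounded_ranking(self) -> pd.DataFrame:
        """Reporting view of ``ranking_``: d and f to 2 decimals, integer angle."""
        out = self.ranking_.copy()
        out["distance"] = out["distance"].map(lambda x: round_half_up(x, 2))
        out["angle"] = out["angle"].map(lambda x: round_half_up(x, 0))
        out["coefficient"] = out["coefficient"].map(lambda x: round_half_up(x, 2))
        return out

    def summary(self) -> str:
        """Human-readable summary of counts, indices and the ranking."""
        lines = [
            "Kano survey evaluation",
            "=" * 70,
            f"Respondents: {self.model.data.n_respondents}"
            f"   Attributes: {len(self.attributes)}"
            f"   POV: {self.model.pov.name}"
            f" (angle reference: {self.model.pov.angle_reference})",
            "",
            "Category counts and assignments",
            "-" * 70,
            self.counts_.to_string(),
            "",
            "Better/Worse indices (half-up, 2 decimals)",
            "-" * 70,
            self.rounded_indices().to_string(),
            "",
            f"In-line-of-sight ranking from the {self.model.pov.name} corner",
            "-" * 70,
            self.rounded_ranking().sort_values("rank").to_string(),
        ]
        if self.rank_frequency_ is not None:
            lines += ["", "Bootstrap rank frequencies", "-" * 70,
                      self.rank_frequency_.round(3).to_string()]
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()

    def to_csv(self, directory) -> dict[str, str]:
        """Write counts/indices/ranking tables to ``directory``.

        Rounded reporting tables mirror the published layout; a
        ``ranking_full_precision.csv`` twin carries unrounded values.
        """
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (
            ("counts", self.counts_),
            ("indices", self.rounded_indices()),
            ("ranking", self.rounded_ranking()),
            ("ranking_full_precision", self.ranking_),
            ("indices_full_precision", self.indices_),
        ):
            path = directory / f"{name}.csv"
            fmt = "%.17g" if name.endswith("full_precision") else None
            frame.rename_axis("attribute_id").to_csv(path, float_format=fmt)
            paths[name] = str(path)
        return paths

    def plot_quadrants(self, path=None, data_path=None,
                       annotate_importance_shift: bool = True):
        """Quadrant chart of the (|Worse|, Better) coordinates; see
        :func:`kanosight.plotting.export_quadrant_plot`."""
        from .plotting import export_quadrant_plot

        indices = [
            timko.TimkoIndices(attr, row["better"], row["worse"], row["importance"],
                               row["better_weighted"], row["worse_weighted"])
            for attr, row in self.indices_.iterrows()
        ]
        return export_quadrant_plot(
            indices, path=path, data_path=data_path,
            annotate_importance_shift=annotate_importance_shift)
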