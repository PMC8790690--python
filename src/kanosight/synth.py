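"""Synthetic Kano survey panels.

No respondent-level data ship with published Kano studies; only aggregated
category counts and mean importance values are printed.  This module
generates full panels whose answer pairs are drawn from per-attribute
probability tables over the 5x5 functional x dysfunctional grid and whose
relevance answers come from a 5-level distribution, so the entire pipeline
(ingestion -> categorization -> indices -> ranking) can be exercised and
calibration targets recovered without external data.

Respondents and attributes are sampled independently (no published
correlation structure to emulate); a ``consistency`` hook lets stress tests
inject respondents who answer every attribute according to one latent
category.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import KanosightError
from .kano import CATEGORIES, CATEGORY_MATRIX, CategoryCounts
from .levels import DYSFUNCTIONAL_LEVELS, FUNCTIONAL_LEVELS, RELEVANCE_LEVELS
from .survey import SurveyDataset
from .timko import DEFAULT_RELEVANCE_WEIGHTS

_PROB_TOL = 1e-9

#: One canonical answer cell per category, used for inverse calibration from
#: category counts; each maps back to its category under the Kano grid.
REPRESENTATIVE_PAIRS: dict[str, tuple[str, str]] = {
    "A": ("delighted", "expected"),
    "P": ("delighted", "dislike"),
    "M": ("expected", "dislike"),
    "I": ("neutral", "neutral"),
    "R": ("dislike", "expected"),
    "Q": ("delighted", "delighted"),
}


@dataclass
class AttributeProfile:
    """Sampling distribution for one attribute.

    ``pair_probs`` is a 5x5 array over (functional, dysfunctional) answer
    levels; ``missing_mass`` is the probability that the pair is (partially)
    unanswered.  ``relevance_probs`` covers the 5 relevance levels with an
    optional ``relevance_missing`` mass.  Each distribution must sum to 1.
    """

    attribute_id: str
    pair_probs: np.ndarray
    relevance_probs: np.ndarray
    missing_mass: float = 0.0
    relevance_missing: float = 0.0

    def __post_init__(self) -> None:
        self.pair_probs = np.asarray(self.pair_probs, dtype=float)
        self.relevance_probs = np.asarray(self.relevance_probs, dtype=float)
        if self.pair_probs.shape != (5, 5):
            raise KanosightError("pair_probs must be a 5x5 table")
        if self.relevance_probs.shape != (5,):
            raise KanosightError("relevance_probs must have 5 entries")
        for name, probs, extra in (
            ("pair_probs", self.pair_probs, self.missing_mass),
            ("relevance_probs", self.relevance_probs, self.relevance_missing),
        ):
            if (probs < -_PROB_TOL).any() or extra < -_PROB_TOL:
                raise KanosightError(f"{name}: probabilities must be non-negative")
            total = probs.sum() + extra
            if abs(total - 1.0) > _PROB_TOL:
                raise KanosightError(f"{name}: probabilities sum to {total}, not 1")

    def expected_category_probs(self) -> dict[str, float]:
        """Category distribution induced by the pair table (complete pairs)."""
        out = {c: 0.0 for c in CATEGORIES}
        complete = self.pair_probs.sum()
        for i, f in enumerate(FUNCTIONAL_LEVELS):
            for j, d in enumerate(DYSFUNCTIONAL_LEVELS):
                out[CATEGORY_MATRIX[(f, d)]] += self.pair_probs[i, j]
        if complete > 0:
            out = {c: p / complete for c, p in out.items()}
        return out

    def expected_importance(self,
                            weights: Mapping[str, float] | None = None) -> float:
        """Mean importance implied by the relevance distribution."""
        weights = weights or DEFAULT_RELEVANCE_WEIGHTS
        mass = self.relevance_probs.sum()
        if mass == 0:
            raise KanosightError("relevance distribution has no non-missing mass")
        return float(sum(
            p * weights[level]
            for p, level in zip(self.relevance_probs, RELEVANCE_LEVELS)
        ) / mass)


def generate_survey(profiles: Sequence[AttributeProfile], n_respondents: int,
                    seed: int | None = None,
                    strata_spec: Mapping[str, Mapping[str, float]] | None = None,
                    consistency: float = 0.0) -> SurveyDataset:
    """Draw a synthetic respondent panel.

    Each respondent draws, independently per attribute, one functional/
    dysfunctional pair (or a missing pair) and one relevance level from the
    attribute's profile.  ``strata_spec`` maps stratum labels to value ->
    probability tables sampled once per respondent.  With probability
    ``consistency`` a respondent instead answers every attribute with the
    representative pair of a single latent category drawn from the averaged
    induced category distribution (default 0: fully independent answers).
    Identical seeds yield identical datasets.
    """
    if n_respondents < 1:
        raise KanosightError("n_respondents must be at least 1")
    if not profiles:
        raise KanosightError("at least one attribute profile is required")
    if not 0 <= consistency <= 1:
        raise KanosightError("consistency must be a probability")
    rng = np.random.default_rng(seed)
    n = int(n_respondents)
    ids = [f"r{i+1:05d}" for i in range(n)]

    latent_mask = rng.random(n) < consistency if consistency > 0 else np.zeros(n, bool)
    if latent_mask.any():
        mean_probs = np.mean(
            [list(p.expected_category_probs().values()) for p in profiles], axis=0)
        mean_probs = mean_probs / mean_probs.sum()
        latent = rng.choice(len(CATEGORIES), size=n, p=mean_probs)

    strata_cols: dict[str, np.ndarray] = {}
    for label, dist in (strata_spec or {}).items():
        values = list(dist)
        probs = np.asarray([dist[v] for v in values], dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > _PROB_TOL:
            raise KanosightError(f"stratum {label!r}: invalid probability vector")
        strata_cols[label] = np.asarray(values, dtype=object)[
            rng.choice(len(values), size=n, p=probs)
        ]

    frames = []
    cells = [(f, d) for f in FUNCTIONAL_LEVELS for d in DYSFUNCTIONAL_LEVELS]
    for profile in profiles:
        pair_p = np.append(profile.pair_probs.ravel(), profile.missing_mass)
        pair_p = np.clip(pair_p, 0, None) / np.clip(pair_p, 0, None).sum()
        draws = rng.choice(len(cells) + 1, size=n, p=pair_p)
        functional = [cells[k][0] if k < len(cells) else None for k in draws]
        dysfunctional = [cells[k][1] if k < len(cells) else None for k in draws]
        rel_p = np.append(profile.relevance_probs, profile.relevance_missing)
        rel_p = np.clip(rel_p, 0, None) / np.clip(rel_p, 0, None).sum()
        rel_draws = rng.choice(len(RELEVANCE_LEVELS) + 1, size=n, p=rel_p)
        relevance = [RELEVANCE_LEVELS[k] if k < len(RELEVANCE_LEVELS) else None
                     for k in rel_draws]
        if latent_mask.any():
            for i in np.flatnonzero(latent_mask):
                f, d = REPRESENTATIVE_PAIRS[CATEGORIES[latent[i]]]
                functional[i], dysfunctional[i] = f, d
        frame = pd.DataFrame({
            "respondent_id": ids,
            "attribute_id": profile.attribute_id,
            "functional": functional,
            "dysfunctional": dysfunctional,
            "relevance": relevance,
        })
        for label, values in strata_cols.items():
            frame[label] = values
        frames.append(frame)
    records = pd.concat(frames, ignore_index=True)
    return SurveyDataset(records, attributes=[p.attribute_id for p in profiles])


def relevance_probs_for_importance(importance: float) -> np.ndarray:
    """Relevance distribution on two adjacent levels with the given mean.

    The default level weights form the grid {1, 0.75, 0.5, 0.25, 0}; any
    target mean in [0, 1] is matched exactly by splitting mass between the
    two grid points that bracket it.
    """
    if not 0 <= importance <= 1:
        raise KanosightError(f"importance must be in [0, 1], got {importance}")
    grid = [DEFAULT_RELEVANCE_WEIGHTS[level] for level in RELEVANCE_LEVELS]
    probs = np.zeros(5)
    hi = max(i for i, w in enumerate(grid) if w >= importance - _PROB_TOL)
    lo = min(i for i, w in enumerate(grid) if w <= importance + _PROB_TOL)
    if hi == lo:
        probs[hi] = 1.0
        return probs
    w_hi = (importance - grid[lo]) / (grid[hi] - grid[lo])
    probs[hi] = w_hi
    probs[lo] = 1.0 - w_hi
    return probs


def profile_from_counts(counts: CategoryCounts, importance: float,
                        missing_mass: float = 0.0) -> AttributeProfile:
    """Inverse-calibrate a profile from category counts and mean importance.

    All probability mass for a category is placed on its representative
    answer cell, so the induced category distribution equals
    ``counts / n_complete`` exactly; the relevance distribution splits mass
    between the two grid levels bracketing ``importance``.
    """
    if counts.n_complete == 0:
        raise KanosightError("cannot calibrate a profile from zero complete pairs")
    pair_probs = np.zeros((5, 5))
    scale = (1.0 - missing_mass) / counts.n_complete
    for cat, n in counts.counts.items():
        f, d = REPRESENTATIVE_PAIRS[cat]
        i, j = FUNCTIONAL_LEVELS.index(f), DYSFUNCTIONAL_LEVELS.index(d)
        pair_probs[i, j] += n * scale
    return AttributeProfile(
        counts.attribute_id,
        pair_probs,
        relevance_probs_for_importance(importance),
        missing_mass=missing_mass,
    )


def profiles_from_tables(counts: Mapping[str, CategoryCounts],
                         importance: Mapping[str, float]) -> list[AttributeProfile]:
    """Calibrate one profile per attribute from count and importance tables."""
    return [profile_from_counts(counts[attr], importance[attr]) for attr in counts]


def profiles_to_yaml(profiles: Sequence[AttributeProfile], path) -> None:
    """Write profiles to a plain-text YAML config."""
    import yaml

    payload = []
    for p in profiles:
        payload.append({
            "attribute_id": p.attribute_id,
            "pair_probs": [[float(x) for x in row] for row in p.pair_probs],
            "relevance_probs": [float(x) for x in p.relevance_probs],
            "missing_mass": float(p.missing_mass),
            "relevance_missing": float(p.relevance_missing),
        })
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def profiles_from_yaml(path) -> list[AttributeProfile]:
    """Read profiles from a YAML config written by :func:`profiles_to_yaml`."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [AttributeProfile(
        entry["attribute_id"],
        np.asarray(entry["pair_probs"], dtype=float),
        np.asarray(entry["relevance_probs"], dtype=float),
        missing_mass=float(entry.get("missing_mass", 0.0)),
        relevance_missing=float(entry.get("relevance_missing", 0.0)),
    ) for entry in payload]
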