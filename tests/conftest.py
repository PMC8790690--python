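import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from kanosight import SurveyDataset, datasets, synth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Published Table-7-style ranking expectations, frozen for regression tests:
#: attribute -> (distance, angle_deg, coefficient, rank), as printed.
PRINTED_RANKING = {
    "A": {
        "practicality": (0.32, 51, 0.36, 4),
        "risk_adequacy": (0.29, 53, 0.34, 3),
        "ethical_soundness": (0.35, 38, 0.38, 5),
        "legal_conformity": (0.23, 37, 0.26, 1),
        "content_validity": (0.24, 59, 0.29, 2),
        "technical_adequacy": (0.51, 48, 0.55, 8),
        "usability": (0.45, 43, 0.48, 6),
        "resource_efficiency": (0.70, 26, 0.72, 9),
        "transparency": (0.46, 34, 0.49, 7),
    },
    "B": {
        "practicality": (0.31, 52, 0.35, 4),
        "risk_adequacy": (0.27, 56, 0.32, 3),
        "ethical_soundness": (0.35, 30, 0.38, 5),
        "legal_conformity": (0.26, 27, 0.28, 1),
        "content_validity": (0.24, 61, 0.29, 2),
        "technical_adequacy": (0.50, 47, 0.54, 8),
        "usability": (0.42, 45, 0.46, 6),
        "resource_efficiency": (0.64, 26, 0.66, 9),
        "transparency": (0.51, 34, 0.54, 7),
    },
}

#: Published Better/Worse table: attribute -> (better, worse, better_w, worse_w).
PRINTED_INDICES = {
    "A": {
        "practicality": (0.28, -0.91, 0.25, -0.80),
        "risk_adequacy": (0.27, -0.94, 0.23, -0.82),
        "ethical_soundness": (0.26, -0.86, 0.22, -0.72),
        "legal_conformity": (0.15, -0.92, 0.14, -0.82),
        "content_validity": (0.23, -0.96, 0.21, -0.88),
        "technical_adequacy": (0.47, -0.80, 0.38, -0.66),
        "usability": (0.37, -0.80, 0.31, -0.67),
        "resource_efficiency": (0.45, -0.55, 0.31, -0.37),
        "transparency": (0.33, -0.78, 0.26, -0.62),
    },
    "B": {
        "practicality": (0.28, -0.91, 0.25, -0.81),
        "risk_adequacy": (0.26, -0.96, 0.23, -0.85),
        "ethical_soundness": (0.22, -0.84, 0.18, -0.69),
        "legal_conformity": (0.13, -0.89, 0.12, -0.77),
        "content_validity": (0.23, -0.94, 0.21, -0.88),
        "technical_adequacy": (0.44, -0.79, 0.37, -0.65),
        "usability": (0.35, -0.83, 0.30, -0.70),
        "resource_efficiency": (0.39, -0.59, 0.28, -0.42),
        "transparency": (0.37, -0.73, 0.29, -0.58),
    },
}

#: The published consensus priority order (identical in both groups).
REFERENCE_ORDER = [
    "legal_conformity", "content_validity", "risk_adequacy", "practicality",
    "ethical_soundness", "usability", "transparency", "technical_adequacy",
    "resource_efficiency",
]


@pytest.fixture(scope="session")
def reference_profiles_a():
    return synth.profiles_from_tables(datasets.reference_counts("A"),
                                      datasets.reference_importance("A"))


@pytest.fixture(scope="session")
def small_panel(reference_profiles_a):
    """A 120-respondent synthetic panel with a gender stratum."""
    return synth.generate_survey(
        reference_profiles_a, n_respondents=120, seed=20260922,
        strata_spec={"gender": {"female": 0.14, "male": 0.86}})


@pytest.fixture()
def tiny_dataset():
    """Three respondents x two attributes, with one absent answer."""
    rows = []
    answers = {
        ("r1", "alpha"): ("expected", "dislike", "very_important"),
        ("r2", "alpha"): ("delighted", "dislike", "important"),
        ("r3", "alpha"): ("neutral", None, "very_important"),
        ("r1", "beta"): ("delighted", "expected", "important"),
        ("r2", "beta"): ("neutral", "neutral", "neutral"),
        ("r3", "beta"): ("dislike", "expected", "unimportant"),
    }
    for (rid, attr), (f, d, r) in answers.items():
        rows.append({"respondent_id": rid, "attribute_id": attr,
                     "functional": f, "dysfunctional": d, "relevance": r,
                     "gender": "female" if rid == "r2" else "male"})
    return SurveyDataset(pd.DataFrame(rows))
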