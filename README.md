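# kanosight

Kano-survey evaluation and **in-line-of-sight prioritization** of quality
attributes.

When a panel is asked to rate product or service attributes with a Kano
questionnaire — each attribute probed with a positively worded *functional*
question ("what if this were present?") and a negatively worded
*dysfunctional* question ("what if it were absent?") — classical evaluation
assigns each attribute one of six categories (attractive **A**, performance /
one-dimensional **P**, must-be **M**, indifferent **I**, reverse **R**,
questionable **Q**). That works poorly when every attribute lands in the same
category, as routinely happens for pre-vetted quality criteria: in the
motivating use case, physicians rating nine health-app quality principles
classed essentially all of them as *must-be*, leaving nothing to prioritize.

`kanosight` implements the full evaluation stack and a geometric ranking that
resolves exactly this situation:

1. **Categorization** — each answer pair maps through the standard 5×5 Kano
   grid; per-attribute category tallies feed the classical *mode* and
   *if-then* assignment rules.
2. **Satisfaction indices** (after Timko) — per attribute,

   ```
   Better =  (A + P) / (A + P + M + I)          0 ≤ Better ≤ 1
   Worse  = −(P + M) / (A + P + M + I)         −1 ≤ Worse  ≤ 0
   ```

   optionally scaled by the mean self-stated importance of the attribute
   (relevance answers mapped to the grid {1, 0.75, 0.5, 0.25, 0}).
3. **In-line-of-sight ranking** — each attribute's weighted (Worse, Better)
   coordinate is scored against a quadrant-corner "point of view" (POV),
   by default the must-be corner (−1, 0):

   ```
   d     Euclidean distance from the coordinate to the corner
   α     angle (degrees) between the quadrant's reference axis and the
         corner-to-coordinate line;  for must-be: α = arctan(Better / (1 + Worse))
   f     = d + (α / 90) · 0.05 · √2
   ```

   Attributes are ranked by ascending `f`: distance dominates, and the angle
   term (scaled to 5% of the maximal in-square distance √2) breaks near-ties
   directionally. Any of the four corners can serve as POV.

Alongside the analysis stack the package ships a **synthetic panel
generator** (per-attribute probability tables over the 5×5 answer grid plus a
5-level relevance distribution, with inverse calibration from published
count tables), Pearson χ² utilities for test/validation group comparisons,
a quadrant plot with importance-shift arrows, and a CLI.

## Worked example

The package bundles the aggregated tables of a published physician survey
(382 respondents, nine health-app quality principles, split into test group
A and validation group B of 191 each) in `kanosight.datasets`. Ranking group
A from the must-be corner:

```python
from kanosight import datasets, indices_from_counts, rank_attributes

counts = datasets.reference_counts("A")
importance = datasets.reference_importance("A")
idx = {a: indices_from_counts(counts[a], importance[a]) for a in counts}
results = rank_attributes({a: i.weighted_coordinate for a, i in idx.items()},
                          "must-be")
```

which, rounded at the reporting boundary, prints

```
                     better  worse  importance     d  alpha     f  rank
legal_conformity       0.15  -0.92        0.89  0.23   37.0  0.25   1.0
content_validity       0.23  -0.96        0.91  0.24   58.0  0.29   2.0
risk_adequacy          0.27  -0.94        0.87  0.30   52.0  0.34   3.0
practicality           0.28  -0.91        0.88  0.32   51.0  0.36   4.0
ethical_soundness      0.26  -0.86        0.85  0.35   39.0  0.38   5.0
usability              0.37  -0.80        0.84  0.45   43.0  0.48   6.0
transparency           0.33  -0.78        0.79  0.46   34.0  0.49   7.0
technical_adequacy     0.47  -0.80        0.82  0.51   48.0  0.55   8.0
resource_efficiency    0.45  -0.55        0.68  0.70   26.0  0.72   9.0
```

Every principle has a low `Better` and strongly negative `Worse` — all
must-be, unrankable by category — yet `f` orders them cleanly: legal
conformity is the top priority (closest to the must-be corner), resource
efficiency the last (farthest, drifting toward indifferent). Running the same
code with `"B"` yields the identical permutation, the replication that
validates the method.

For raw response data, the statsmodels-style facade runs the whole pipeline:

```python
from kanosight import KanoModel, read_survey, split_groups

data = read_survey("responses.csv")
a, b = split_groups(data, 0.5, seed=42)
res = KanoModel(a, pov="must-be").fit()     # optionally fit(n_boot=200)
print(res.summary())
res.plot_quadrants(path="quadrants.png", data_path="quadrants.csv")
```

and the same pipeline is scriptable from the shell:

```
kanosight simulate --out panel.csv --n 382 --seed 3 --group A
kanosight rank --input panel.csv --out-dir report --seed 3 --pov must-be
```

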