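# Methods

This note documents the models and procedures implemented in `kanosight`,
the choices made where the design was genuinely open, and what the bundled
synthetic data can and cannot show.

## The Kano categorization

Each attribute is probed with a functional ("what if present?") and a
dysfunctional ("what if absent?") question on the same 5-level scale
(*delighted, expected, neutral, tolerated, dislike*). A complete answer pair
maps through the standard 5×5 grid to one of six categories:

| functional \ dysfunctional | delighted | expected | neutral | tolerated | dislike |
|---|---|---|---|---|---|
| delighted | Q | A | A | A | P |
| expected  | R | Q | I | I | M |
| neutral   | R | I | I | I | M |
| tolerated | R | I | I | Q | M |
| dislike   | R | R | R | R | Q |

Enumerating the grid gives the category multiset {Q:4, A:3, P:1, M:3, I:7,
R:7}, which the test suite asserts as a brute-force oracle. A pair with
either half absent is uncategorizable; it is tallied in `n_missing` and
never imputed.

Two classical per-attribute assignment rules operate on the category tally:
the **mode rule** (largest count wins) and the **if-then rule** (if
P+A+M > I+R+Q, the argmax within {P, A, M}; if smaller, the argmax within
{I, R, Q}). The rules are silent on ties, so the package uses a documented,
configurable precedence **M > P > A > I > R > Q** — an essentials-first
convention; the reference tables never exhibit a tie, so the choice cannot
be validated against them. On exact equality of the if-then sides (also
unspecified) the rule falls back to the global argmax under the same
precedence.

## Better/Worse indices and importance weighting

From the tally, with R and Q excluded,

```
Better =  (A + P) / (A + P + M + I) ∈ [0, 1]
Worse  = −(P + M) / (A + P + M + I) ∈ [−1, 0]
```

`Worse` is stored signed; presentation layers show |Worse|. Both indices are
undefined when A+P+M+I = 0 (an explicit error, not a silent 0).

Importance per attribute is the mean of the 5-level relevance answers under
the mapping {very important → 1, important → 0.75, neutral → 0.5,
less important → 0.25, unimportant → 0}. The uniform linear grid is the
package default because it reproduces the 0.68–0.94 importance magnitudes of
the reference tables; the mapping is a parameter, since survey traditions
differ. Weighted indices are plain scalar products `Better·importance`,
`Worse·importance`, which can never leave the index bounds.

All arithmetic runs at full double precision; **half-up rounding (2 decimals
for indices and coefficients, whole degrees for angles) is applied only at
the reporting boundary**. The reference tables carry occasional one-unit-in-
the-last-place artifacts from their own rounding chains, so regression tests
compare at one ULP rather than bit-exactly.

## In-line-of-sight ranking

The four quadrant corners in signed (Worse, Better) coordinates are
must-be (−1, 0), attractive (0, 1), one-dimensional (−1, 1) and indifferent
(0, 0). Given a POV corner, each attribute's importance-weighted coordinate
is scored by

```
d = Euclidean distance to the corner
α = angle in [0°, 90°] from the quadrant's reference boundary ray
f = d + (α / 90) · 0.05 · √2
```

and attributes are ranked by ascending `f`. The angle scale is fixed at 5%
of the maximal in-square distance √2 ≈ 1.414, i.e. 0.0707: the angle can
reorder only attributes whose distances differ by less than that, making `d`
the primary and `α` the secondary criterion.

Open geometric choices, and how they were fixed:

- **Reference ray per POV** (configurable): must-be measures α from the
  Worse axis increasing toward one-dimensional (α = arctan(Better/(1+Worse)),
  validated against the reference ranking tables); attractive from the
  Better axis toward one-dimensional; one-dimensional and indifferent toward
  must-be — for professional-quality contexts, proximity to must-be is the
  sensible secondary criterion. Smaller α always ranks better at equal d.
- **α at the corner itself** is defined as 0 (the directional limit does not
  exist; 0 is the only choice that keeps the corner strictly best, f = 0).
- **Exact f ties** keep input order and are flagged `tied` rather than
  resolved by an invented preference.
- A prose description of the must-be variant that circulates ("prefer less
  pronounced Worse values") is the opposite of what the validated formula
  does — small α favors points *near* the Worse axis. The implementation
  follows the formula, which reproduces all published d/α/f/rank cells.

Bound: 0 ≤ f ≤ 1.05·√2 for any in-square point, property-tested.

## Group splitting and comparison

`split_groups` partitions respondents with a seeded generator; group A gets
⌈fraction·n⌉ respondents (so 382 at 0.5 gives the 191/191 reference
design). Demographic and answer balance between groups is checked with the
Pearson χ² statistic, no continuity correction and no multiple-testing
adjustment (raw p-values only — mirroring the reference analysis; a
small-expected-count warning is emitted but does not alter the statistic).
Replication quality of a ranking is quantified per attribute by the
Euclidean distance between the two groups' weighted coordinates; a stable
design keeps all such distances below 0.05·√2 ≈ 0.0707.

## Synthetic panels

`kanosight.synth` draws respondents independently: per attribute, one
answer pair from a 5×5 probability table (plus optional missing mass) and
one relevance level from a 5-level distribution. Inverse calibration from a
published count table places each category's probability mass on one
representative cell — A→(delighted, expected), P→(delighted, dislike),
M→(expected, dislike), I→(neutral, neutral), R→(dislike, expected),
Q→(delighted, delighted) — so the induced category distribution equals the
count proportions exactly; the relevance distribution splits mass between
the two grid levels bracketing the target mean importance, matching it
exactly. Default generator conditions are therefore the reference study's
own aggregates (group sizes 191/382, category proportions and importance
values from the published tables).

What this emulates and what it does not: calibrated panels reproduce
per-attribute *category* and *importance* distributions, but not the real
spread of answers within a category across the 5×5 cells (respondent-level
answers were never published), nor any correlation between attributes or
between a respondent's answers and their strata — respondents are
exchangeable by construction. A `consistency` parameter (default 0) can
inject respondents who answer every attribute from one latent category, for
stress tests only. Passing tests on synthetic panels therefore demonstrate
correctness of the pipeline's arithmetic and its sampling behavior under
independence, not robustness to the dependence structure of real panels.

### Sampling limits of rank recovery

The coefficient gap between adjacently ranked attributes in the reference
tables can be small: usability vs transparency in group A differ by
Δf ≈ 0.008 at infinite n. On calibrated panels of n = 5000 the Monte-Carlo
standard deviation of that f difference is ≈ 0.0055, so the pair swaps in
roughly 8% of panels and the full nine-attribute permutation is recovered in
only ≈ 80% of seeds; near-certain (>99%) recovery of the complete
permutation requires panels on the order of n ≈ 15 000–30 000 (the suite
demonstrates recovery at n = 20 000). This is a property of the reference
effect sizes, not of the implementation; the corresponding Monte-Carlo test
at n = 5000 documents it by failing honestly.

## Problem sizes used in the test suite

Unit and property tests run on panels of 50–800 respondents; convergence
checks at n ∈ {100, 1000, 10000}; the split-replication check at n = 12000
and order recovery at n = 20000; the Monte-Carlo recovery study uses 100
seeds × n = 5000. The full suite completes in well under a minute on one
CPU.

## Known limitations

- The categorization grid is the standard one; modified Kano grids are out
  of scope.
- Importance weighting is scalar multiplication only; no regression-based
  self-stated-importance schemes.
- No multi-corner composite scores or cluster-then-rank procedures.
- Question-order randomization, if present in the source survey, is not
  modeled (no analysis here uses order).
- Bootstrap uncertainty (`fit(n_boot=...)`) resamples respondents i.i.d.;
  it inherits the independence caveats above.
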