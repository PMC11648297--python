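# Methods

## Model and procedure

`nmatransit` operationalises transitivity assessment for a connected
treatment network as a three-step procedure over a studies ×
characteristics table.

**Step 1 — study-pair dissimilarities.** Every pair of studies gets a
Gower dissimilarity: numeric characteristics contribute the
range-normalised absolute difference |xᵢ − yᵢ|/Rᵢ, binary and categorical
ones a 0/1 mismatch indicator, averaged with availability weights δᵢ
(δᵢ = 0 when either study misses the characteristic). The result lies in
[0, 1]; it is undefined when the pair shares no observed characteristic.
Simple matching for multi-level categorical characteristics is the
standard Gower extension of the binary rule.

**Step 2 — aggregation per comparison.** Study-pair dissimilarities are
pooled with the root mean square — a population standard deviation around
zero, preferred to the arithmetic mean because zero is the meaningful
anchor (complete similarity). Dᵂ pools the C(k,2) pairs within a
comparison (undefined for k < 2); Dᴮ pools the kₚ·k_q cross pairs of two
comparisons. Undefined pairs are excluded and the denominator reduced
(pairwise-like deletion); an aggregate with zero defined pairs propagates
as undefined. The P×P matrix with Dᵂ on the diagonal and Dᴮ off-diagonal
is the object a reviewer inspects.

**Step 3 — thresholds and verdict.** Because D values measure variability
on the same [0, 1] scale as the I² heterogeneity statistic, quartiles of
empirically derived predictive distributions of I² act as surrogate
references for "low" dissimilarity, tabulated by outcome type
(objective outcomes use the all-cause-mortality entries), treatment-
comparator type and average-study-size bin, plus a design-free general
entry (median 0.13, Q3 0.53). A D value strictly below the chosen
quantile is *low*; otherwise *likely concerning*. A network with ≥1
defined likely-concerning Dᴮ is *likely intransitive*; with no defined
Dᴮ at all it is *undetermined*, never silently transitive. The
applicability of these surrogate thresholds to any concrete clinical
question is unknown; they are configuration (a CSV the user can replace),
not truth.

**Statistical-test comparator.** Per characteristic, a one-way ANOVA F
test (numeric) or a chi-squared test without continuity correction
(binary/categorical) against the observed comparisons, at α = 0.05.
Feasibility rules mirror how these batteries fail on real networks: any
single-study comparison removes all numeric characteristics; constant
characteristics support no test; numeric characteristics constant within
a multi-study comparison leave the F statistic undefined. Datasets with
fewer than four surviving characteristics are infeasible. No multiplicity
adjustment is applied — the point of the comparator is to exhibit the
unadjusted family-wise error rate 1 − (1 − α)ᵐ. Low-expected-count
chi-squared tables are tested but flagged (`expected_counts_ok=False`)
rather than discarded.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_observed_per_multistudy_comparison` | 2 | drop rule: a characteristic observed fewer times than this in some multi-study comparison can never inform that comparison's Dᵂ |
| eligibility | ≥ 4 characteristics | below this, dissimilarity summaries are too coarse to interpret |
| `quantile` | median (q3 optional) | which quartile of the reference distribution defines "low" |
| `alpha` | 0.05 | per-test significance level of the comparator |
| `equal_var` | True | pooled-variance one-way F; `False` selects Welch's unequal-variance form |

The pooled/Welch choice is genuinely open — field practice reports "the
F test of one-way ANOVA" without specifying the variance assumption, and
common software defaults differ — so both are provided behind one flag.

## Synthetic data generator

`simulate.generate_network` emulates the structure of empirically
extracted transitivity databases: a connected network (random spanning
tree plus extra edges to the target density), a mixed characteristic set,
a large share of single-study comparisons, and MCAR missingness. The
defaults are fixed at the typical geometry of such databases — 7
treatments, 42% of possible comparisons observed, 44% single-study
comparisons, 2–5 studies otherwise (≈ 17–26 studies per network), 12
characteristics of which 7 are numeric, 7.1% missing cells, subjective
outcome vs placebo with average study size 100.

Intransitivity is injected where the assumption lives: each comparison p
receives a unit direction u_p in characteristic space, and `imbalance`
shifts the comparison-specific distributions along it — numeric means by
`imbalance·u_p[i]` on a unit-variance Gaussian base, binary/categorical
level probabilities via a softmax tilt of the logits. `imbalance = 0`
makes characteristics exchangeable across comparisons (transitive by
construction); ≥ 2 standardised units separates them sharply. All
randomness flows from one integer seed; batch members derive their seeds
by counter.

What the generator does **not** emulate: missing-not-at-random patterns,
correlated characteristics, heavy-tailed or discretised numeric scales,
field-specific effect-modifier semantics, multi-arm designs, and
arm-level outcome data. Passing tests therefore demonstrate correctness
of the machinery and behaviour under controlled imbalance, not
performance claims about any particular clinical literature.

## Numerical and design choices

- A numeric characteristic with zero observed range contributes d = 0
  with full weight δ = 1: identical values mean zero dissimilarity, and
  excluding it would silently reweight the remaining characteristics.
- Rᵢ is computed once per dataset from all observed values after
  characteristic dropping, not per comparison, so dissimilarities are
  comparable across the whole matrix.
- Comparison labels are undirected and normalised to lexicographic
  "A vs B" order; matrices order comparisons lexicographically, making
  every output deterministic under study permutation.
- Threshold comparison is strict (< is low); boundary equality is
  concerning. The middle study-size bin is closed, [50, 200].
- Two-decimal rounding is display-only; classification always uses
  unrounded values.
- Multi-arm studies are not decomposed: each input row carries exactly
  one comparison label, taken as given.
- Batch runs quarantine per-dataset failures with their error message
  instead of aborting, since real databases lose datasets at several
  stages and the counts themselves are part of the result.

## Problem sizes used in the checked examples

The automated checks run the oracle comparison on 200 random networks of
≤ 8 studies and ≤ 5 characteristics; the null-multiplicity simulation on
2 000 replicates of a 15-study, 3-comparison network with 6 i.i.d.
numeric characteristics; and verdict recovery on 50 + 50 labelled
synthetic networks at default geometry. These sizes give Monte-Carlo
standard errors of about one percentage point on the multiplicity rate
while keeping the whole suite fast.

## Known limitations

- The I²-based thresholds are surrogates adopted for their shared scale
  and direction, not calibrated to Gower dissimilarities; verdicts should
  be read as screening signals, with content expertise deciding whether
  intransitivity concerns are warranted.
- Pairwise-like deletion assumes missingness unrelated to the values
  (MCAR-like); informative missingness can bias D in either direction.
- Characteristics are unweighted; an important effect modifier counts no
  more than an incidental one.
- The per-characteristic tests inherit all their usual small-sample
  caveats (normality for the F test, expected counts for chi-squared);
  the package flags but does not repair them.
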