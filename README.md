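# nmatransit

Quantitative assessment of the **transitivity assumption** in network
meta-analysis (NMA) from study dissimilarities.

Indirect treatment comparisons are only credible when effect modifiers are
comparably distributed across the direct comparisons of the network —
the transitivity assumption. `nmatransit` measures how far a network is
from that ideal using the study-level aggregate characteristics reported
in systematic reviews, and contrasts the result with the common (but
problematic) practice of running one statistical test per characteristic.

It is aimed at systematic reviewers and evidence-synthesis methodologists
who have a table of studies × characteristics per network and want a
transparent, test-free transitivity verdict.

## Method

For studies *x*, *y* with characteristics *i = 1..m*, the **Gower
dissimilarity** is the availability-weighted mean

&nbsp;&nbsp;*d*(*x*,*y*) = Σᵢ δᵢ·dᵢ / Σᵢ δᵢ,&nbsp;&nbsp; with
dᵢ = |xᵢ − yᵢ| / Rᵢ (numeric, Rᵢ the observed range) or the 0/1 mismatch
indicator (binary/categorical), and δᵢ = 0 when either value is missing.

Study-pair dissimilarities are pooled per comparison with the **root mean
square** (a population SD around zero):

- within-comparison: *D*ᵂₚ = √( Σⱼ d²₍ⱼ₎ / C(k,2) ) over the C(k,2) study
  pairs of comparison *p* (undefined for single-study comparisons);
- between-comparison: *D*ᴮₚ٫q over all kₚ·k_q cross pairs.

Each *D* ∈ [0,1] is compared with an empirically derived **low-dissimilarity
threshold**: the median (or third quartile) of a predictive distribution of
the I² heterogeneity statistic matched to the design setting (outcome type,
treatment-comparator type, average study size), shipped as a constants
table. A *D*ᴮ at or above the threshold is *likely concerning*; one
concerning between-comparison cell makes the network **likely
intransitive**.

The comparator approach runs a one-way ANOVA F test (numeric) or
chi-squared test (categorical) of each characteristic against the observed
comparisons at α = 5%, applies the feasibility rules that make such test
batteries collapse in practice (single-study comparisons, constant
characteristics, undefined F statistics), and reports the family-wise
error rate 1 − (1 − α)ᵐ instead of adjusting — demonstrating the
multiplicity problem rather than hiding it.

## Worked example

The canonical toy network has three treatments A, B, C and six studies:
two comparing A–B, three comparing A–C, and a single study comparing B–C.

```python
from nmatransit.examples import toy_network_gower
from nmatransit.gower import dissimilarity_matrix_from_gower
from nmatransit.thresholds import classify, lookup_threshold

gm, comparisons = toy_network_gower()
dm = dissimilarity_matrix_from_gower(gm, comparisons)
print(dm.to_dataframe().round(2).to_string(na_rep="NA"))
verdict = classify(dm, lookup_threshold())
print("threshold:", lookup_threshold(), "verdict:", verdict.network_verdict)
```

prints

```
        A vs B  A vs C  B vs C
A vs B    0.01    0.99    0.31
A vs C    0.99    0.01    0.68
B vs C    0.31    0.68      NA
threshold: 0.13 verdict: likely_intransitive
```

The diagonal shows the studies *within* A–B and A–C to be nearly identical
(Dᵂ = 0.01; B–C is a single-study comparison, so Dᵂ does not apply), while
the A–B and A–C studies come from almost completely different settings
(Dᴮ = 0.99). Against the general-healthcare-setting median threshold of
0.13 every between-comparison cell is likely concerning, so an indirect
B–C estimate routed through A would likely be biased: the network is
judged likely intransitive.

## Command line

```bash
nmatransit simulate --out data/ --n 5 --seed 1     # synthetic networks
nmatransit assess data/synthetic-1.csv             # matrix + verdict
nmatransit test data/synthetic-1.csv               # per-characteristic tests
nmatransit study data/*.csv --out report/          # batch report
```

Input datasets are CSVs with columns `study_id, comparison, <characteristics>`
(missing cells empty or `NA`) and an optional YAML sidecar with
`outcome_type`, `comparator_type`, `average_study_size` and a type map.

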