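"""The multiple-statistical-test comparator for transitivity assessment.

For each characteristic, association with the observed comparisons is
tested at a 5% significance level: a one-way ANOVA F test for numeric
characteristics (pooled-variance by default, Welch's unequal-variance
form selectable) and a chi-squared test of independence, without
continuity correction, for binary/categorical ones.  One rejection is
enough to call the network likely intransitive ("conclusive");
otherwise the evidence is inconclusive.

Several feasibility rules precede testing and mirror how such test
batteries break down in practice:

* a single-study comparison anywhere in the network rules out the F
  test, so all numeric characteristics are removed;
* a characteristic constant across all studies supports neither test;
* a numeric characteristic constant within some multi-study comparison
  leaves the F statistic undefined.

Datasets retaining fewer than four characteristics are infeasible.  No
multiplicity adjustment is applied — deliberately: the family-wise
error rate 1 - (1 - alpha)^m is reported instead, to show how quickly
unadjusted per-characteristic testing inflates the false-positive risk.
Chi-squared tables with an expected cell below 5 are tested but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import NUMERIC, RESERVED_COLUMNS, TransitivityDataset
from .thresholds import (
    LIKELY_INTRANSITIVE,
    LIKELY_TRANSITIVE,
    TransitivityVerdict,
    UNDETERMINED,
)

__all__ = [
    "CharacteristicTestResult",
    "TestSuiteResult",
    "filter_testable_characteristics",
    "test_characteristic",
    "run_test_suite",
    "familywise_error_rate",
    "compare_conclusions",
]

# exclusion reasons
NONE = "none"
SINGLE_STUDY = "single_study_comparison_present"
CONSTANT_EVERYWHERE = "constant_everywhere"
CONSTANT_WITHIN = "constant_within_multistudy_comparison"
UNDEFINED_P = "undefined_p"

# verdicts
CONCLUSIVE = "likely_intransitive_conclusive"
INCONCLUSIVE = "inconclusive"
INFEASIBLE = "infeasible"

NOT_COMPARABLE = "not_comparable"


@dataclass
class CharacteristicTestResult:
    name: str
    test_used: str  # anova_f | chi_squared | none
    p_value: float = float("nan")
    statistic: float = float("nan")
    df: tuple[float, ...] = ()
    exclusion_reason: str = NONE
    expected_counts_ok: bool | None = None  # chi-squared only

    @property
    def defined(self) -> bool:
        return self.test_used != "none" and self.exclusion_reason == NONE


@dataclass
class TestSuiteResult:
    results: list[CharacteristicTestResult]
    m_tests: int
    alpha: float
    fwer: float
    verdict: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "characteristic": r.name,
                    "test": r.test_used,
                    "statistic": r.statistic,
                    "df": "/".join(f"{d:g}" for d in r.df),
                    "p_value": r.p_value,
                    "exclusion_reason": r.exclusion_reason,
                    "expected_counts_ok": r.expected_counts_ok,
                }
                for r in self.results
            ]
        )

    def write(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.to_csv(path, index=False, na_rep="NA")
        with open(path, "a") as fh:
            fh.write(
                f"# m_tests={self.m_tests} alpha={self.alpha} "
                f"fwer={self.fwer:.6f} verdict={self.verdict}\n"
            )


def familywise_error_rate(m_tests: int, alpha: float = 0.05) -> float:
    """Probability of at least one false positive among m independent tests."""
    return 1.0 - (1.0 - alpha) ** m_tests


# ----------------------------------------------------------------------
# Feasibility filtering


def filter_testable_characteristics(
    ds: TransitivityDataset,
) -> tuple[TransitivityDataset, list[tuple[str, str]]]:
    """Remove characteristics that break either test; order-independent.

    When a characteristic matches several rules, the recorded reason
    follows the priority constant-everywhere > single-study-comparison
    > constant-within-multistudy-comparison.
    """
    sizes = ds.comparison_sizes()
    any_single = any(k == 1 for k in sizes.values())
    multi = [p for p, k in sizes.items() if k >= 2]

    exclusions: list[tuple[str, str]] = []
    keep = []
    for spec in ds.characteristics:
        col = ds.data[spec.name]
        observed = col.dropna()
        if observed.nunique() <= 1:
            exclusions.append((spec.name, CONSTANT_EVERYWHERE))
            continue
        if spec.kind == NUMERIC:
            if any_single:
                exclusions.append((spec.name, SINGLE_STUDY))
                continue
            constant_within = False
            for p in multi:
                grp = col[ds.data["comparison"] == p].dropna()
                if len(grp) >= 2 and grp.nunique() == 1:
                    constant_within = True
                    break
            if constant_within:
                exclusions.append((spec.name, CONSTANT_WITHIN))
                continue
        keep.append(spec)

    cols = list(RESERVED_COLUMNS) + [s.name for s in keep]
    filtered = replace(ds, data=ds.data[cols].copy(), characteristics=list(keep))
    return filtered, exclusions


# ----------------------------------------------------------------------
# Per-characteristic tests


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, tuple[float, float], float]:
    """Welch's unequal-variance one-way F test."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    if np.any(variances == 0):
        return float("nan"), (float("nan"), float("nan")), float("nan")
    w = ns / variances
    mw = np.sum(w * means) / np.sum(w)
    a = np.sum(w * (means - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1))
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), (df1, df2), p


def test_characteristic(
    ds: TransitivityDataset,
    name: str,
    equal_var: bool = True,
) -> CharacteristicTestResult:
    """Test one characteristic against the observed comparisons.

    The comparison label is the independent (grouping) variable.
    Missing values are dropped listwise for the characteristic under
    test.  Degenerate inputs that slipped past filtering yield
    ``exclusion_reason='undefined_p'`` rather than an exception.
    """
    spec = ds.spec(name)
    col = ds.data[name]
    mask = col.notna()
    if spec.kind == NUMERIC:
        groups = [
            g.to_numpy(dtype=float)
            for _, g in col[mask].groupby(ds.data.loc[mask, "comparison"])
        ]
        groups = [g for g in groups if len(g) > 0]
        result = CharacteristicTestResult(name=name, test_used="anova_f")
        if len(groups) < 2 or sum(len(g) for g in groups) - len(groups) < 1:
            return replace(result, exclusion_reason=UNDEFINED_P)
        if equal_var:
            with np.errstate(invalid="ignore", divide="ignore"):
                f, p = stats.f_oneway(*groups)
            df = (
                float(len(groups) - 1),
                float(sum(len(g) for g in groups) - len(groups)),
            )
        else:
            f, df, p = _welch_anova(groups)
        if not np.isfinite(f) or not np.isfinite(p):
            return replace(result, exclusion_reason=UNDEFINED_P)
        return replace(result, statistic=float(f), df=df, p_value=float(p))

    table = pd.crosstab(ds.data.loc[mask, "comparison"], col[mask])
    result = CharacteristicTestResult(name=name, test_used="chi_squared")
    if table.shape[0] < 2 or table.shape[1] < 2:
        return replace(result, exclusion_reason=UNDEFINED_P)
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if not np.isfinite(chi2):
        return replace(result, exclusion_reason=UNDEFINED_P)
    return replace(
        result,
        statistic=float(chi2),
        df=(float(dof),),
        p_value=float(p),
        expected_counts_ok=bool((expected >= 5).all()),
    )


def run_test_suite(
    ds: TransitivityDataset,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> TestSuiteResult:
    """Feasibility-filter, test every surviving characteristic, summarise.

    ``m_tests`` counts the tests with a defined p-value; the verdict is
    conclusive (likely intransitive) as soon as one p-value falls below
    ``alpha``, inconclusive when all defined p-values are at or above
    it, and infeasible when fewer than four characteristics survive
    filtering or no test yields a defined p-value.
    """
    filtered, exclusions = filter_testable_characteristics(ds)
    results = [
        CharacteristicTestResult(name=n, test_used="none", exclusion_reason=r)
        for n, r in exclusions
    ]
    for spec in filtered.characteristics:
        results.append(test_characteristic(filtered, spec.name, equal_var=equal_var))
    defined = [r for r in results if r.defined]
    m = len(defined)
    if len(filtered.characteristics) < 4 or m == 0:
        verdict = INFEASIBLE
    elif any(r.p_value < alpha for r in defined):
        verdict = CONCLUSIVE
    else:
        verdict = INCONCLUSIVE
    return TestSuiteResult(
        results=results,
        m_tests=m,
        alpha=alpha,
        fwer=familywise_error_rate(m, alpha),
        verdict=verdict,
    )


# ----------------------------------------------------------------------
# Concordance with the dissimilarity approach


def compare_conclusions(
    verdict_dissim: TransitivityVerdict,
    verdict_tests: TestSuiteResult,
) -> str:
    """Cell of the 2x2 cross-classification of the two approaches.

    Returns one of ``intransitive_conclusive``,
    ``intransitive_inconclusive``, ``transitive_conclusive``,
    ``transitive_inconclusive``, or ``not_comparable`` when either
    verdict is undetermined/infeasible.
    """
    if (
        verdict_dissim.network_verdict == UNDETERMINED
        or verdict_tests.verdict == INFEASIBLE
    ):
        return NOT_COMPARABLE
    d = (
        "intransitive"
        if verdict_dissim.network_verdict == LIKELY_INTRANSITIVE
        else "transitive"
    )
    t = "conclusive" if verdict_tests.verdict == CONCLUSIVE else "inconclusive"
    return f"{d}_{t}"
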