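"""Low-dissimilarity thresholds and transitivity verdicts.

Because D^W and D^B measure variability on the same [0, 1] scale as the
I-squared heterogeneity statistic, empirically derived predictive
distributions of I-squared serve as surrogate references for what "low"
dissimilarity looks like in a given design setting.  The shipped
constants tabulate the median and third quartile of those predictive
distributions by outcome type (objective outcomes use the
all-cause-mortality rows), treatment-comparator type, and average study
size bin, plus a design-free general healthcare setting.

A D value strictly below the chosen quantile is "low"; otherwise it is
"likely concerning".  A network with at least one defined
between-comparison dissimilarity of likely-concerning size is judged
likely intransitive.  The constants are configuration, not truth: their
applicability to any concrete research question is an open empirical
matter, and user-supplied tables are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import COMPARATOR_TYPES, OUTCOME_TYPES, TransitivityDataset
from .gower import DissimilarityMatrix

__all__ = [
    "ThresholdTable",
    "TransitivityVerdict",
    "lookup_threshold",
    "classify",
    "proportion_summary",
    "LOW",
    "LIKELY_CONCERNING",
    "UNDEFINED",
]

LOW = "low"
LIKELY_CONCERNING = "likely_concerning"
UNDEFINED = "undefined"

LIKELY_TRANSITIVE = "likely_transitive"
LIKELY_INTRANSITIVE = "likely_intransitive"
UNDETERMINED = "undetermined"

SIZE_BINS = ("<50", "50-200", ">200")
QUANTILES = ("median", "q3")

_GENERAL = "general"


def size_bin(average_study_size: float) -> str:
    """Bin an average study size: below 50, 50-200 inclusive, above 200."""
    if average_study_size < 50:
        return "<50"
    if average_study_size <= 200:
        return "50-200"
    return ">200"


@dataclass
class ThresholdTable:
    """Design-factor -> (median, q3) low-dissimilarity constants."""

    entries: dict[tuple[str, str, str], tuple[float, float]]
    general: tuple[float, float]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThresholdTable":
        entries: dict[tuple[str, str, str], tuple[float, float]] = {}
        general: tuple[float, float] | None = None
        for row in df.itertuples(index=False):
            pair = (float(row.median), float(row.q3))
            if row.outcome_type == _GENERAL:
                general = pair
            else:
                entries[(row.outcome_type, row.comparator_type, row.size_bin)] = pair
        if general is None:
            raise ValueError("threshold table lacks the general-setting row")
        return cls(entries=entries, general=general)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ThresholdTable":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))

    @classmethod
    def default(cls) -> "ThresholdTable":
        text = (
            resources.files("nmatransit")
            .joinpath("data/low_dissimilarity_thresholds.csv")
            .read_text()
        )
        return cls.from_frame(pd.read_csv(StringIO(text), keep_default_na=False))

    def lookup(
        self,
        outcome_type: str | None = None,
        comparator_type: str | None = None,
        average_study_size: float | None = None,
        quantile: str = "median",
    ) -> float:
        """Resolve a design setting to its threshold constant.

        Any missing design descriptor falls back to the general
        healthcare setting.
        """
        if quantile not in QUANTILES:
            raise ValueError(f"quantile must be one of {QUANTILES}, got {quantile!r}")
        col = 0 if quantile == "median" else 1
        if outcome_type is None or comparator_type is None or average_study_size is None:
            return self.general[col]
        if outcome_type not in OUTCOME_TYPES:
            raise ValueError(f"unknown outcome_type {outcome_type!r}")
        if comparator_type not in COMPARATOR_TYPES:
            raise ValueError(f"unknown comparator_type {comparator_type!r}")
        key = (outcome_type, comparator_type, size_bin(average_study_size))
        return self.entries[key][col]


def lookup_threshold(
    outcome_type: str | None = None,
    comparator_type: str | None = None,
    average_study_size: float | None = None,
    quantile: str = "median",
    table: ThresholdTable | None = None,
) -> float:
    """Threshold constant for a design setting (default shipped table)."""
    table = table or ThresholdTable.default()
    return table.lookup(outcome_type, comparator_type, average_study_size, quantile)


# ----------------------------------------------------------------------


@dataclass
class TransitivityVerdict:
    """Cell-level dissimilarity labels plus the network-level verdict.

    ``per_cell`` maps ``(p, p)`` for within-comparison cells and
    ``(p, q)`` with p < q for between-comparison cells to one of
    ``low``/``likely_concerning``/``undefined``.  The network verdict
    rests on the between-comparison cells only: likely intransitive as
    soon as one defined D^B is likely concerning, undetermined when no
    D^B is defined.
    """

    per_cell: dict[tuple[str, str], str]
    network_verdict: str
    threshold_used: float
    quantile_used: str | None = None

    def cells(self, within: bool) -> dict[tuple[str, str], str]:
        return {k: v for k, v in self.per_cell.items() if (k[0] == k[1]) == within}


def classify(
    dm: DissimilarityMatrix,
    threshold: float,
    quantile: str | None = None,
) -> TransitivityVerdict:
    """Label every D cell against a threshold and derive the network verdict.

    Strictly below the threshold counts as low; a value equal to the
    threshold is already likely concerning.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    per_cell: dict[tuple[str, str], str] = {}
    concerning_between = 0
    defined_between = 0
    for i, p in enumerate(dm.comparisons):
        for j in range(i, dm.p):
            q = dm.comparisons[j]
            v = dm.values[i, j]
            if np.isnan(v):
                label = UNDEFINED
            elif v < threshold:
                label = LOW
            else:
                label = LIKELY_CONCERNING
            per_cell[(p, q)] = label
            if i != j and label != UNDEFINED:
                defined_between += 1
                concerning_between += label == LIKELY_CONCERNING
    if defined_between == 0:
        verdict = UNDETERMINED
    elif concerning_between > 0:
        verdict = LIKELY_INTRANSITIVE
    else:
        verdict = LIKELY_TRANSITIVE
    return TransitivityVerdict(
        per_cell=per_cell,
        network_verdict=verdict,
        threshold_used=threshold,
        quantile_used=quantile,
    )


def proportion_summary(
    verdicts: Sequence[TransitivityVerdict],
    groups: Sequence[Mapping[str, object]] | None = None,
) -> pd.DataFrame:
    """Proportions of low / likely-concerning cells and intransitive networks.

    ``groups`` optionally supplies one mapping of design descriptors per
    verdict; rows are emitted per distinct group (plus an overall row
    when no groups are given).  Percentages of within- and
    between-comparison cells are computed over defined cells only.
    """
    if not verdicts:
        raise ValueError("no verdicts supplied")
    if groups is not None and len(groups) != len(verdicts):
        raise ValueError("groups must align with verdicts")
    keys = sorted({k for g in groups for k in g}) if groups else []
    records = []
    for v, g in zip(verdicts, groups or [{}] * len(verdicts)):
        rec = {k: g.get(k) for k in keys}
        for within in (True, False):
            cells = [lab for lab in v.cells(within).values() if lab != UNDEFINED]
            prefix = "within" if within else "between"
            rec[f"n_{prefix}_defined"] = len(cells)
            rec[f"n_{prefix}_low"] = sum(lab == LOW for lab in cells)
        rec["intransitive"] = v.network_verdict == LIKELY_INTRANSITIVE
        rec["determined"] = v.network_verdict != UNDETERMINED
        records.append(rec)
    df = pd.DataFrame(records)
    grouped = df.groupby(keys, dropna=False) if keys else [((), df)]
    rows = []
    for name, sub in grouped:
        row = dict(zip(keys, name if isinstance(name, tuple) else (name,)))
        row["n_datasets"] = len(sub)
        for prefix in ("within", "between"):
            n = sub[f"n_{prefix}_defined"].sum()
            low = sub[f"n_{prefix}_low"].sum()
            row[f"pct_{prefix}_low"] = 100.0 * low / n if n else np.nan
            row[f"pct_{prefix}_concerning"] = 100.0 * (n - low) / n if n else np.nan
        det = sub["determined"].sum()
        row["pct_datasets_intransitive"] = (
            100.0 * sub["intransitive"].sum() / det if det else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
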