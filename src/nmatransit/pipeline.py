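"""Batch orchestration: run the whole assessment over many datasets.

For each dataset: preprocess (drop characteristics missing in almost
all studies of some comparison, apply the four-characteristics
eligibility rule), build the Gower and comparison-level dissimilarity
matrices, classify against the design-specific thresholds at the
requested quantiles, run the multiple-statistical-test comparator, and
cross-classify the two approaches' conclusions.  Per-dataset failures
are quarantined with their error message, never aborting the batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dataset import TransitivityDataset, drop_unusable_characteristics
from .gower import build_gower_matrix, dissimilarity_matrix_from_gower
from .stattests import compare_conclusions, run_test_suite
from .thresholds import (
    LIKELY_INTRANSITIVE,
    QUANTILES,
    ThresholdTable,
    TransitivityVerdict,
    classify,
)

__all__ = ["StudyReport", "run_study", "export_report"]


@dataclass
class StudyReport:
    """Per-dataset rows plus pooled summaries of a batch run.

    ``db_values`` is the long-form table of every defined
    between-comparison dissimilarity with its design descriptors; the
    pooled summaries are re-aggregations of it.
    """

    per_dataset: pd.DataFrame
    pooled: pd.DataFrame
    proportions: pd.DataFrame
    concordance: pd.DataFrame
    db_values: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)
    config: dict = field(default_factory=dict)


_GROUP_KEYS = ["outcome_type", "comparator_type"]


def run_study(
    datasets: Iterable[TransitivityDataset],
    alpha: float = 0.05,
    quantiles: Sequence[str] = QUANTILES,
    thresholds: ThresholdTable | None = None,
    equal_var: bool = True,
) -> StudyReport:
    """Assess every dataset and pool the results by design setting."""
    thresholds = thresholds or ThresholdTable.default()
    rows: list[dict] = []
    db_rows: list[dict] = []
    failures: list[tuple[str, str]] = []

    for ds in datasets:
        try:
            rows_ds, db_ds = _assess_one(ds, alpha, quantiles, thresholds, equal_var)
            rows.append(rows_ds)
            db_rows.extend(db_ds)
        except Exception as exc:  # quarantine, keep the batch going
            failures.append((ds.dataset_id, f"{type(exc).__name__}: {exc}"))

    per_dataset = pd.DataFrame(rows)
    db_values = pd.DataFrame(
        db_rows, columns=_GROUP_KEYS + ["dataset_id", "comparison_pair", "db"]
    )

    pooled = _pool_db(db_values)
    proportions = _verdict_rates(per_dataset, quantiles)
    concordance = _concordance_counts(per_dataset, quantiles)

    return StudyReport(
        per_dataset=per_dataset,
        pooled=pooled,
        proportions=proportions,
        concordance=concordance,
        db_values=db_values,
        failures=failures,
        config={
            "alpha": alpha,
            "quantiles": list(quantiles),
            "equal_var": equal_var,
            "version": __version__,
        },
    )


def _assess_one(ds, alpha, quantiles, thresholds, equal_var):
    processed, report = drop_unusable_characteristics(ds)
    row = {
        "dataset_id": ds.dataset_id,
        "outcome_type": ds.outcome_type,
        "comparator_type": ds.comparator_type,
        "average_study_size": ds.average_study_size,
        "n_studies": ds.n_studies,
        "n_characteristics": report.n_characteristics_remaining,
        "n_dropped_characteristics": len(report.dropped_characteristics),
        "eligible": report.eligible,
    }
    db_rows: list[dict] = []
    if not report.eligible:
        return row, db_rows

    gm = build_gower_matrix(processed)
    dm = dissimilarity_matrix_from_gower(gm, processed.comparisons)
    dw = np.diag(dm.values)
    iu = np.triu_indices(dm.p, k=1)
    db = dm.values[iu]
    row.update(
        median_gd=float(np.nanmedian(gm.pair_values())) if gm.n > 1 else np.nan,
        median_dw=float(np.nanmedian(dw)) if np.any(~np.isnan(dw)) else np.nan,
        median_db=float(np.nanmedian(db)) if np.any(~np.isnan(db)) else np.nan,
    )
    for i, j in zip(*iu):
        if not np.isnan(dm.values[i, j]):
            db_rows.append(
                {
                    "outcome_type": ds.outcome_type,
                    "comparator_type": ds.comparator_type,
                    "dataset_id": ds.dataset_id,
                    "comparison_pair": f"{dm.comparisons[i]} | {dm.comparisons[j]}",
                    "db": float(dm.values[i, j]),
                }
            )

    suite = run_test_suite(processed, alpha=alpha, equal_var=equal_var)
    row.update(test_verdict=suite.verdict, m_tests=suite.m_tests, fwer=suite.fwer)

    for quantile in quantiles:
        threshold = thresholds.lookup(
            ds.outcome_type, ds.comparator_type, ds.average_study_size, quantile
        )
        verdict = classify(dm, threshold, quantile=quantile)
        row[f"threshold_{quantile}"] = threshold
        row[f"verdict_{quantile}"] = verdict.network_verdict
        row[f"concordance_{quantile}"] = compare_conclusions(verdict, suite)
    return row, db_rows


def _pool_db(db_values: pd.DataFrame) -> pd.DataFrame:
    if db_values.empty:
        return pd.DataFrame(
            columns=_GROUP_KEYS + ["median", "q1", "q3", "min", "max", "n_pairs"]
        )
    rows = []
    for keys, sub in db_values.groupby(_GROUP_KEYS, dropna=False):
        v = sub["db"].to_numpy()
        rows.append(
            dict(
                zip(_GROUP_KEYS, keys),
                median=float(np.median(v)),
                q1=float(np.quantile(v, 0.25)),
                q3=float(np.quantile(v, 0.75)),
                min=float(v.min()),
                max=float(v.max()),
                n_pairs=len(v),
            )
        )
    return pd.DataFrame(rows)


def _verdict_rates(per_dataset: pd.DataFrame, quantiles) -> pd.DataFrame:
    rows = []
    eligible = (
        per_dataset[per_dataset["eligible"]]
        if "eligible" in per_dataset
        else per_dataset.iloc[0:0]
    )
    if eligible.empty:
        return pd.DataFrame(
            columns=_GROUP_KEYS + ["quantile", "n_datasets", "pct_intransitive"]
        )
    for keys, sub in eligible.groupby(_GROUP_KEYS, dropna=False):
        for quantile in quantiles:
            col = sub[f"verdict_{quantile}"]
            determined = col != "undetermined"
            n_det = int(determined.sum())
            rows.append(
                dict(
                    zip(_GROUP_KEYS, keys),
                    quantile=quantile,
                    n_datasets=len(sub),
                    pct_intransitive=(
                        100.0 * (col == LIKELY_INTRANSITIVE).sum() / n_det
                        if n_det
                        else np.nan
                    ),
                )
            )
    return pd.DataFrame(rows)


def _concordance_counts(per_dataset: pd.DataFrame, quantiles) -> pd.DataFrame:
    rows = []
    for quantile in quantiles:
        col = f"concordance_{quantile}"
        if col not in per_dataset:
            continue
        counts = per_dataset[col].value_counts(dropna=True)
        for cell, n in counts.items():
            rows.append({"quantile": quantile, "cell": cell, "n_datasets": int(n)})
    return pd.DataFrame(rows, columns=["quantile", "cell", "n_datasets"])


def export_report(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """Write the report tables and a run manifest; deterministic output."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (
        ("per_dataset", report.per_dataset),
        ("pooled_by_design", report.pooled),
        ("proportions", report.proportions),
        ("concordance", report.concordance),
        ("db_values", report.db_values),
    ):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, na_rep="NA")
        written.append(path)
    manifest = {
        "config": report.config,
        "n_datasets": int(len(report.per_dataset)),
        "failures": report.failures,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
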