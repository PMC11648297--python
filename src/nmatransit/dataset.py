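"""Data model for transitivity-evaluation datasets.

A dataset holds one row per study of a connected treatment network, a
treatment-comparison label per study, and a set of study-level aggregate
characteristics (candidate effect modifiers) of mixed type: numeric,
binary, or categorical.  Missing cells are allowed and are handled by
pairwise-like deletion downstream.

The on-disk contract is a delimited text file with a header row
``study_id, comparison, <characteristic columns>`` plus an optional YAML
sidecar carrying design metadata (outcome type, treatment-comparator
type, average study size) and an explicit characteristic-type map.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CharacteristicSpec",
    "TransitivityDataset",
    "PreprocessReport",
    "load_dataset",
    "write_dataset",
    "drop_unusable_characteristics",
    "summarize_dataset",
    "normalize_comparison",
]

NUMERIC = "numeric"
BINARY = "binary"
CATEGORICAL = "categorical"
KINDS = (NUMERIC, BINARY, CATEGORICAL)

OUTCOME_TYPES = ("objective", "semi-objective", "subjective")
COMPARATOR_TYPES = ("pharm_vs_placebo", "pharm_vs_pharm", "nonpharm_vs_any")

RESERVED_COLUMNS = ("study_id", "comparison")

_VS_RE = re.compile(r"\s+vs\.?\s+", flags=re.IGNORECASE)


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() in ("", "NA"):
        return True
    return value is pd.NA


def normalize_comparison(label: str) -> str:
    """Normalise a treatment-comparison label to ``"A vs B"`` form.

    Comparisons are undirected, so the two treatment names are sorted
    lexicographically: ``"B vs A"`` and ``"A vs B"`` denote the same
    comparison.
    """
    if not isinstance(label, str):
        raise ValueError(f"comparison label must be text, got {label!r}")
    parts = _VS_RE.split(label.strip())
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValueError(
            f"comparison label {label!r} is not of the form 'T1 vs T2'"
        )
    a, b = sorted(p.strip() for p in parts)
    if a == b:
        raise ValueError(
            f"comparison label {label!r} does not name two distinct treatments"
        )
    return f"{a} vs {b}"


@dataclass(frozen=True)
class CharacteristicSpec:
    """Type and scaling information for one study-level characteristic.

    For numeric characteristics ``range_`` is the observed range R used
    to normalise absolute differences; for binary/categorical ones
    ``levels`` lists the observed category labels.
    """

    name: str
    kind: str
    range_: float | None = None
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown characteristic kind {self.kind!r}")
        if self.kind == NUMERIC:
            if self.range_ is None or self.range_ < 0:
                raise ValueError(
                    f"numeric characteristic {self.name!r} needs a non-negative range"
                )
        else:
            if self.range_ is not None:
                raise ValueError(
                    f"non-numeric characteristic {self.name!r} cannot carry a range"
                )
            if self.kind == BINARY and self.levels is not None and len(self.levels) > 2:
                raise ValueError(
                    f"binary characteristic {self.name!r} has >2 levels: {self.levels}"
                )


@dataclass
class TransitivityDataset:
    """Studies-by-characteristics table for one treatment network.

    ``data`` carries the columns ``study_id``, ``comparison`` (labels
    normalised to lexicographic ``"A vs B"`` order) and one column per
    characteristic; numeric columns are float with NaN for missing,
    other columns are strings with NaN for missing.
    """

    dataset_id: str
    data: pd.DataFrame
    characteristics: list[CharacteristicSpec]
    outcome_type: str | None = None
    comparator_type: str | None = None
    average_study_size: float | None = None

    # ------------------------------------------------------------------
    @property
    def n_studies(self) -> int:
        return len(self.data)

    @property
    def characteristic_names(self) -> list[str]:
        return [s.name for s in self.characteristics]

    @property
    def comparisons(self) -> np.ndarray:
        """Per-study comparison labels, aligned with the study rows."""
        return self.data["comparison"].to_numpy()

    @property
    def observed_comparisons(self) -> list[str]:
        """Distinct comparison labels in lexicographic order."""
        return sorted(self.data["comparison"].unique())

    @property
    def treatments(self) -> list[str]:
        seen: set[str] = set()
        for label in self.data["comparison"]:
            a, b = label.split(" vs ")
            seen.update((a, b))
        return sorted(seen)

    def comparison_sizes(self) -> dict[str, int]:
        """Number of studies k informing each observed comparison."""
        return self.data["comparison"].value_counts().to_dict()

    def spec(self, name: str) -> CharacteristicSpec:
        for s in self.characteristics:
            if s.name == name:
                return s
        raise KeyError(f"unknown characteristic {name!r}")

    def study_records(self) -> list[dict]:
        """Per-study characteristic mappings (missing as NaN)."""
        return self.data[self.characteristic_names].to_dict("records")

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dataset_id: str = "dataset",
        outcome_type: str | None = None,
        comparator_type: str | None = None,
        average_study_size: float | None = None,
        type_map: Mapping[str, str] | None = None,
    ) -> "TransitivityDataset":
        """Validate a raw table, infer characteristic types, compute ranges.

        Kind inference: numeric if every non-missing cell parses as a
        number; binary if exactly two distinct non-numeric values; else
        categorical.  ``type_map`` overrides inference per column.
        """
        for col in RESERVED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        char_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
        if not char_cols:
            raise ValueError("no characteristic columns found")
        if len(set(char_cols)) != len(char_cols):
            raise ValueError("characteristic names are not unique")
        if len(df) < 2:
            raise ValueError(f"dataset needs at least 2 studies, got {len(df)}")
        if outcome_type is not None and outcome_type not in OUTCOME_TYPES:
            raise ValueError(f"unknown outcome_type {outcome_type!r}")
        if comparator_type is not None and comparator_type not in COMPARATOR_TYPES:
            raise ValueError(f"unknown comparator_type {comparator_type!r}")
        if average_study_size is not None and not average_study_size > 0:
            raise ValueError("average_study_size must be positive")

        out = pd.DataFrame(index=range(len(df)))
        out["study_id"] = df["study_id"].astype(str).to_numpy()
        out["comparison"] = [
            normalize_comparison(c) for c in df["comparison"].astype(str)
        ]

        specs: list[CharacteristicSpec] = []
        for col in char_cols:
            raw = df[col].tolist()
            observed = [v for v in raw if not _is_missing(v)]
            if not observed:
                raise ValueError(f"characteristic column {col!r} has no observed values")
            kind = type_map.get(col) if type_map else None
            if kind is None:
                kind = _infer_kind(observed)
            elif kind not in KINDS:
                raise ValueError(f"type map entry for {col!r} is invalid: {kind!r}")
            if kind == NUMERIC:
                values = pd.to_numeric(
                    pd.Series([np.nan if _is_missing(v) else v for v in raw]),
                    errors="raise",
                ).astype(float)
                out[col] = values.to_numpy()
                obs = values.dropna()
                specs.append(
                    CharacteristicSpec(col, NUMERIC, range_=float(obs.max() - obs.min()))
                )
            else:
                values = [np.nan if _is_missing(v) else _as_label(v) for v in raw]
                out[col] = pd.Series(values, dtype=object).to_numpy()
                levels = tuple(sorted({v for v in values if isinstance(v, str)}))
                if kind == BINARY and len(levels) > 2:
                    raise ValueError(
                        f"characteristic {col!r} declared binary but has levels {levels}"
                    )
                specs.append(CharacteristicSpec(col, kind, levels=levels))
        return cls(
            dataset_id=dataset_id,
            data=out,
            characteristics=specs,
            outcome_type=outcome_type,
            comparator_type=comparator_type,
            average_study_size=average_study_size,
        )


def _as_label(value: object) -> str:
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value).strip()


def _infer_kind(observed: Sequence[object]) -> str:
    try:
        for v in observed:
            float(v)  # type: ignore[arg-type]
        return NUMERIC
    except (TypeError, ValueError):
        pass
    distinct = {_as_label(v) for v in observed}
    return BINARY if len(distinct) == 2 else CATEGORICAL


# ----------------------------------------------------------------------
# I/O


def load_dataset(
    path: str | Path,
    config: str | Path | Mapping | None = None,
    dataset_id: str | None = None,
    **metadata,
) -> TransitivityDataset:
    """Read a dataset from delimited text (CSV/TSV by extension).

    ``config`` may be a mapping or a path to a YAML sidecar holding
    ``outcome_type``, ``comparator_type``, ``average_study_size`` and an
    optional ``type_map``; when omitted, a sidecar named ``<stem>.yaml``
    next to the data file is picked up automatically.  Keyword metadata
    overrides the sidecar.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False)
    df = df.replace({"": np.nan, "NA": np.nan})

    cfg: dict = {}
    if config is None:
        sidecar = path.with_suffix(".yaml")
        if sidecar.exists():
            cfg = yaml.safe_load(sidecar.read_text()) or {}
    elif isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text()) or {}
    else:
        cfg = dict(config)
    cfg.update({k: v for k, v in metadata.items() if v is not None})

    return TransitivityDataset.from_dataframe(
        df,
        dataset_id=dataset_id or cfg.get("dataset_id", path.stem),
        outcome_type=cfg.get("outcome_type"),
        comparator_type=cfg.get("comparator_type"),
        average_study_size=cfg.get("average_study_size"),
        type_map=cfg.get("type_map"),
    )


def write_dataset(ds: TransitivityDataset, path: str | Path) -> None:
    """Write the data table plus a YAML sidecar; round-trips exactly."""
    path = Path(path)
    out = ds.data.copy()
    for s in ds.characteristics:
        if s.kind == NUMERIC:
            out[s.name] = out[s.name].map(
                lambda v: "" if _is_missing(v) else repr(float(v))
            )
        else:
            out[s.name] = out[s.name].map(lambda v: "" if _is_missing(v) else v)
    out.to_csv(path, index=False)
    sidecar = {
        "dataset_id": ds.dataset_id,
        "outcome_type": ds.outcome_type,
        "comparator_type": ds.comparator_type,
        "average_study_size": ds.average_study_size,
        "type_map": {s.name: s.kind for s in ds.characteristics},
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


# ----------------------------------------------------------------------
# Preprocessing


@dataclass
class PreprocessReport:
    dropped_characteristics: list[tuple[str, str]] = field(default_factory=list)
    eligible: bool = True
    n_characteristics_remaining: int = 0


def drop_unusable_characteristics(
    ds: TransitivityDataset,
    min_observed_per_multistudy_comparison: int = 2,
) -> tuple[TransitivityDataset, PreprocessReport]:
    """Drop characteristics missing in almost all studies of some comparison.

    A characteristic is unusable when, in at least one comparison
    informed by two or more studies, it is observed in fewer than
    ``min_observed_per_multistudy_comparison`` studies of that
    comparison: it can then never contribute to that comparison's
    within-comparison dissimilarity.  Datasets retaining fewer than four
    characteristics are flagged ineligible for the dissimilarity
    analysis.
    """
    sizes = ds.comparison_sizes()
    multi = [p for p, k in sizes.items() if k >= 2]
    dropped: list[tuple[str, str]] = []
    keep: list[CharacteristicSpec] = []
    for spec in ds.characteristics:
        col = ds.data[spec.name]
        reason = None
        for p in multi:
            observed = col[ds.data["comparison"] == p].notna().sum()
            if observed < min_observed_per_multistudy_comparison:
                reason = (
                    f"observed in {observed} studies of multi-study comparison {p!r}"
                )
                break
        if reason is None:
            keep.append(spec)
        else:
            dropped.append((spec.name, reason))

    cols = list(RESERVED_COLUMNS) + [s.name for s in keep]
    survivors = [_recompute_range(ds.data, s) for s in keep]
    new_ds = replace(ds, data=ds.data[cols].copy(), characteristics=survivors)
    report = PreprocessReport(
        dropped_characteristics=dropped,
        eligible=len(survivors) >= 4,
        n_characteristics_remaining=len(survivors),
    )
    return new_ds, report


def _recompute_range(data: pd.DataFrame, spec: CharacteristicSpec) -> CharacteristicSpec:
    if spec.kind != NUMERIC:
        return spec
    obs = data[spec.name].dropna()
    return replace(spec, range_=float(obs.max() - obs.min()))


# ----------------------------------------------------------------------
# Description


def summarize_dataset(ds: TransitivityDataset) -> dict:
    """Descriptive summary: network geometry, characteristic mix, missingness."""
    sizes = ds.comparison_sizes()
    n_treat = len(ds.treatments)
    possible = n_treat * (n_treat - 1) // 2
    n_comp = len(sizes)
    chars = ds.characteristic_names
    cells = ds.data[chars]
    n_cells = cells.size
    n_missing = int(cells.isna().sum().sum())
    n_numeric = sum(1 for s in ds.characteristics if s.kind == NUMERIC)
    return {
        "dataset_id": ds.dataset_id,
        "n_studies": ds.n_studies,
        "n_treatments": n_treat,
        "n_comparisons": n_comp,
        "pct_possible_comparisons": 100.0 * n_comp / possible,
        "pct_single_study_comparisons": 100.0
        * sum(1 for k in sizes.values() if k == 1)
        / n_comp,
        "n_characteristics": len(chars),
        "pct_numeric": 100.0 * n_numeric / len(chars),
        "pct_non_numeric": 100.0 * (len(chars) - n_numeric) / len(chars),
        "pct_missing_overall": 100.0 * n_missing / n_cells,
        "pct_missing_per_characteristic": {
            c: 100.0 * float(cells[c].isna().mean()) for c in chars
        },
    }
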