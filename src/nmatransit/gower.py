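"""Gower dissimilarities and within/between-comparison aggregation.

For a pair of studies (x, y) the Gower dissimilarity (GD) averages
per-characteristic dissimilarities d_i with availability weights:
numeric characteristics contribute |x_i - y_i| / R_i (R_i the observed
range), binary/categorical ones a 0/1 mismatch indicator, and a
characteristic is weighted out of the pair when either value is
missing.  GD lies in [0, 1]; it is undefined when no characteristic is
jointly observed.

Study-pair GDs are then aggregated per treatment comparison with the
root mean square (RMS): the within-comparison dissimilarity D^W of a
comparison p pools its C(k, 2) study pairs; the between-comparison
dissimilarity D^B of two comparisons p, q pools all k_p * k_q cross
pairs.  The RMS equals a population standard deviation around zero, so
D gauges the spread of dissimilarities away from complete similarity.
Undefined pairs are excluded with the denominator reduced accordingly
(pairwise-like deletion); an aggregate over zero defined pairs is
itself undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import (
    NUMERIC,
    CharacteristicSpec,
    TransitivityDataset,
    _is_missing,
)

__all__ = [
    "GowerMatrix",
    "DissimilarityMatrix",
    "pairwise_gower",
    "build_gower_matrix",
    "rms_aggregate",
    "within_comparison_dissimilarity",
    "between_comparison_dissimilarity",
    "dissimilarity_matrix_from_gower",
    "build_dissimilarity_matrix",
]


@dataclass
class GowerMatrix:
    """Symmetric N x N study-pair Gower dissimilarities.

    ``values`` holds NaN for undefined pairs (no jointly observed
    characteristic); the diagonal is 0.  ``weight_counts[i, j]`` is the
    number of characteristics observed in both studies of the pair.
    """

    values: np.ndarray
    weight_counts: np.ndarray
    study_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.study_ids or [str(i) for i in range(self.n)]
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, na_rep="NA")

    def pair_values(self) -> np.ndarray:
        """Upper-triangle off-diagonal GDs (defined and undefined)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class DissimilarityMatrix:
    """P x P comparison-level dissimilarity matrix.

    Diagonal cells are within-comparison dissimilarities D^W (NaN for
    single-study comparisons), off-diagonal cells between-comparison
    dissimilarities D^B.
    """

    comparisons: list[str]
    values: np.ndarray

    @property
    def p(self) -> int:
        return len(self.comparisons)

    def cell(self, p: str, q: str | None = None) -> float:
        i = self.comparisons.index(p)
        j = i if q is None else self.comparisons.index(q)
        return float(self.values[i, j])

    def within(self) -> dict[str, float]:
        return {p: float(self.values[i, i]) for i, p in enumerate(self.comparisons)}

    def between(self) -> dict[tuple[str, str], float]:
        out = {}
        for i in range(self.p):
            for j in range(i + 1, self.p):
                out[(self.comparisons[i], self.comparisons[j])] = float(
                    self.values[i, j]
                )
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.comparisons, columns=self.comparisons)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, na_rep="NA")


# ----------------------------------------------------------------------


def pairwise_gower(
    x: Mapping[str, object],
    y: Mapping[str, object],
    specs: Sequence[CharacteristicSpec],
) -> tuple[float, int]:
    """Gower dissimilarity of one study pair.

    Returns ``(gd, weight_count)``; ``gd`` is NaN when no characteristic
    is observed in both studies.  A numeric characteristic with zero
    observed range contributes d = 0 with full weight: identical values
    mean zero dissimilarity, and silently excluding the characteristic
    would change the weights of the remaining ones.
    """
    total = 0.0
    weight = 0
    for spec in specs:
        xv, yv = x.get(spec.name), y.get(spec.name)
        if _is_missing(xv) or _is_missing(yv):
            continue
        if spec.kind == NUMERIC:
            if spec.range_ == 0:
                d = 0.0
            else:
                d = abs(float(xv) - float(yv)) / spec.range_  # type: ignore[arg-type]
        else:
            d = 0.0 if xv == yv else 1.0
        total += d
        weight += 1
    if weight == 0:
        return float("nan"), 0
    return total / weight, weight


def build_gower_matrix(ds: TransitivityDataset) -> GowerMatrix:
    """All-pairs Gower dissimilarity matrix for a dataset.

    Vectorised per characteristic; symmetric by construction.
    """
    n = ds.n_studies
    num = np.zeros((n, n))
    den = np.zeros((n, n), dtype=int)
    for spec in ds.characteristics:
        col = ds.data[spec.name]
        if spec.kind == NUMERIC:
            v = col.to_numpy(dtype=float)
            obs = ~np.isnan(v)
            if spec.range_ == 0:
                d = np.zeros((n, n))
            else:
                d = np.abs(v[:, None] - v[None, :]) / spec.range_
        else:
            v = col.to_numpy(dtype=object)
            obs = col.notna().to_numpy()
            d = (v[:, None] != v[None, :]).astype(float)
        both = np.logical_and(obs[:, None], obs[None, :])
        num += np.where(both, np.nan_to_num(d), 0.0)
        den += both
    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    return GowerMatrix(
        values=values,
        weight_counts=den,
        study_ids=list(ds.data["study_id"]),
    )


def rms_aggregate(values: Sequence[float] | np.ndarray) -> float:
    """Root mean square of the defined (non-NaN) entries.

    Coincides with a population standard deviation around zero.
    Returns NaN when no defined entries remain.
    """
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(arr**2)))


def _indices_of(comparisons: np.ndarray, p: str) -> np.ndarray:
    idx = np.flatnonzero(comparisons == p)
    if idx.size == 0:
        raise ValueError(f"unknown comparison label {p!r}")
    return idx


def within_comparison_dissimilarity(
    gm: GowerMatrix, comparisons: Sequence[str], p: str
) -> float:
    """D^W: RMS of the C(k, 2) study-pair GDs within comparison p.

    NaN for single-study comparisons (dissimilarity does not apply) or
    when all within pairs are undefined.
    """
    comparisons = np.asarray(comparisons)
    idx = _indices_of(comparisons, p)
    if idx.size < 2:
        return float("nan")
    block = gm.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return rms_aggregate(block[iu])


def between_comparison_dissimilarity(
    gm: GowerMatrix, comparisons: Sequence[str], p: str, q: str
) -> float:
    """D^B: RMS of all k_p * k_q cross-pair GDs between comparisons p, q."""
    if p == q:
        raise ValueError(
            "between-comparison dissimilarity needs two distinct comparisons; "
            "use within_comparison_dissimilarity for p == q"
        )
    comparisons = np.asarray(comparisons)
    ip = _indices_of(comparisons, p)
    iq = _indices_of(comparisons, q)
    return rms_aggregate(gm.values[np.ix_(ip, iq)])


def dissimilarity_matrix_from_gower(
    gm: GowerMatrix, comparisons: Sequence[str]
) -> DissimilarityMatrix:
    """Assemble the P x P dissimilarity matrix from a GD matrix.

    Comparisons are ordered lexicographically; D^W on the diagonal and
    D^B off-diagonal.
    """
    comparisons = np.asarray(comparisons)
    labels = sorted(set(comparisons.tolist()))
    p = len(labels)
    values = np.full((p, p), np.nan)
    for i, a in enumerate(labels):
        values[i, i] = within_comparison_dissimilarity(gm, comparisons, a)
        for j in range(i + 1, p):
            d = between_comparison_dissimilarity(gm, comparisons, a, labels[j])
            values[i, j] = values[j, i] = d
    return DissimilarityMatrix(comparisons=labels, values=values)


def build_dissimilarity_matrix(ds: TransitivityDataset) -> DissimilarityMatrix:
    """Dataset -> GD matrix -> comparison-level dissimilarity matrix."""
    gm = build_gower_matrix(ds)
    return dissimilarity_matrix_from_gower(gm, ds.comparisons)
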