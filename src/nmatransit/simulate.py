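"""Synthetic treatment-network datasets with controllable intransitivity.

The generator emulates the structure of empirically extracted
transitivity databases: a connected network of treatments, a mix of
numeric/binary/categorical study-level characteristics, a sizeable
share of single-study comparisons, and missing cells scattered
completely at random.  Defaults follow the typical geometry of such
databases — seven treatments, about 42% of the possible comparisons
observed, about 44% of comparisons informed by a single study, a dozen
characteristics of which roughly half are numeric, and about 7%
missing cells.

Intransitivity is injected at the comparison level, where the
transitivity assumption lives: each observed comparison p receives a
unit direction vector u_p, and the ``imbalance`` parameter shifts the
comparison-specific distribution of every characteristic along it —
numeric characteristics by ``imbalance * u_p[i]`` standard deviations
around a common unit-variance Gaussian base, binary/categorical level
probabilities through a softmax tilt of the logits.  ``imbalance = 0``
makes characteristics exchangeable across comparisons (a transitive
network by construction); large values separate the comparisons'
effect-modifier distributions (intransitive by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .dataset import TransitivityDataset

__all__ = ["SyntheticConfig", "generate_network", "generate_labelled_batch"]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for one synthetic network dataset.

    ``density`` is the fraction of the T(T-1)/2 possible comparisons
    that are observed (at least T-1 are needed for connectivity);
    ``prop_single_study`` the probability that an observed comparison is
    informed by a single study, the rest drawing study counts uniformly
    from [min_studies, max_studies]; ``imbalance`` the standardised
    comparison-level distribution shift described in the module
    docstring.
    """

    n_treatments: int = 7
    density: float = 0.42
    min_studies: int = 2
    max_studies: int = 5
    prop_single_study: float = 0.44
    n_numeric: int = 7
    n_binary: int = 3
    n_categorical: int = 2
    categorical_levels: int = 3
    imbalance: float = 0.0
    missing_rate: float = 0.071
    outcome_type: str = "subjective"
    comparator_type: str = "pharm_vs_placebo"
    average_study_size: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatments < 3:
            raise ValueError("need at least 3 treatments for a network")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.n_numeric + self.n_binary + self.n_categorical < 1:
            raise ValueError("need at least one characteristic")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.min_studies < 2 or self.max_studies < self.min_studies:
            raise ValueError("need 2 <= min_studies <= max_studies")
        possible = self.n_treatments * (self.n_treatments - 1) // 2
        if round(self.density * possible) < self.n_treatments - 1:
            raise ValueError(
                f"density {self.density} cannot connect {self.n_treatments} treatments"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def _sample_edges(cfg: SyntheticConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random spanning tree plus extra edges up to the target density."""
    t = cfg.n_treatments
    order = rng.permutation(t)
    edges = set()
    for i in range(1, t):
        j = order[rng.integers(0, i)]
        edges.add(tuple(sorted((int(order[i]), int(j)))))
    n_edges = max(int(round(cfg.density * t * (t - 1) / 2)), t - 1)
    remaining = [e for e in combinations(range(t), 2) if e not in edges]
    extra = n_edges - len(edges)
    if extra > 0:
        idx = rng.choice(len(remaining), size=min(extra, len(remaining)), replace=False)
        edges.update(remaining[i] for i in idx)
    return sorted(edges)


def generate_network(cfg: SyntheticConfig) -> TransitivityDataset:
    """Draw one connected synthetic network dataset; reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    treatments = [f"T{i + 1}" for i in range(cfg.n_treatments)]
    edges = _sample_edges(cfg, rng)
    labels = sorted(f"{treatments[a]} vs {treatments[b]}" for a, b in edges)

    counts = [
        1
        if rng.random() < cfg.prop_single_study
        else int(rng.integers(cfg.min_studies, cfg.max_studies + 1))
        for _ in labels
    ]
    n_studies = sum(counts)
    n_chars = cfg.n_numeric + cfg.n_binary + cfg.n_categorical

    # one unit direction per comparison over the characteristic space
    directions = rng.standard_normal((len(labels), n_chars))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    comparison_col: list[str] = []
    for label, k in zip(labels, counts):
        comparison_col.extend([label] * k)
    comp_index = np.repeat(np.arange(len(labels)), counts)

    columns: dict[str, list] = {
        "study_id": [f"s{i + 1:03d}" for i in range(n_studies)],
        "comparison": comparison_col,
    }
    type_map: dict[str, str] = {}
    j = 0
    for i in range(cfg.n_numeric):
        shift = cfg.imbalance * directions[comp_index, j]
        columns[f"num{i + 1}"] = (shift + rng.standard_normal(n_studies)).tolist()
        type_map[f"num{i + 1}"] = "numeric"
        j += 1
    for i in range(cfg.n_binary):
        logit = cfg.imbalance * directions[comp_index, j]
        p = 1.0 / (1.0 + np.exp(-logit))
        draws = rng.random(n_studies) < p
        columns[f"bin{i + 1}"] = np.where(draws, "yes", "no").tolist()
        type_map[f"bin{i + 1}"] = "binary"
        j += 1
    contrast = np.linspace(-1.0, 1.0, cfg.categorical_levels)
    for i in range(cfg.n_categorical):
        logits = cfg.imbalance * directions[comp_index, j][:, None] * contrast[None, :]
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n_studies)
        level_idx = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
        columns[f"cat{i + 1}"] = [f"L{k + 1}" for k in level_idx]
        type_map[f"cat{i + 1}"] = "categorical"
        j += 1

    df = pd.DataFrame(columns)
    char_names = list(type_map)
    if cfg.missing_rate > 0:
        mask = rng.random((n_studies, n_chars)) < cfg.missing_rate
        for c, name in enumerate(char_names):
            col_mask = mask[:, c]
            if col_mask.all():  # keep one observed cell so the column stays usable
                col_mask[rng.integers(0, n_studies)] = False
            df.loc[col_mask, name] = np.nan

    return TransitivityDataset.from_dataframe(
        df,
        dataset_id=f"synthetic-{cfg.seed}",
        outcome_type=cfg.outcome_type,
        comparator_type=cfg.comparator_type,
        average_study_size=cfg.average_study_size,
        type_map=type_map,
    )


def generate_labelled_batch(
    cfg_transitive: SyntheticConfig,
    cfg_intransitive: SyntheticConfig,
    n_each: int,
    master_seed: int | None = None,
) -> list[tuple[TransitivityDataset, str]]:
    """Batch of datasets with known generating labels.

    Per-dataset seeds are derived from ``master_seed`` (default: the
    transitive config's seed) by counter, so the batch is reproducible
    and labels live outside the dataset objects.
    """
    base = cfg_transitive.seed if master_seed is None else master_seed
    out: list[tuple[TransitivityDataset, str]] = []
    for i in range(n_each):
        for cfg, label in (
            (cfg_transitive, "transitive"),
            (cfg_intransitive, "intransitive"),
        ):
            offset = 2 * i + (label == "intransitive")
            child = replace(cfg, seed=(base * 100003 + offset) % _MAX_SEED)
            out.append((generate_network(child), label))
    return out
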