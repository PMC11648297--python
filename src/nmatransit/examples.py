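"""Canonical toy network used throughout the documentation and tests.

A fictional connected network of three treatments A, B, C informed by
six two-arm studies: two studies compare A with B, three compare A with
C, and one compares B with C (a single-study comparison, for which
within-comparison dissimilarity does not apply).  The pairwise Gower
dissimilarities over its four fully observed characteristics are fixed
reference values; the A-vs-B and A-vs-C studies come from completely
different settings, which is what drives the between-comparison
dissimilarity of 0.99 and the likely-intransitivity verdict under the
general-setting threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import TransitivityDataset
from .gower import GowerMatrix

__all__ = ["toy_network_gower", "toy_dataset"]

#: comparison label of each of the six studies, in row order
TOY_COMPARISONS = [
    "A vs B",
    "A vs B",
    "A vs C",
    "A vs C",
    "A vs C",
    "B vs C",
]

# canonical pairwise Gower dissimilarities, keyed by study-row pairs
_TOY_PAIRS = {
    (0, 1): 0.01,  # within A vs B
    (2, 3): 0.01,  # within A vs C
    (2, 4): 0.02,
    (3, 4): 0.01,
    (0, 2): 0.97,  # A vs B x A vs C
    (1, 2): 0.98,
    (0, 3): 0.99,
    (1, 3): 0.98,
    (0, 4): 0.99,
    (1, 4): 1.00,
    (2, 5): 0.67,  # A vs C x B vs C
    (3, 5): 0.68,
    (4, 5): 0.69,
    (0, 5): 0.30,  # A vs B x B vs C
    (1, 5): 0.31,
}


def toy_network_gower() -> tuple[GowerMatrix, list[str]]:
    """The six-study toy network's Gower matrix and comparison labels.

    All four characteristics are observed in every study, so every pair
    carries weight count 4.
    """
    n = len(TOY_COMPARISONS)
    values = np.zeros((n, n))
    for (i, j), d in _TOY_PAIRS.items():
        values[i, j] = values[j, i] = d
    gm = GowerMatrix(
        values=values,
        weight_counts=np.full((n, n), 4, dtype=int),
        study_ids=[f"study {i + 1}" for i in range(n)],
    )
    return gm, list(TOY_COMPARISONS)


def toy_dataset() -> TransitivityDataset:
    """A synthetic six-study table with the toy network's shape.

    Illustrative stand-in for the worked example's characteristic
    table: same network geometry (comparisons A-B, A-C and single-study
    B-C) and four fully observed mixed-type characteristics, with the
    A-B and A-C studies drawn from starkly different settings.  Its
    exact dissimilarity values are computed, not fixed; use
    :func:`toy_network_gower` for the canonical reference numbers.
    """
    df = pd.DataFrame(
        {
            "study_id": [f"study {i + 1}" for i in range(6)],
            "comparison": TOY_COMPARISONS,
            "mean_age": [34.0, 35.0, 71.0, 70.0, 72.0, 52.0],
            "pct_female": [48.0, 50.0, 81.0, 80.0, 82.0, 65.0],
            "inpatient": ["no", "no", "yes", "yes", "yes", "no"],
            "risk_of_bias": ["low", "low", "high", "high", "high", "moderate"],
        }
    )
    return TransitivityDataset.from_dataframe(
        df,
        dataset_id="toy-network",
        outcome_type="subjective",
        comparator_type="pharm_vs_placebo",
        average_study_size=100.0,
    )
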