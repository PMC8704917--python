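"""Mueller index of potential indirect influence via shared partners.

For plants i (target) and j (acting) sharing pollinators k:

    d_ij = sum_k (a_ik / R_i) * (a_jk / C_k)

i.e. the share of the target's visits made by partner k, weighted by how
much of partner k's activity is concentrated on the acting species.  Each
target row sums to 1, so d_ij is the fraction of i's interactions
"attributable" to j; the matrix is asymmetric (j can matter more to i than
i does to j).  The pollinator-level index is the same computation on the
transposed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .network import InteractionNetwork

Level = Literal["plants", "pollinators"]


@dataclass
class InfluenceMatrix:
    """Square influence matrix; rows are targets, columns acting species."""

    values: np.ndarray
    labels: list[str]
    level: Level

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def mueller_matrix(net: InteractionNetwork, level: Level = "plants") -> InfluenceMatrix:
    """Influence of every acting species on every target of the same level."""
    if level == "plants":
        A, labels = net.counts.astype(float), net.plant_labels
    elif level == "pollinators":
        A, labels = net.counts.T.astype(float), net.pollinator_labels
    else:
        raise ValueError(f"level must be 'plants' or 'pollinators', got {level!r}")
    R = A.sum(axis=1, keepdims=True)   # target totals
    C = A.sum(axis=0, keepdims=True)   # shared-partner totals
    M = (A / R) @ (A / C).T
    return InfluenceMatrix(values=M, labels=list(labels), level=level)


def influence_summary(M: InfluenceMatrix) -> pd.DataFrame:
    """Per acting species: column sum and mean over all same-level targets,
    sorted descending by sum.  Self-influence is included, and the mean
    divides by the total number of same-level species."""
    sums = M.values.sum(axis=0)
    n = len(M.labels)
    return (
        pd.DataFrame({"species": M.labels, "sum": sums, "mean": sums / n})
        .sort_values("sum", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
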