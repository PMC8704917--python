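"""Abundance-weighted null model for pollinator sharing with a focal plant.

The question: is a plant's pollinator composition more similar to the focal
plant (the mass-flowering crop) than expected if every plant simply sampled
pollinators in proportion to their community-wide abundance?  The null
redraws each plant's visitation events from the pollinator abundance
distribution (keeping the plant's event total fixed), recomputes Bray-Curtis
distances to the focal plant, and wraps the observed distance in the
null 95% percentile envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .composition import bray_curtis
from .network import InteractionNetwork
from .seeds import spawn_seeds

Classification = Literal[
    "more_similar_than_null", "within_null", "more_dissimilar_than_null"
]


@dataclass
class NullEnvelope:
    """Observed distance of one plant to the focal plant, with the null
    mean and central 95% interval from the resampling null."""

    plant: str
    observed: float
    null_mean: float
    null_lower: float
    null_upper: float
    classification: Classification


def simulate_null_network(net: InteractionNetwork, seed=None) -> np.ndarray:
    """One null count matrix: each plant's R_i events redrawn i.i.d. from
    the pollinator relative-abundance distribution p_k = C_k / F.

    Row totals are preserved exactly; column totals vary stochastically.
    Frequently observed pollinators are proportionally more likely to be
    drawn, which is the abundance-sampling hypothesis under test.
    """
    rng = np.random.default_rng(seed)
    p = net.col_totals / net.total
    null = np.empty_like(net.counts)
    for i, r_i in enumerate(net.row_totals):
        null[i] = rng.multinomial(int(r_i), p)
    return null


def null_sharing_envelope(
    net: InteractionNetwork,
    focal: str,
    n_rep: int = 1000,
    seed: int | None = None,
) -> list[NullEnvelope]:
    """Null envelopes of Bray-Curtis distance to the focal plant.

    Every replicate redraws the whole matrix (the focal row included) and
    recomputes each plant's distance to the focal plant's null row.  Per
    plant the replicate distribution yields the mean and the 2.5/97.5
    percentiles; the observed distance is classified by strict comparison
    with those bounds (ties count as within the null).
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    fi = net.plant_index(focal)
    observed = np.array(
        [bray_curtis(row, net.counts[fi]) for row in net.counts]
    )
    null_d = np.empty((n_rep, net.n_plants))
    for rep, rep_seed in enumerate(spawn_seeds(seed, n_rep, "sharing-null")):
        null = simulate_null_network(net, seed=rep_seed)
        focal_row = null[fi]
        for i in range(net.n_plants):
            if i == fi:
                null_d[rep, i] = 0.0
            else:
                null_d[rep, i] = bray_curtis(null[i], focal_row)
    lower = np.percentile(null_d, 2.5, axis=0)
    upper = np.percentile(null_d, 97.5, axis=0)
    mean = null_d.mean(axis=0)
    envelopes = []
    for i, plant in enumerate(net.plant_labels):
        if observed[i] < lower[i]:
            cls: Classification = "more_similar_than_null"
        elif observed[i] > upper[i]:
            cls = "more_dissimilar_than_null"
        else:
            cls = "within_null"
        envelopes.append(
            NullEnvelope(
                plant=plant,
                observed=float(observed[i]),
                null_mean=float(mean[i]),
                null_lower=float(lower[i]),
                null_upper=float(upper[i]),
                classification=cls,
            )
        )
    return envelopes


def envelopes_to_frame(envelopes: list[NullEnvelope]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plant": [e.plant for e in envelopes],
            "observed": [e.observed for e in envelopes],
            "null_mean": [e.null_mean for e in envelopes],
            "null_lower": [e.null_lower for e in envelopes],
            "null_upper": [e.null_upper for e in envelopes],
            "classification": [e.classification for e in envelopes],
        }
    )
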