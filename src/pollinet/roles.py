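"""Species roles from within-module degree (z) and among-module
connectivity (c), with null-model-derived thresholds.

For species *s* with binary degree k_s (distinct partners) in module m:

    z_s = (k_sm - mean(k_.m)) / sd(k_.m)      (population sd over the
                                               same-trophic-level members
                                               of module m; z = 0 if sd = 0)
    c_s = 1 - sum_t (k_st / k_s)^2            (k_st = partners in module t)

Peripheral species have low c and z; connectors bridge modules (high c);
module hubs dominate within their module (high z); network hubs do both.
Thresholds are the 95% quantiles of c and z over species from
margin-preserving (Patefield) random networks, pooled per trophic level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import random_table

from .modularity import Partition, _labels_to_arrays, lpa_optimize
from .network import InteractionNetwork
from .seeds import derive_seed, spawn_seeds

Role = Literal["peripheral", "connector", "module_hub", "network_hub"]
NullFamily = Literal["patefield", "row-multinomial"]


@dataclass
class SpeciesRole:
    species: str
    level: Literal["plant", "pollinator"]
    c: float
    z: float
    role: Role


@dataclass
class RoleThresholds:
    """Per-trophic-level c/z thresholds from a null-network quantile."""

    plant_c: float
    plant_z: float
    pollinator_c: float
    pollinator_z: float
    n_null: int
    quantile: float

    def for_level(self, level: str) -> tuple[float, float]:
        if level == "plant":
            return self.plant_c, self.plant_z
        if level == "pollinator":
            return self.pollinator_c, self.pollinator_z
        raise ValueError(f"unknown trophic level {level!r}")


def _cz_one_side(
    B: np.ndarray, own: np.ndarray, other: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """c and z for the row species of binary matrix B.

    ``own``/``other``: module ids of row species and of column species.
    """
    n = B.shape[0]
    deg = B.sum(axis=1)
    # c: evenness of partner spread over partner modules
    c = np.empty(n)
    for s in range(n):
        partner_mods = other[B[s].astype(bool)]
        _, counts = np.unique(partner_mods, return_counts=True)
        c[s] = 1.0 - np.sum((counts / deg[s]) ** 2)
    # z: within-module degree standardized over same-level module members
    k_in = np.array([B[s, other == own[s]].sum() for s in range(n)])
    z = np.zeros(n)
    for m in np.unique(own):
        members = np.flatnonzero(own == m)
        vals = k_in[members]
        sd = vals.std()  # population sd
        if sd > 0:
            z[members] = (vals - vals.mean()) / sd
    return c, z


def cz_values(net: InteractionNetwork, partition: Partition) -> pd.DataFrame:
    """c- and z-values for every plant and pollinator under a partition.

    Returns a frame with columns species, level, degree, c, z.
    """
    mp, mk = _labels_to_arrays(net, partition)
    B = (net.counts > 0).astype(np.int64)
    c_p, z_p = _cz_one_side(B, mp, mk)
    c_k, z_k = _cz_one_side(B.T, mk, mp)
    return pd.DataFrame(
        {
            "species": net.plant_labels + net.pollinator_labels,
            "level": ["plant"] * net.n_plants + ["pollinator"] * net.n_pollinators,
            "degree": np.concatenate([B.sum(axis=1), B.sum(axis=0)]),
            "c": np.concatenate([c_p, c_k]),
            "z": np.concatenate([z_p, z_k]),
        }
    )


def _null_matrices(
    net: InteractionNetwork, n_null: int, family: NullFamily, rng: np.random.Generator
) -> np.ndarray:
    R = net.row_totals
    C = net.col_totals
    if family == "patefield":
        return random_table(R, C).rvs(n_null, random_state=rng)
    if family == "row-multinomial":
        p = C / net.total
        out = np.stack(
            [
                np.array([rng.multinomial(int(r_i), p) for r_i in R])
                for _ in range(n_null)
            ]
        )
        return out
    raise ValueError(f"unknown null family {family!r}")


def role_thresholds(
    net: InteractionNetwork,
    n_null: int = 1000,
    quantile: float = 0.95,
    seed: int | None = None,
    null_family: NullFamily = "patefield",
) -> RoleThresholds:
    """c/z thresholds as the requested quantile over null-network species.

    Each of the ``n_null`` margin-preserving random networks gets a single
    label-propagation run; c and z of all its species are pooled per trophic
    level and the per-level quantiles become the thresholds.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    rng = np.random.default_rng(derive_seed(seed, "role-null-matrices"))
    mats = _null_matrices(net, n_null, null_family, rng)
    lpa_seeds = spawn_seeds(seed, n_null, "role-null-lpa")
    pooled = {("plant", "c"): [], ("plant", "z"): [],
              ("pollinator", "c"): [], ("pollinator", "z"): []}
    for rep in range(n_null):
        mat = np.asarray(mats[rep])
        # Patefield preserves margins, row-multinomial may zero a column;
        # drop empty columns to keep the network invariant.
        keep = mat.sum(axis=0) > 0
        null_net = InteractionNetwork(
            counts=mat[:, keep],
            plant_labels=net.plant_labels,
            pollinator_labels=[
                k for k, keep_k in zip(net.pollinator_labels, keep) if keep_k
            ],
        )
        part = lpa_optimize(null_net, seed=lpa_seeds[rep])
        cz = cz_values(null_net, part)
        for level in ("plant", "pollinator"):
            sub = cz[cz["level"] == level]
            pooled[(level, "c")].append(sub["c"].to_numpy())
            pooled[(level, "z")].append(sub["z"].to_numpy())
    q = 100 * quantile
    return RoleThresholds(
        plant_c=float(np.percentile(np.concatenate(pooled[("plant", "c")]), q)),
        plant_z=float(np.percentile(np.concatenate(pooled[("plant", "z")]), q)),
        pollinator_c=float(
            np.percentile(np.concatenate(pooled[("pollinator", "c")]), q)
        ),
        pollinator_z=float(
            np.percentile(np.concatenate(pooled[("pollinator", "z")]), q)
        ),
        n_null=n_null,
        quantile=quantile,
    )


def classify_roles(
    cz: pd.DataFrame, thresholds: RoleThresholds
) -> list[SpeciesRole]:
    """Classify species by strict comparison of c and z with the thresholds.

    (low c, low z) -> peripheral; high c only -> connector; high z only ->
    module hub; both high -> network hub.  A value exactly equal to its
    threshold counts as low.
    """
    roles: list[SpeciesRole] = []
    for row in cz.itertuples(index=False):
        c_thr, z_thr = thresholds.for_level(row.level)
        high_c = row.c > c_thr
        high_z = row.z > z_thr
        if high_c and high_z:
            role: Role = "network_hub"
        elif high_c:
            role = "connector"
        elif high_z:
            role = "module_hub"
        else:
            role = "peripheral"
        roles.append(
            SpeciesRole(species=row.species, level=row.level,
                        c=float(row.c), z=float(row.z), role=role)
        )
    return roles


def roles_to_frame(roles: Sequence[SpeciesRole]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [r.species for r in roles],
            "level": [r.level for r in roles],
            "c": [r.c for r in roles],
            "z": [r.z for r in roles],
            "role": [r.role for r in roles],
        }
    )
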