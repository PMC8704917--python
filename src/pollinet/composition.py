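"""Pollinator-composition dissimilarity and distance-based PERMANOVA.

Bray-Curtis dissimilarity on raw pooled counts quantifies how different two
plants' pollinator faunas are (0 = identical composition, 1 = no shared
taxa).  A one-way PERMANOVA (McArdle-Anderson partitioning of squared
distances) tests whether composition differs between groups of plants, e.g.
flower-type functional groups, with a label-permutation p-value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .network import InteractionNetwork


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x,y)) / (sum x + sum y).

    Both vectors must be non-negative counts of equal length and at least
    one must have a positive total.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("count vectors must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(x, y))


def dissimilarity_matrix(
    net: InteractionNetwork, level: Literal["plants", "pollinators"] = "plants"
) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between plants (over their pollinator
    counts) or between pollinators (over their plant counts)."""
    if level == "plants":
        data, labels = net.counts, net.plant_labels
    elif level == "pollinators":
        data, labels = net.counts.T, net.pollinator_labels
    else:
        raise ValueError(f"level must be 'plants' or 'pollinators', got {level!r}")
    condensed = pdist(np.asarray(data, dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=labels)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    groups: tuple[str, ...]


def pseudo_f(d: np.ndarray, groups: Sequence) -> float:
    """McArdle-Anderson pseudo-F from a square distance matrix.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within sums the same quantity within
    each group (divided by the group size); F = (SS_between/(g-1)) /
    (SS_within/(N-g)).  Returns +inf when SS_within is zero.
    """
    d = np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    n = len(groups)
    labels = np.unique(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = d**2
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        if len(idx) == n:
            raise ValueError("a single group contains every object")
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return float("inf")
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    d,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with a permutation p-value.

    The p-value uses the +1 convention, p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm), so it can never be exactly zero.  Permutations shuffle the
    group labels with the given seed.
    """
    if isinstance(d, DistanceMatrix):
        dmat = d.data
    else:
        dmat = np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    f_obs = pseudo_f(dmat, groups)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        f_perm = pseudo_f(dmat, rng.permutation(groups))
        if f_perm >= f_obs:
            n_ge += 1
    return PermanovaResult(
        pseudo_f=f_obs,
        p_value=(1 + n_ge) / (1 + n_perm),
        n_permutations=n_perm,
        groups=tuple(str(x) for x in np.unique(groups)),
    )


def permanova_exhaustive(d, groups: Sequence) -> PermanovaResult:
    """Exact permutation test enumerating all distinct label assignments.

    Feasible only for small N; p = #{assignments with F >= F_obs} / #assignments.
    """
    if isinstance(d, DistanceMatrix):
        dmat = d.data
    else:
        dmat = np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    f_obs = pseudo_f(dmat, groups)
    perms = set(itertools.permutations(groups.tolist()))
    n_ge = sum(1 for p in perms if pseudo_f(dmat, np.asarray(p)) >= f_obs)
    return PermanovaResult(
        pseudo_f=f_obs,
        p_value=n_ge / len(perms),
        n_permutations=len(perms),
        groups=tuple(str(x) for x in np.unique(groups)),
    )
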