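"""Barber bipartite modularity and weighted label-propagation module search.

Barber's Q compares the interaction weight inside modules against the
margins-based expectation R_i * C_k / F:

    Q = (1/F) * sum_{i,k} (a_ik - R_i C_k / F) * delta(m_i, m_k)

on a scale from -1 to 1, where 0 means the division is no better than the
random expectation.  Modules are detected with weighted bipartite label
propagation: species adopt, in seed-shuffled order, the neighbouring module
with the largest positive Q gain, followed by a greedy module-merge
refinement; ``meta_optimize`` keeps the best of several seeded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import InteractionNetwork
from .seeds import spawn_seeds

_EPS = 1e-12


@dataclass
class Partition:
    """Module assignment for every plant and pollinator (shared id space,
    ids contiguous from 1) together with its Barber modularity Q."""

    plant_modules: dict[str, int]
    pollinator_modules: dict[str, int]
    q: float

    @property
    def n_modules(self) -> int:
        return len(
            set(self.plant_modules.values()) | set(self.pollinator_modules.values())
        )

    def module_of(self, species: str) -> int:
        if species in self.plant_modules:
            return self.plant_modules[species]
        if species in self.pollinator_modules:
            return self.pollinator_modules[species]
        raise KeyError(f"species {species!r} not in partition")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": s, "level": "plant", "module": m}
            for s, m in self.plant_modules.items()
        ] + [
            {"species": s, "level": "pollinator", "module": m}
            for s, m in self.pollinator_modules.items()
        ]
        return pd.DataFrame(rows)


def _labels_to_arrays(
    net: InteractionNetwork, partition: Partition
) -> tuple[np.ndarray, np.ndarray]:
    try:
        mp = np.array([partition.plant_modules[p] for p in net.plant_labels])
    except KeyError as e:
        raise KeyError(f"plant {e.args[0]!r} missing from partition") from None
    try:
        mk = np.array([partition.pollinator_modules[k] for k in net.pollinator_labels])
    except KeyError as e:
        raise KeyError(f"pollinator {e.args[0]!r} missing from partition") from None
    return mp, mk


def _q_from_arrays(A: np.ndarray, mp: np.ndarray, mk: np.ndarray) -> float:
    F = A.sum()
    R = A.sum(axis=1)
    C = A.sum(axis=0)
    q = 0.0
    for m in np.unique(np.concatenate([mp, mk])):
        rows = mp == m
        cols = mk == m
        q += A[np.ix_(rows, cols)].sum() - R[rows].sum() * C[cols].sum() / F
    return float(q / F)


def barber_modularity(net: InteractionNetwork, partition: Partition) -> float:
    """Barber's bipartite modularity Q of a partition on its network."""
    mp, mk = _labels_to_arrays(net, partition)
    return _q_from_arrays(net.counts.astype(float), mp, mk)


def _relabel_contiguous(mp: np.ndarray, mk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids = np.unique(np.concatenate([mp, mk]))
    remap = {old: new for new, old in enumerate(ids, start=1)}
    return (
        np.array([remap[m] for m in mp]),
        np.array([remap[m] for m in mk]),
    )


def _lpa_arrays(A: np.ndarray, seed: int | None) -> tuple[np.ndarray, np.ndarray]:
    """Label propagation + merge refinement on the raw count matrix."""
    rng = np.random.default_rng(seed)
    n_p, n_k = A.shape
    F = A.sum()
    R = A.sum(axis=1)
    C = A.sum(axis=0)
    # every species starts in its own module
    mp = np.arange(n_p)
    mk = np.arange(n_p, n_p + n_k)
    partners_of_plant = [np.flatnonzero(A[i]) for i in range(n_p)]
    partners_of_poll = [np.flatnonzero(A[:, k]) for k in range(n_k)]

    def sweep() -> bool:
        moved = False
        order = rng.permutation(n_p + n_k)
        for s in order:
            if s < n_p:  # plant node
                i = s
                cur = mp[i]
                cand = np.unique(np.append(mk[partners_of_plant[i]], cur))
                # gain(b) = S_i(b) - R_i*C(b)/F, up to the constant gain(cur)
                best_m, best_gain = cur, 0.0
                cur_cols = mk == cur
                base = A[i, cur_cols].sum() - R[i] * C[cur_cols].sum() / F
                for b in cand:
                    if b == cur:
                        continue
                    cols = mk == b
                    gain = A[i, cols].sum() - R[i] * C[cols].sum() / F - base
                    if gain > best_gain + _EPS or (
                        abs(gain - best_gain) <= _EPS and best_gain > _EPS and b < best_m
                    ):
                        best_m, best_gain = b, gain
                if best_m != cur:
                    mp[i] = best_m
                    moved = True
            else:  # pollinator node
                k = s - n_p
                cur = mk[k]
                cand = np.unique(np.append(mp[partners_of_poll[k]], cur))
                cur_rows = mp == cur
                base = A[cur_rows, k].sum() - C[k] * R[cur_rows].sum() / F
                best_m, best_gain = cur, 0.0
                for b in cand:
                    if b == cur:
                        continue
                    rows = mp == b
                    gain = A[rows, k].sum() - C[k] * R[rows].sum() / F - base
                    if gain > best_gain + _EPS or (
                        abs(gain - best_gain) <= _EPS and best_gain > _EPS and b < best_m
                    ):
                        best_m, best_gain = b, gain
                if best_m != cur:
                    mk[k] = best_m
                    moved = True
        return moved

    def merge_refine(min_gain: float = _EPS) -> bool:
        """Greedily merge module pairs while the Q gain exceeds ``min_gain``.

        With ``min_gain`` at -EPS this also accepts zero-gain merges, which
        collapses Q-equivalent splits (e.g. a structureless matrix) into
        the fewest modules.
        """
        merged_any = False
        while True:
            mods = np.unique(np.concatenate([mp, mk]))
            if len(mods) < 2:
                return merged_any
            # block sums between plant-side and pollinator-side of modules
            E = np.zeros((len(mods), len(mods)))
            Rm = np.zeros(len(mods))
            Cm = np.zeros(len(mods))
            idx = {m: t for t, m in enumerate(mods)}
            mp_t = np.array([idx[m] for m in mp])
            mk_t = np.array([idx[m] for m in mk])
            for a in range(len(mods)):
                rows = mp_t == a
                Rm[a] = R[rows].sum()
                if rows.any():
                    E[a] = np.bincount(mk_t, weights=A[rows].sum(axis=0),
                                       minlength=len(mods))
            for b in range(len(mods)):
                Cm[b] = C[mk_t == b].sum()
            best_gain, best_pair = min_gain, None
            for a in range(len(mods)):
                for b in range(a + 1, len(mods)):
                    gain = E[a, b] + E[b, a] - (Rm[a] * Cm[b] + Rm[b] * Cm[a]) / F
                    if gain > best_gain:
                        best_gain, best_pair = gain, (mods[a], mods[b])
            if best_pair is None:
                return merged_any
            keep, drop = best_pair
            mp[mp == drop] = keep
            mk[mk == drop] = keep
            merged_any = True

    while True:
        improved = False
        while sweep():
            improved = True
        if merge_refine():
            improved = True
            continue
        if not improved:
            # Q is locally maximal; absorb zero-gain splits (fewer modules
            # at identical Q) and re-enter only if that happened.
            if merge_refine(min_gain=-_EPS):
                continue
            break
    return _relabel_contiguous(mp, mk)


def normalized_mutual_information(a, b) -> float:
    """NMI between two labelings (arithmetic-mean normalization).

    Used to compare detected modules with planted ground truth; 1 means the
    partitions are identical up to relabeling, 0 means independence.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    n = len(a)
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((ia.max() + 1, ib.max() + 1))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())
    denom = 0.5 * (entropy(pa) + entropy(pb))
    return mi / denom if denom > 0 else 1.0


def lpa_optimize(net: InteractionNetwork, seed: int | None = None) -> Partition:
    """One seeded label-propagation run; a local maximum of Q under
    single-species moves and pairwise module merges."""
    A = net.counts.astype(float)
    mp, mk = _lpa_arrays(A, seed)
    q = _q_from_arrays(A, mp, mk)
    return Partition(
        plant_modules=dict(zip(net.plant_labels, (int(m) for m in mp))),
        pollinator_modules=dict(zip(net.pollinator_labels, (int(m) for m in mk))),
        q=q,
    )


def meta_optimize(
    net: InteractionNetwork, n_restarts: int = 10, seed: int | None = None
) -> Partition:
    """Best-of-N restarts: run ``lpa_optimize`` with derived seeds, return
    the partition with maximal Q (ties: fewer modules, then first found)."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best: Partition | None = None
    for s in spawn_seeds(seed, n_restarts, "lpa-restart"):
        part = lpa_optimize(net, seed=s)
        if (
            best is None
            or part.q > best.q + _EPS
            or (abs(part.q - best.q) <= _EPS and part.n_modules < best.n_modules)
        ):
            best = part
    assert best is not None
    return best
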