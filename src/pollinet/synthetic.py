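"""Synthetic visitation data with the statistical structure the analysis
assumes.

Two regimes:

* ``generate_neutral`` — plant and pollinator abundances are i.i.d.
  lognormal, and who visits whom is driven purely by relative abundance
  (P(i, k) proportional to w_i * v_k).  This is exactly the mechanism the
  sharing null model resamples, so it provides calibration data.
* ``generate_modular`` — species are assigned round-robin to modules
  (think trait-affinity blocks); a visit lands on the plant's own module's
  pollinators with probability ``affinity``, otherwise on the complement.
  Provides planted ground truth for module recovery and role tests.

Species that end up with zero sampled interactions are dropped (a species
enters a network only through interactions); the ground truth records them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import VisitationRecord


@dataclass
class SyntheticConfig:
    n_plants: int = 40
    n_pollinators: int = 60
    n_modules: int = 4
    affinity: float = 0.95
    abundance_sigma: float = 1.0
    total_visits: int = 2000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_plants < 1 or self.n_pollinators < 1 or self.total_visits < 1:
            raise ValueError("n_plants, n_pollinators, total_visits must be positive")
        if not (1 <= self.n_modules <= min(self.n_plants, self.n_pollinators)):
            raise ValueError("need 1 <= n_modules <= min(n_plants, n_pollinators)")
        if not (0.0 <= self.affinity <= 1.0):
            raise ValueError("affinity must be in [0, 1]")
        if self.abundance_sigma < 0:
            raise ValueError("abundance_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic dataset."""

    plant_modules: dict[str, int]
    pollinator_modules: dict[str, int]
    dropped_plants: list[str] = field(default_factory=list)
    dropped_pollinators: list[str] = field(default_factory=list)
    dropped_visits: int = 0
    config: SyntheticConfig | None = None


def _plant_labels(n: int) -> list[str]:
    return [f"plant_{i + 1:03d}" for i in range(n)]


def _poll_labels(n: int) -> list[str]:
    return [f"poll_{k + 1:03d}" for k in range(n)]


def _records_from_counts(
    counts: np.ndarray, plants: list[str], polls: list[str]
) -> list[VisitationRecord]:
    recs = []
    for i, k in zip(*np.nonzero(counts)):
        recs.append(
            VisitationRecord(
                plant=plants[i], pollinator=polls[k], count=int(counts[i, k])
            )
        )
    return recs


def _finalize(
    counts: np.ndarray,
    plants: list[str],
    polls: list[str],
    plant_mod: np.ndarray,
    poll_mod: np.ndarray,
    config: SyntheticConfig,
) -> tuple[list[VisitationRecord], GroundTruth]:
    keep_p = counts.sum(axis=1) > 0
    keep_k = counts.sum(axis=0) > 0
    gt = GroundTruth(
        plant_modules={
            p: int(m) for p, m, keep in zip(plants, plant_mod, keep_p) if keep
        },
        pollinator_modules={
            k: int(m) for k, m, keep in zip(polls, poll_mod, keep_k) if keep
        },
        dropped_plants=[p for p, keep in zip(plants, keep_p) if not keep],
        dropped_pollinators=[k for k, keep in zip(polls, keep_k) if not keep],
        dropped_visits=int(config.total_visits - counts.sum()),
        config=config,
    )
    kept = counts[np.ix_(keep_p, keep_k)]
    recs = _records_from_counts(
        kept,
        [p for p, keep in zip(plants, keep_p) if keep],
        [k for k, keep in zip(polls, keep_k) if keep],
    )
    return recs, gt


def _round_robin(n: int, n_modules: int) -> np.ndarray:
    return np.arange(n) % n_modules + 1


def generate_neutral(
    config: SyntheticConfig,
) -> tuple[list[VisitationRecord], GroundTruth]:
    """Neutral regime: visitation driven purely by relative abundances.

    Weights are lognormal(0, ``abundance_sigma``); ``total_visits`` events
    are one multinomial draw over the plant x pollinator grid with cell
    probability proportional to w_i * v_k.  ``affinity`` is ignored.
    """
    rng = np.random.default_rng(config.seed)
    plants = _plant_labels(config.n_plants)
    polls = _poll_labels(config.n_pollinators)
    w = rng.lognormal(0.0, config.abundance_sigma, config.n_plants)
    v = rng.lognormal(0.0, config.abundance_sigma, config.n_pollinators)
    p = np.outer(w, v)
    p /= p.sum()
    counts = rng.multinomial(config.total_visits, p.ravel()).reshape(p.shape)
    ones = np.ones(config.n_plants, dtype=int)
    return _finalize(
        counts, plants, polls, ones, np.ones(config.n_pollinators, dtype=int), config
    )


def generate_modular(
    config: SyntheticConfig,
) -> tuple[list[VisitationRecord], GroundTruth]:
    """Trait-affinity block regime with planted modules.

    Species are assigned round-robin to ``n_modules`` modules.  Each visit
    picks its plant by abundance weight; with probability ``affinity`` the
    pollinator is drawn (by weight) from the plant's module, otherwise from
    the complement.  ``affinity = 1`` gives an exactly block-diagonal count
    matrix under the planted ordering.
    """
    rng = np.random.default_rng(config.seed)
    plants = _plant_labels(config.n_plants)
    polls = _poll_labels(config.n_pollinators)
    plant_mod = _round_robin(config.n_plants, config.n_modules)
    poll_mod = _round_robin(config.n_pollinators, config.n_modules)
    w = rng.lognormal(0.0, config.abundance_sigma, config.n_plants)
    v = rng.lognormal(0.0, config.abundance_sigma, config.n_pollinators)

    visits_per_plant = rng.multinomial(config.total_visits, w / w.sum())
    counts = np.zeros((config.n_plants, config.n_pollinators), dtype=np.int64)
    for i, n_i in enumerate(visits_per_plant):
        if n_i == 0:
            continue
        inside = poll_mod == plant_mod[i]
        if inside.all():
            n_in = int(n_i)
        else:
            n_in = int(rng.binomial(n_i, config.affinity))
        if n_in > 0:
            p_in = v * inside
            counts[i] += rng.multinomial(n_in, p_in / p_in.sum())
        n_out = int(n_i) - n_in
        if n_out > 0:
            p_out = v * ~inside
            counts[i] += rng.multinomial(n_out, p_out / p_out.sum())
    return _finalize(counts, plants, polls, plant_mod, poll_mod, config)
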