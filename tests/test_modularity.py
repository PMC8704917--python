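import numpy as np
import pytest

from pollinet import (
    InteractionNetwork,
    Partition,
    barber_modularity,
    lpa_optimize,
    meta_optimize,
)
from pollinet.seeds import spawn_seeds


def brute_force_q(net, partition):
    """Literal double loop over all plant-pollinator pairs."""
    F = net.total
    q = 0.0
    for i, p in enumerate(net.plant_labels):
        for k, poll in enumerate(net.pollinator_labels):
            if partition.module_of(p) == partition.module_of(poll):
                q += net.counts[i, k] - net.row_totals[i] * net.col_totals[k] / F
    return q / F


def set_partitions(items):
    """All ways to split ``items`` into non-empty unlabeled blocks."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for blocks in set_partitions(rest):
        for i in range(len(blocks)):
            yield blocks[:i] + [blocks[i] + [head]] + blocks[i + 1 :]
        yield [[head]] + blocks


class TestBarberModularity:
    def test_single_module_is_zero(self, tiny_net):
        part = Partition({"A": 1, "B": 1}, {"x": 1, "y": 1}, 0.0)
        assert barber_modularity(tiny_net, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_block_toy_is_half(self, two_block_net, two_block_partition):
        assert barber_modularity(two_block_net, two_block_partition) == pytest.approx(0.5)

    def test_antimodular_assignment_is_minus_half(self, two_block_net):
        swapped = Partition(
            plant_modules={"p1": 2, "p2": 2, "p3": 1, "p4": 1},
            pollinator_modules={"k1": 1, "k2": 1, "k3": 2, "k4": 2},
            q=0.0,
        )
        assert barber_modularity(two_block_net, swapped) == pytest.approx(-0.5)

    def test_missing_species_named_in_error(self, tiny_net):
        part = Partition({"A": 1}, {"x": 1, "y": 1}, 0.0)
        with pytest.raises(KeyError, match="B"):
            barber_modularity(tiny_net, part)

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(17)
        from conftest import random_network

        for _ in range(5):
            net = random_network(rng, 5, 6)
            labels = net.plant_labels + net.pollinator_labels
            mods = rng.integers(1, 4, size=len(labels))
            part = Partition(
                {p: int(m) for p, m in zip(net.plant_labels, mods[: net.n_plants])},
                {
                    k: int(m)
                    for k, m in zip(net.pollinator_labels, mods[net.n_plants :])
                },
                0.0,
            )
            assert barber_modularity(net, part) == pytest.approx(
                brute_force_q(net, part), abs=1e-12
            )


class TestOptimizer:
    def test_recovers_two_block_toy(self, two_block_net):
        part = lpa_optimize(two_block_net, seed=0)
        assert part.q == pytest.approx(0.5)
        assert part.n_modules == 2

    def test_structureless_matrix_collapses_to_one_module(self):
        net = InteractionNetwork(
            np.ones((4, 4), dtype=np.int64),
            [f"p{i}" for i in range(4)],
            [f"k{i}" for i in range(4)],
        )
        part = meta_optimize(net, n_restarts=5, seed=1)
        assert part.q == pytest.approx(0.0, abs=1e-12)
        assert part.n_modules == 1

    def test_deterministic_given_seed(self, two_block_net):
        a = lpa_optimize(two_block_net, seed=3)
        b = lpa_optimize(two_block_net, seed=3)
        assert a.plant_modules == b.plant_modules
        assert a.pollinator_modules == b.pollinator_modules

    def test_module_ids_contiguous_from_one(self):
        rng = np.random.default_rng(23)
        from conftest import random_network

        net = random_network(rng, 6, 7)
        part = lpa_optimize(net, seed=2)
        ids = sorted(
            set(part.plant_modules.values()) | set(part.pollinator_modules.values())
        )
        assert ids == list(range(1, len(ids) + 1))

    def test_local_optimality_under_single_moves(self):
        rng = np.random.default_rng(29)
        from conftest import random_network

        net = random_network(rng, 5, 6)
        part = meta_optimize(net, n_restarts=3, seed=4)
        module_ids = set(part.plant_modules.values()) | set(
            part.pollinator_modules.values()
        )
        for species_map in (part.plant_modules, part.pollinator_modules):
            for s in species_map:
                for target in module_ids:
                    if target == species_map[s]:
                        continue
                    alt = Partition(
                        dict(part.plant_modules), dict(part.pollinator_modules), 0.0
                    )
                    (alt.plant_modules if s in alt.plant_modules
                     else alt.pollinator_modules)[s] = target
                    assert barber_modularity(net, alt) <= part.q + 1e-9

    def test_matches_exhaustive_search_on_tiny_networks(self):
        rng = np.random.default_rng(31)
        from conftest import random_network

        for _ in range(3):
            net = random_network(rng, 3, 3, max_count=3)
            species = net.plant_labels + net.pollinator_labels
            best = -np.inf
            for blocks in set_partitions(species):
                assign = {s: m for m, block in enumerate(blocks, 1) for s in block}
                part = Partition(
                    {p: assign[p] for p in net.plant_labels},
                    {k: assign[k] for k in net.pollinator_labels},
                    0.0,
                )
                best = max(best, barber_modularity(net, part))
            found = meta_optimize(net, n_restarts=20, seed=5)
            assert found.q == pytest.approx(best, abs=1e-9)


class TestNormalizedMutualInformation:
    def test_matches_scikit_learn(self):
        sk = pytest.importorskip("sklearn.metrics")
        from pollinet.modularity import normalized_mutual_information

        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.integers(0, 4, size=50)
            b = rng.integers(0, 3, size=50)
            assert normalized_mutual_information(a, b) == pytest.approx(
                sk.normalized_mutual_info_score(a, b), abs=1e-9
            )

    def test_identical_up_to_relabeling_is_one(self):
        from pollinet.modularity import normalized_mutual_information

        a = [1, 1, 2, 2, 3]
        b = [9, 9, 4, 4, 7]
        assert normalized_mutual_information(a, b) == pytest.approx(1.0)


class TestMetaOptimize:
    def test_single_restart_equals_lpa_with_derived_seed(self, two_block_net):
        meta = meta_optimize(two_block_net, n_restarts=1, seed=6)
        single = lpa_optimize(two_block_net, seed=spawn_seeds(6, 1, "lpa-restart")[0])
        assert meta.plant_modules == single.plant_modules
        assert meta.q == single.q

    def test_q_monotone_in_restarts(self):
        rng = np.random.default_rng(37)
        from conftest import random_network

        net = random_network(rng, 6, 8)
        qs = [meta_optimize(net, n_restarts=n, seed=7).q for n in (1, 2, 4, 8)]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_returns_max_over_restarts(self, two_block_net):
        part = meta_optimize(two_block_net, n_restarts=6, seed=8)
        individual = [
            lpa_optimize(two_block_net, seed=s).q
            for s in spawn_seeds(8, 6, "lpa-restart")
        ]
        assert part.q == pytest.approx(max(individual))
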