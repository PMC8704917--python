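import numpy as np
import pytest

from pollinet import (
    InteractionNetwork,
    Partition,
    classify_roles,
    cz_values,
    role_thresholds,
)
from pollinet.roles import RoleThresholds, _null_matrices


def _cz_of(net, partition, species):
    cz = cz_values(net, partition)
    return cz.set_index("species").loc[species]


class TestCValues:
    def test_all_partners_in_own_module_gives_zero(self):
        # p1 links only to k1,k2 which share its module
        A = np.array([[1, 1, 0], [0, 1, 1]])
        net = InteractionNetwork(A, ["p1", "p2"], ["k1", "k2", "k3"])
        part = Partition({"p1": 1, "p2": 2}, {"k1": 1, "k2": 1, "k3": 2}, 0.0)
        assert _cz_of(net, part, "p1")["c"] == pytest.approx(0.0)

    def test_even_split_across_two_modules(self):
        A = np.array([[1, 1], [1, 1]])
        net = InteractionNetwork(A, ["p1", "p2"], ["k1", "k2"])
        part = Partition({"p1": 1, "p2": 2}, {"k1": 1, "k2": 2}, 0.0)
        assert _cz_of(net, part, "p1")["c"] == pytest.approx(0.5)

    def test_c_matches_brute_force_partner_tally(self):
        rng = np.random.default_rng(41)
        from conftest import random_network

        net = random_network(rng, 5, 7)
        mods = rng.integers(1, 4, size=net.n_plants + net.n_pollinators)
        part = Partition(
            {p: int(m) for p, m in zip(net.plant_labels, mods[: net.n_plants])},
            {k: int(m) for k, m in zip(net.pollinator_labels, mods[net.n_plants :])},
            0.0,
        )
        cz = cz_values(net, part).set_index("species")
        for i, p in enumerate(net.plant_labels):
            partners = [
                part.pollinator_modules[net.pollinator_labels[k]]
                for k in np.flatnonzero(net.counts[i])
            ]
            k_s = len(partners)
            expected = 1 - sum(
                (partners.count(t) / k_s) ** 2 for t in set(partners)
            )
            assert cz.loc[p, "c"] == pytest.approx(expected, abs=1e-12)


class TestZValues:
    def test_hand_computed_module(self):
        # one module whose three plants have within-module degrees 4, 2, 2:
        # z of the first = (4 - 8/3) / population sd 0.9428 ~ 1.414
        A = np.zeros((3, 4), dtype=np.int64)
        A[0, :4] = 1
        A[1, :2] = 1
        A[2, 2:4] = 1
        net = InteractionNetwork(A, ["a", "b", "c"], ["k1", "k2", "k3", "k4"])
        part = Partition(
            {"a": 1, "b": 1, "c": 1}, {"k1": 1, "k2": 1, "k3": 1, "k4": 1}, 0.0
        )
        assert _cz_of(net, part, "a")["z"] == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_within_module_z_standardized(self):
        rng = np.random.default_rng(43)
        from conftest import random_network

        net = random_network(rng, 8, 10)
        mods = rng.integers(1, 3, size=net.n_plants + net.n_pollinators)
        part = Partition(
            {p: int(m) for p, m in zip(net.plant_labels, mods[: net.n_plants])},
            {k: int(m) for k, m in zip(net.pollinator_labels, mods[net.n_plants :])},
            0.0,
        )
        cz = cz_values(net, part)
        for level in ("plant", "pollinator"):
            sub = cz[cz["level"] == level]
            for m in set(part.plant_modules.values()):
                members = sub[
                    [part.module_of(s) == m for s in sub["species"]]
                ]
                z = members["z"].to_numpy()
                if len(z) >= 2 and z.std() > 0:
                    assert z.mean() == pytest.approx(0.0, abs=1e-9)
                    assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_degrees_give_zero_z(self):
        A = np.ones((3, 3), dtype=np.int64)
        net = InteractionNetwork(A, ["a", "b", "c"], ["x", "y", "z"])
        part = Partition(
            {"a": 1, "b": 1, "c": 1}, {"x": 1, "y": 1, "z": 1}, 0.0
        )
        cz = cz_values(net, part)
        assert (cz["z"] == 0).all()


class TestNullFamilies:
    def test_patefield_preserves_both_margins(self):
        rng = np.random.default_rng(47)
        from conftest import random_network

        net = random_network(rng, 5, 6)
        mats = _null_matrices(net, 50, "patefield", np.random.default_rng(1))
        for mat in mats:
            assert np.array_equal(mat.sum(axis=1), net.row_totals)
            assert np.array_equal(mat.sum(axis=0), net.col_totals)

    def test_patefield_cell_means_approach_expectation(self):
        rng = np.random.default_rng(53)
        from conftest import random_network

        net = random_network(rng, 4, 5)
        n = 3000
        mats = _null_matrices(net, n, "patefield", np.random.default_rng(2))
        mean = np.asarray(mats).mean(axis=0)
        expected = np.outer(net.row_totals, net.col_totals) / net.total
        # Monte-Carlo tolerance: 4 standard errors of the cell mean
        se = np.sqrt(np.maximum(expected, 0.05)) / np.sqrt(n)
        assert (np.abs(mean - expected) <= 4 * se + 0.05).all()

    def test_row_multinomial_preserves_row_margins_only(self):
        rng = np.random.default_rng(59)
        from conftest import random_network

        net = random_network(rng, 5, 6)
        mats = _null_matrices(net, 20, "row-multinomial", np.random.default_rng(3))
        for mat in mats:
            assert np.array_equal(mat.sum(axis=1), net.row_totals)


class TestThresholdsAndClassification:
    def test_quantile_bound_by_construction(self):
        rng = np.random.default_rng(61)
        from conftest import random_network

        net = random_network(rng, 6, 8)
        thr = role_thresholds(net, n_null=30, quantile=0.9, seed=4)
        assert np.isfinite([thr.plant_c, thr.plant_z,
                            thr.pollinator_c, thr.pollinator_z]).all()
        assert 0 <= thr.plant_c < 1

    def test_thresholds_reproducible_by_seed(self):
        rng = np.random.default_rng(67)
        from conftest import random_network

        net = random_network(rng, 5, 6)
        a = role_thresholds(net, n_null=20, seed=9)
        b = role_thresholds(net, n_null=20, seed=9)
        assert (a.plant_c, a.plant_z) == (b.plant_c, b.plant_z)

    @pytest.mark.parametrize(
        "c,z,expected",
        [
            (0.0, 0.0, "peripheral"),
            (0.5, 0.0, "peripheral"),      # c exactly at threshold: strict rule
            (0.6, 0.0, "connector"),
            (0.0, 3.0, "module_hub"),
            (0.7, 2.6, "network_hub"),
        ],
    )
    def test_strict_threshold_classification(self, c, z, expected):
        import pandas as pd

        thr = RoleThresholds(
            plant_c=0.5, plant_z=2.5, pollinator_c=0.5, pollinator_z=2.5,
            n_null=10, quantile=0.95,
        )
        cz = pd.DataFrame(
            {"species": ["s"], "level": ["plant"], "degree": [3], "c": [c], "z": [z]}
        )
        assert classify_roles(cz, thr)[0].role == expected

    def test_role_counts_partition_species(self):
        rng = np.random.default_rng(71)
        from conftest import random_network
        from pollinet import meta_optimize

        net = random_network(rng, 6, 8)
        part = meta_optimize(net, n_restarts=3, seed=1)
        thr = role_thresholds(net, n_null=20, seed=2)
        roles = classify_roles(cz_values(net, part), thr)
        assert len(roles) == net.n_plants + net.n_pollinators
        counts = {}
        for r in roles:
            counts[r.role] = counts.get(r.role, 0) + 1
        assert sum(counts.values()) == len(roles)
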