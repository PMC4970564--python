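"""Overlap counting, k-of-n conjunction, intersection and seed labeling."""

import numpy as np
import pytest

from alekit.grid import GridError, StatMap, make_box_mask
from alekit.networks import (
    OverlapMap,
    intersect_networks,
    k_of_n_network,
    label_seed_components,
    overlap_count,
    partition_two_group,
)


def _random_binary(grid, rng, p=0.3):
    return StatMap(grid=grid, values=(rng.uniform(0, 1, grid.shape) < p).astype(float), kind="binary")


class TestOverlapCount:
    def test_common_voxel_counts_all(self, grid16):
        v = np.zeros(grid16.shape)
        v[4, 4, 4] = 1
        maps = [StatMap(grid=grid16, values=v.copy(), kind="binary") for _ in range(4)]
        assert overlap_count(maps).counts[4, 4, 4] == 4

    def test_disjoint_maps_count_at_most_one(self, grid16):
        a = np.zeros(grid16.shape)
        b = np.zeros(grid16.shape)
        a[1, 1, 1] = 1
        b[5, 5, 5] = 1
        om = overlap_count(
            [StatMap(grid=grid16, values=a, kind="binary"), StatMap(grid=grid16, values=b, kind="binary")]
        )
        assert set(np.unique(om.counts)) <= {0, 1}

    def test_equals_summation_oracle(self, grid16, rng):
        maps = [_random_binary(grid16, rng) for _ in range(5)]
        om = overlap_count(maps)
        assert np.array_equal(om.counts, sum(m.values.astype(int) for m in maps))


class TestKofN:
    def test_threshold_at_two_of_four(self, ):
        grid = make_box_mask((5, 1, 1), 1.0, (0, 0, 0))
        counts = np.array([0, 1, 2, 3, 4]).reshape(5, 1, 1)
        om = OverlapMap(grid=grid, counts=counts, n_conditions=4)
        net = k_of_n_network(om, 2)
        assert net.values.ravel().tolist() == [0, 0, 1, 1, 1]

    def test_k1_is_union_kn_is_intersection(self, grid16, rng):
        maps = [_random_binary(grid16, rng) for _ in range(4)]
        om = overlap_count(maps)
        union = np.clip(sum(m.values for m in maps), 0, 1)
        inter = np.prod([m.values for m in maps], axis=0)
        assert np.array_equal(k_of_n_network(om, 1).values, union)
        assert np.array_equal(k_of_n_network(om, 4).values, inter)

    def test_nestedness_over_random_quadruples(self, grid16, rng):
        for _ in range(100):
            om = overlap_count([_random_binary(grid16, rng) for _ in range(4)])
            prev = k_of_n_network(om, 1).values
            for k in (2, 3, 4):
                cur = k_of_n_network(om, k).values
                assert np.all(cur <= prev)
                prev = cur

    def test_k_out_of_range(self, grid16, rng):
        om = overlap_count([_random_binary(grid16, rng) for _ in range(3)])
        for bad in (0, 4):
            with pytest.raises(ValueError):
                k_of_n_network(om, bad)


class TestIntersect:
    def test_idempotent_and_disjoint(self, grid16, rng):
        m = _random_binary(grid16, rng)
        assert np.array_equal(intersect_networks(m, m).values, m.values)
        empty = StatMap(grid=grid16, values=np.zeros(grid16.shape), kind="binary")
        assert intersect_networks(m, empty).values.sum() == 0

    def test_commutative_associative(self, grid16, rng):
        a, b, c = (_random_binary(grid16, rng) for _ in range(3))
        ab = intersect_networks(a, b)
        ba = intersect_networks(b, a)
        assert np.array_equal(ab.values, ba.values)
        assert np.array_equal(
            intersect_networks(ab, c).values, intersect_networks(a, intersect_networks(b, c)).values
        )

    def test_grid_mismatch(self, grid16, rng):
        other = make_box_mask((16, 16, 16), 2.0, (1, 0, 0))
        with pytest.raises(GridError):
            intersect_networks(_random_binary(grid16, rng), _random_binary(other, rng))


class TestSeedLabeling:
    def test_equal_weights_center_at_midpoint(self, grid16):
        v = np.zeros(grid16.shape)
        v[4, 4, 4] = v[4, 4, 5] = 1
        seeds = label_seed_components(StatMap(grid=grid16, values=v, kind="binary"))
        assert len(seeds) == 1
        assert np.allclose(seeds.components[0].weighted_center_mm, (8.0, 8.0, 9.0))

    def test_weighted_center_pulled_toward_heavier_voxel(self):
        grid = make_box_mask((8, 8, 8), 4.0, (0.0, 0.0, 0.0))
        v = np.zeros(grid.shape)
        v[4, 4, 4] = v[4, 4, 5] = 1  # adjacent voxels, 4 mm apart
        w = np.zeros(grid.shape)
        w[4, 4, 4] = 0.3
        w[4, 4, 5] = 0.1
        seeds = label_seed_components(
            StatMap(grid=grid, values=v, kind="binary"),
            StatMap(grid=grid, values=w, kind="ale"),
        )
        # weights (3, 1): center 1 mm from the heavier voxel (z = 16 + 1)
        assert len(seeds) == 1
        assert np.allclose(seeds.components[0].weighted_center_mm, (16.0, 16.0, 17.0))

    def test_labels_ordered_by_size_and_inside_bbox(self, grid16, rng):
        seeds = label_seed_components(_random_binary(grid16, rng, p=0.1), connectivity=6)
        sizes = [c.n_voxels for c in seeds.components]
        assert sizes == sorted(sizes, reverse=True)
        for c in seeds.components:
            coords = np.argwhere(seeds.component_labels == c.label)
            lo = coords.min(axis=0) * grid16.voxel_size + grid16.origin
            hi = coords.max(axis=0) * grid16.voxel_size + grid16.origin
            assert np.all(c.weighted_center_mm >= lo - 1e-9)
            assert np.all(c.weighted_center_mm <= hi + 1e-9)

    def test_empty_map_gives_empty_seedset(self, grid16):
        empty = StatMap(grid=grid16, values=np.zeros(grid16.shape), kind="binary")
        seeds = label_seed_components(empty)
        assert len(seeds) == 0
        assert seeds.to_table().empty


class TestPartition:
    def test_identical_inputs_all_shared(self, grid16, rng):
        m = _random_binary(grid16, rng)
        m_only, f_only, shared = partition_two_group(m, m)
        assert m_only.values.sum() == 0 and f_only.values.sum() == 0
        assert np.array_equal(shared.values, m.values)

    def test_disjoint_and_exhaustive_on_random_pairs(self, grid16, rng):
        for _ in range(100):
            a, b = _random_binary(grid16, rng), _random_binary(grid16, rng)
            m_only, f_only, shared = partition_two_group(a, b)
            total = m_only.values + f_only.values + shared.values
            assert total.max() <= 1  # pairwise disjoint
            assert np.array_equal(total > 0, (a.values + b.values) > 0)
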