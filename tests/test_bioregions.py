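from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_average_linkage_heights
from mesodiv.bioregions import (
    DistanceMatrix,
    cluster,
    cut,
    delineate_bioregions,
    distance_matrix,
    forbes_distance,
    haversine_km,
    haversine_matrix,
    partition_meet,
)

coord = st.tuples(
    st.floats(-90, 90, allow_nan=False), st.floats(-179.9, 180, allow_nan=False)
)


class TestHaversine:
    def test_identity(self):
        assert haversine_km((10.0, 20.0), (10.0, 20.0)) == 0.0

    def test_antipodes(self):
        assert haversine_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(
            math.pi * 6371.0, abs=1e-6
        )

    def test_one_degree_equator(self):
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(
            math.pi / 180.0 * 6371.0, abs=1e-6
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            haversine_km((float("nan"), 0.0), (0.0, 0.0))

    @given(coord, coord)
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_bounds(self, p, q):
        d = haversine_km(p, q)
        assert d == pytest.approx(haversine_km(q, p), abs=1e-9)
        assert 0.0 <= d <= math.pi * 6371.0 + 1e-9

    def test_matrix_matches_pairwise(self, rng):
        pts = [(float(rng.uniform(-80, 80)), float(rng.uniform(-179, 179))) for _ in range(5)]
        m = haversine_matrix(pts)
        for i in range(5):
            for j in range(5):
                assert m[i, j] == pytest.approx(haversine_km(pts[i], pts[j]), abs=1e-9)


class TestForbes:
    def test_identical_sets(self):
        assert forbes_distance({"a", "b"}, {"a", "b"}) == 0.0

    def test_disjoint_sets(self):
        assert forbes_distance({"a"}, {"b", "c"}) == 1.0

    def test_worked_example(self):
        # a=2, b=1, c=1, n=4: similarity = 2(4+2)/(2(4+2)+1.5) = 12/13.5
        d = forbes_distance({"s1", "s2", "u1"}, {"s1", "s2", "u2"})
        assert d == pytest.approx(1.0 - 12.0 / 13.5, abs=1e-12)

    def test_empty_assemblage_rejected(self):
        with pytest.raises(ValueError):
            forbes_distance(set(), {"a"})

    @given(
        st.sets(st.integers(0, 30), min_size=1, max_size=15),
        st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_symmetry(self, a, b):
        d = forbes_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(forbes_distance(b, a), abs=1e-12)


def _geo_dm(coords, ids=None):
    from mesodiv.occurrences import Collection

    ids = ids or [f"c{i}" for i in range(len(coords))]
    colls = [Collection(i, la, lo, 210.0, 200.0) for i, (la, lo) in zip(ids, coords)]
    return distance_matrix(colls, kind="geographic_km")


class TestDistanceMatrix:
    def test_colocated_identical_fauna(self):
        from mesodiv.occurrences import Collection

        colls = [Collection(f"c{i}", 10.0, 10.0, 210.0, 200.0) for i in range(2)]
        geo = distance_matrix(colls, kind="geographic_km")
        tax = distance_matrix(
            colls, {"c0": {"x"}, "c1": {"x"}}, kind="taxonomic"
        )
        assert geo.values[0, 1] == 0.0
        assert tax.values[0, 1] == 0.0

    def test_structure(self):
        dm = _geo_dm([(0, 0), (10, 10), (20, 20)])
        assert dm.values.shape == (3, 3)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_empty_assemblage_dropped_with_warning(self):
        from mesodiv.occurrences import Collection

        colls = [Collection(f"c{i}", float(i), 0.0, 210.0, 200.0) for i in range(3)]
        with pytest.warns(UserWarning):
            dm = distance_matrix(
                colls, {"c0": {"x"}, "c1": set(), "c2": {"y"}}, kind="taxonomic"
            )
        assert dm.labels == ("c0", "c2")

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]), "taxonomic")


class TestCluster:
    def test_two_leaves(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]), "taxonomic")
        for linkage in ("average", "complete", "single"):
            dend = cluster(dm, linkage)
            assert len(dend.merges) == 1
            assert dend.merges[0][2] == 3.0

    def test_three_equidistant(self):
        v = np.full((3, 3), 2.0)
        np.fill_diagonal(v, 0.0)
        dend = cluster(DistanceMatrix(("a", "b", "c"), v, "taxonomic"))
        assert [h for *_, h in dend.merges] == [2.0, 2.0]

    def test_tie_break_is_lexicographic(self):
        v = np.full((3, 3), 2.0)
        np.fill_diagonal(v, 0.0)
        dend = cluster(DistanceMatrix(("b", "c", "a"), v, "taxonomic"))
        left, right, _ = dend.merges[0]
        assert (left, right) == (("a",), ("b",))

    def test_matches_brute_force_average_linkage(self, rng):
        for _ in range(5):
            n = 6
            base = rng.uniform(1.0, 10.0, size=(n, n))
            v = (base + base.T) / 2.0
            np.fill_diagonal(v, 0.0)
            dm = DistanceMatrix(tuple(f"c{i}" for i in range(n)), v, "taxonomic")
            heights = sorted(h for *_, h in cluster(dm, "average").merges)
            expected = brute_average_linkage_heights(v)
            assert np.allclose(heights, expected, atol=1e-9)

    def test_single_leaf_rejected(self):
        dm = DistanceMatrix(("a",), np.zeros((1, 1)), "taxonomic")
        with pytest.raises(ValueError):
            cluster(dm)

    def test_heights_nondecreasing(self, rng):
        base = rng.uniform(0.0, 5.0, size=(8, 8))
        v = (base + base.T) / 2.0
        np.fill_diagonal(v, 0.0)
        dm = DistanceMatrix(tuple(f"c{i}" for i in range(8)), v, "taxonomic")
        for linkage in ("average", "complete", "single"):
            heights = [h for *_, h in cluster(dm, linkage).merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_newick_roundtrip_topology(self):
        dm = _geo_dm([(0, 0), (0.1, 0), (30, 30)])
        nwk = cluster(dm).to_newick()
        assert nwk.endswith(";") and nwk.count(",") == 2


class TestCut:
    def _dend(self):
        return cluster(_geo_dm([(0, 0), (0.2, 0), (10, 10), (10.2, 10)]))

    def test_height_zero_all_singletons(self):
        part = cut(self._dend(), 0.0)
        assert sorted(part.values()) == [1, 2, 3, 4]

    def test_root_height_single_cluster(self):
        dend = self._dend()
        assert set(cut(dend, dend.root_height).values()) == {1}

    def test_two_separated_pairs(self):
        part = cut(self._dend(), 100.0)
        assert part["c0"] == part["c1"]
        assert part["c2"] == part["c3"]
        assert part["c0"] != part["c2"]

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            cut(self._dend(), -1.0)


class TestPartitionMeet:
    def test_meet_refines_both(self):
        p1 = {"a": 1, "b": 1, "c": 2, "d": 2}
        p2 = {"a": 1, "b": 2, "c": 2, "d": 2}
        meet = partition_meet(p1, p2)
        for x in "abcd":
            for y in "abcd":
                same = meet[x] == meet[y]
                assert same == (p1[x] == p1[y] and p2[x] == p2[y])

    def test_labels_dense_from_one(self):
        meet = partition_meet({"a": 5, "b": 9}, {"a": 2, "b": 2})
        assert sorted(set(meet.values())) == [1, 2]


class TestDelineate:
    def _colls(self, coords):
        from mesodiv.occurrences import Collection

        return [
            Collection(f"c{i}", la, lo, 210.0, 200.0) for i, (la, lo) in enumerate(coords)
        ]

    def test_tight_identical_fauna_single_region(self):
        colls = self._colls([(0, 0), (0.2, 0), (0, 0.2)])
        assem = {c.collection_id: {"s1", "s2"} for c in colls}
        assert set(delineate_bioregions(colls, assem).values()) == {1}

    def test_distance_forces_split(self):
        colls = self._colls([(0, 0), (5, 0)])  # ~556 km apart
        assem = {c.collection_id: {"s1"} for c in colls}
        part = delineate_bioregions(colls, assem)
        assert part["c0"] != part["c1"]

    def test_fauna_forces_split_when_colocated(self):
        colls = self._colls([(0, 0), (0, 0)])
        assem = {"c0": {"s1", "s2"}, "c1": {"s3", "s4"}}
        part = delineate_bioregions(colls, assem)
        assert part["c0"] != part["c1"]

    def test_singleton_bin(self):
        colls = self._colls([(0, 0)])
        assert delineate_bioregions(colls, {"c0": {"s1"}}) == {"c0": 1}

    def test_meet_subset_of_both_partitions(self, rng):
        coords = [(float(rng.uniform(-60, 60)), float(rng.uniform(-170, 170))) for _ in range(8)]
        colls = self._colls(coords)
        pool = [f"s{i}" for i in range(12)]
        assem = {
            c.collection_id: set(rng.choice(pool, size=4, replace=False)) for c in colls
        }
        part = delineate_bioregions(colls, assem)
        geo = cut(cluster(distance_matrix(colls, kind="geographic_km")), 100.0)
        tax = cut(cluster(distance_matrix(colls, assem, kind="taxonomic")), 0.5)
        for a in part:
            for b in part:
                if part[a] == part[b]:
                    assert geo[a] == geo[b] and tax[a] == tax[b]

    def test_doubling_height_never_increases_regions(self, rng):
        for _ in range(5):
            coords = [
                (float(rng.uniform(-30, 30)), float(rng.uniform(-30, 30))) for _ in range(10)
            ]
            colls = self._colls(coords)
            assem = {c.collection_id: {"s1"} for c in colls}
            n1 = len(set(delineate_bioregions(colls, assem, geo_height_km=100).values()))
            n2 = len(set(delineate_bioregions(colls, assem, geo_height_km=200).values()))
            assert n2 <= n1
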