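"""Bioregion delineation by paired geographic and taxonomic clustering.

Collections within a time bin are clustered twice — once on great-circle
distance between paleocoordinates and once on corrected-Forbes taxonomic
distance between their assemblages.  Each dendrogram is cut at a fixed
height (100 km geographic by default) and the bioregions are the meet of
the two partitions: two collections share a bioregion only when they share
a cluster in both analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .occurrences import Collection

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "haversine_matrix",
    "forbes_distance",
    "DistanceMatrix",
    "Dendrogram",
    "distance_matrix",
    "cluster",
    "cut",
    "partition_meet",
    "delineate_bioregions",
]

EARTH_RADIUS_KM = 6371.0

Partition = dict[str, int]


def haversine_km(
    p1: tuple[float, float], p2: tuple[float, float], radius_km: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    for v in (lat1, lon1, lat2, lon2):
        if not math.isfinite(v):
            raise ValueError("coordinates must be finite")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(h)))


def haversine_matrix(
    points: Sequence[tuple[float, float]], radius_km: float = EARTH_RADIUS_KM
) -> np.ndarray:
    """Full pairwise great-circle distance matrix (km), vectorised."""
    pts = np.asarray(points, dtype=float)
    if pts.size and not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    lat = np.radians(pts[:, 0])[:, None]
    lon = np.radians(pts[:, 1])[:, None]
    dphi = lat - lat.T
    dlam = lon - lon.T
    h = np.sin(dphi / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlam / 2.0) ** 2
    np.fill_diagonal(h, 0.0)
    return 2.0 * radius_km * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def forbes_distance(assemblage_a: Iterable[str], assemblage_b: Iterable[str]) -> float:
    """Corrected-Forbes dissimilarity between two taxon sets, in [0, 1].

    With ``a`` shared taxa, ``b`` and ``c`` unique to each set and
    ``n = a + b + c``, similarity is ``a(n + sqrt(n)) /
    (a(n + sqrt(n)) + 1.5 bc)`` and the distance is its complement.
    """
    sa, sb = set(assemblage_a), set(assemblage_b)
    if not sa or not sb:
        raise ValueError("Forbes distance is undefined for an empty assemblage")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    if a == 0:
        return 1.0
    n = a + b + c
    num = a * (n + math.sqrt(n))
    return 1.0 - num / (num + 1.5 * b * c)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal
    kind: str  # "geographic_km" | "taxonomic"

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration record: merges of (left leaves, right leaves, height)."""

    leaves: tuple[str, ...]
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]

    @property
    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        node: dict[tuple[str, ...], tuple[str, float]] = {
            (leaf,): (leaf, 0.0) for leaf in self.leaves
        }
        for left, right, h in self.merges:
            ls, lh = node.pop(tuple(left))
            rs, rh = node.pop(tuple(right))
            rep = f"({ls}:{(h - lh) / 2:g},{rs}:{(h - rh) / 2:g})"
            node[tuple(sorted(left + right))] = (rep, h)
        (rep, _), = node.values()
        return rep + ";"


def distance_matrix(
    collections: Sequence[Collection],
    assemblages: Mapping[str, set[str]] | None = None,
    kind: str = "geographic_km",
) -> DistanceMatrix:
    """Build the full pairwise distance matrix of one kind.

    For ``kind="taxonomic"``, collections with an empty assemblage are
    dropped with a warning (the Forbes comparison is undefined for them).
    """
    if len(collections) < 2:
        raise ValueError("need at least two collections")
    if kind == "geographic_km":
        labels = tuple(c.collection_id for c in collections)
        values = haversine_matrix([c.point for c in collections])
        return DistanceMatrix(labels, values, kind)
    if kind == "taxonomic":
        if assemblages is None:
            raise ValueError("taxonomic distances require assemblages")
        keep = [c for c in collections if assemblages.get(c.collection_id)]
        dropped = [c.collection_id for c in collections if not assemblages.get(c.collection_id)]
        if dropped:
            warnings.warn(
                f"dropping collections with empty assemblages: {dropped}",
                stacklevel=2,
            )
        labels = tuple(c.collection_id for c in keep)
        n = len(keep)
        values = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            d = forbes_distance(assemblages[labels[i]], assemblages[labels[j]])
            values[i, j] = values[j, i] = d
        return DistanceMatrix(labels, values, kind)
    raise ValueError(f"unknown distance kind {kind!r}")


def cluster(dm: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with a deterministic lexicographic tie-break.

    Among all minimum-distance cluster pairs, the pair whose sorted leaf
    tuples compare smallest is merged first, so results are reproducible
    regardless of input order.  Linkages: ``average`` (UPGMA, default),
    ``complete``, ``single``.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(dm.labels)
    if n < 2:
        raise ValueError("clustering needs at least two leaves")

    # cluster key = sorted tuple of member leaf labels
    keys: list[tuple[str, ...]] = [(lab,) for lab in dm.labels]
    sizes: dict[tuple[str, ...], int] = {k: 1 for k in keys}
    dist: dict[frozenset, float] = {}
    for i, j in combinations(range(n), 2):
        dist[frozenset((keys[i], keys[j]))] = float(dm.values[i, j])

    merges = []
    active = sorted(keys)
    while len(active) > 1:
        best = None
        for ka, kb in combinations(active, 2):
            cand = (dist[frozenset((ka, kb))], ka, kb)
            if best is None or cand < best:
                best = cand
        h, ka, kb = best
        merges.append((ka, kb, h))
        new = tuple(sorted(ka + kb))
        na, nb = sizes.pop(ka), sizes.pop(kb)
        sizes[new] = na + nb
        active = [k for k in active if k not in (ka, kb)]
        for k in active:  # Lance-Williams update
            da = dist.pop(frozenset((ka, k)))
            db = dist.pop(frozenset((kb, k)))
            if linkage == "average":
                d = (na * da + nb * db) / (na + nb)
            elif linkage == "complete":
                d = max(da, db)
            else:
                d = min(da, db)
            dist[frozenset((new, k))] = d
        dist.pop(frozenset((ka, kb)))
        active.append(new)
        active.sort()
    return Dendrogram(leaves=tuple(dm.labels), merges=tuple(merges))


def cut(dend: Dendrogram, height: float) -> Partition:
    """Cut a dendrogram: clusters are maximal subtrees merged at <= height.

    Region labels are dense from 1, ordered by each region's smallest
    member id.
    """
    if height < 0:
        raise ValueError("cut height must be nonnegative")
    parent = {leaf: leaf for leaf in dend.leaves}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for left, right, h in dend.merges:
        if h <= height:
            ra, rb = find(left[0]), find(right[0])
            if ra != rb:
                parent[ra] = rb

    groups: dict[str, list[str]] = {}
    for leaf in dend.leaves:
        groups.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    out: Partition = {}
    for i, members in enumerate(ordered, start=1):
        for m in members:
            out[m] = i
    return out


def partition_meet(p1: Partition, p2: Partition) -> Partition:
    """Common refinement: same region iff same cluster in both partitions."""
    common = sorted(set(p1) & set(p2))
    seen: dict[tuple[int, int], int] = {}
    out: Partition = {}
    for cid in common:
        key = (p1[cid], p2[cid])
        if key not in seen:
            seen[key] = len(seen) + 1
        out[cid] = seen[key]
    return out


def delineate_bioregions(
    collections: Sequence[Collection],
    assemblages: Mapping[str, set[str]],
    geo_height_km: float = 100.0,
    tax_height: float = 0.5,
    linkage: str = "average",
) -> Partition:
    """Delineate bioregions for the collections of one time bin.

    Returns the meet of the geographic partition (cut at ``geo_height_km``)
    and the taxonomic partition (cut at ``tax_height``).  Collections with
    empty assemblages are dropped (warning).  A single collection forms a
    singleton bioregion without clustering.
    """
    if not collections:
        raise ValueError("no collections in bin")
    usable = [c for c in collections if assemblages.get(c.collection_id)]
    dropped = [c.collection_id for c in collections if not assemblages.get(c.collection_id)]
    if dropped:
        warnings.warn(f"dropping collections with empty assemblages: {dropped}", stacklevel=2)
    if not usable:
        return {}
    if len(usable) == 1:
        return {usable[0].collection_id: 1}
    geo = cut(cluster(distance_matrix(usable, kind="geographic_km"), linkage), geo_height_km)
    tax_dm = distance_matrix(usable, assemblages, kind="taxonomic")
    tax = cut(cluster(tax_dm, linkage), tax_height)
    return partition_meet(geo, tax)
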