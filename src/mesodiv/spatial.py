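"""Minimum-spanning-tree spatial-sampling proxy and range fractions.

The total MST length over all synapsid-bearing collections in a bin
measures the geographic spread of sampling; the MST length over the
collections bearing a given group, divided by that total, is the group's
sampling-normalised range fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bioregions import haversine_matrix

__all__ = ["RangeResult", "mst_length", "range_fraction"]


@dataclass(frozen=True)
class RangeResult:
    bin: str
    group: str
    n_collections: int
    mst_km: float
    total_mst_km: float
    fraction: float | None  # None when the bin total is degenerate
    present: bool = True  # False when the group is absent from the bin


def _prim_total(dist: np.ndarray) -> float:
    """Total MST weight by Prim's algorithm on a dense symmetric matrix.

    Handles zero-weight edges (co-located collections) correctly, which
    rules out sparse-graph MST routines that treat zeros as missing edges.
    The total is unique even under ties.
    """
    n = dist.shape[0]
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = dist[0].copy()
    best[0] = np.inf
    total = 0.0
    for _ in range(n - 1):
        j = int(np.argmin(best))  # lexicographic tie-break via first argmin
        total += float(best[j])
        in_tree[j] = True
        best = np.minimum(best, dist[j])
        best[in_tree] = np.inf
    return total


def mst_length(points: Sequence[tuple[float, float]]) -> float:
    """MST length in km over haversine distances; 0 for fewer than 2 points."""
    if len(points) < 2:
        return 0.0
    return _prim_total(haversine_matrix(points))


def range_fraction(
    bin_name: str,
    coords: Mapping[str, tuple[float, float]],
    group_collections: Mapping[str, set[str]],
) -> list[RangeResult]:
    """Per-group MST lengths and range fractions for one time bin.

    Parameters
    ----------
    coords:
        collection_id -> (paleo_lat, paleo_lon) for every synapsid-bearing
        collection in the bin.
    group_collections:
        group name -> ids of the collections where the group occurs; ids
        must be a subset of ``coords``.

    Notes
    -----
    An ``all`` row (fraction 1) is always emitted.  With fewer than two
    collections in the bin the fractions are undefined (``None``).  A group
    absent from the bin gets ``mst_km=0, fraction=0, present=False``.
    """
    all_ids = sorted(coords)
    total = mst_length([coords[c] for c in all_ids])
    degenerate = len(all_ids) < 2
    results = [
        RangeResult(
            bin=bin_name,
            group="all",
            n_collections=len(all_ids),
            mst_km=total,
            total_mst_km=total,
            fraction=None if degenerate else 1.0,
        )
    ]
    for group in sorted(group_collections):
        ids = sorted(group_collections[group])
        unknown = [i for i in ids if i not in coords]
        if unknown:
            raise ValueError(f"group {group!r} references unknown collections {unknown}")
        km = mst_length([coords[c] for c in ids])
        if degenerate or total == 0.0:
            frac = None
        else:
            frac = km / total
        results.append(
            RangeResult(
                bin=bin_name,
                group=group,
                n_collections=len(ids),
                mst_km=km,
                total_mst_km=total,
                fraction=frac,
                present=bool(ids),
            )
        )
    return results
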