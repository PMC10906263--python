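"""Synthetic PBDB-like occurrence worlds with known ground truth.

Worlds are built on the sphere: each time bin holds K regions whose
centroids are rejection-sampled at a minimum great-circle spacing,
collections scatter uniformly within a radius of their centroid, and each
region draws occurrences from a species pool with a configurable endemic
fraction, crown/stem split, abundance model and genus-indeterminate rate.
The emitted tables use the exact CSV dialect read by
:mod:`mesodiv.occurrences`, and the planted truth (partitions, group
labels, range fractions) rides alongside for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import spatial
from .bioregions import EARTH_RADIUS_KM, haversine_km

__all__ = ["WorldSpec", "WorldTruth", "World", "generate_world", "score_partition"]


@dataclass(frozen=True)
class WorldSpec:
    n_bins: int = 3
    K: int = 4  # regions per bin
    centroid_spacing_km: float = 1000.0
    region_radius_km: float = 50.0
    collections_per_region: int = 10
    pool_size: int = 30  # species per regional pool
    endemicity: float = 0.8  # fraction of each pool unique to its region
    group_split: float = 0.5  # fraction of species assigned to crown
    stem_region_whitelist: frozenset[int] | None = None  # region indices with stem
    abundance_model: str = "geometric"  # or "log_series"
    abundance_param: float = 0.5
    occurrences_per_collection: int | tuple[int, int] = 20
    genus_indeterminate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_bins, self.K, self.collections_per_region, self.pool_size) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.endemicity <= 1.0:
            raise ValueError("endemicity must lie in [0, 1]")
        if not 0.0 <= self.group_split <= 1.0:
            raise ValueError("group_split must lie in [0, 1]")
        if self.abundance_model not in ("geometric", "log_series"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")


@dataclass(frozen=True)
class WorldTruth:
    partitions: dict[str, dict[str, int]]  # bin -> collection_id -> region
    species_groups: dict[str, str]  # species name -> crown|stem
    region_pools: dict[str, dict[int, tuple[str, ...]]]  # bin -> region -> species
    range_fractions: dict[str, dict[str, float | None]]  # bin -> group -> fraction


@dataclass(frozen=True)
class World:
    occurrences: pd.DataFrame
    collections: pd.DataFrame
    bins: pd.DataFrame
    truth: WorldTruth

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.occurrences.to_csv(out / "occurrences.csv", index=False)
        self.collections.to_csv(out / "collections.csv", index=False)
        self.bins.to_csv(out / "bins.csv", index=False)
        rows = [
            {"bin": b, "collection_id": cid, "region": reg}
            for b, part in self.truth.partitions.items()
            for cid, reg in sorted(part.items())
        ]
        pd.DataFrame(rows).to_csv(out / "truth_partition.csv", index=False)


def _random_point(rng: np.random.Generator) -> tuple[float, float]:
    """Uniform point on the sphere as (lat, lon) degrees."""
    lon = float(rng.uniform(-180.0, 180.0))
    lat = float(np.degrees(np.arcsin(rng.uniform(-1.0, 1.0))))
    return lat, lon


def _destination(
    lat: float, lon: float, bearing_deg: float, dist_km: float
) -> tuple[float, float]:
    """Point reached travelling dist_km on the given initial bearing."""
    delta = dist_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    phi1 = math.radians(lat)
    lam1 = math.radians(lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    )
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    lon2 = math.degrees(lam2)
    lon2 = (lon2 + 180.0) % 360.0 - 180.0
    if lon2 == -180.0:
        lon2 = 180.0
    return math.degrees(phi2), lon2


def _place_centroids(
    rng: np.random.Generator, k: int, spacing_km: float, max_attempts: int = 20000
) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < k:
        cand = _random_point(rng)
        if all(haversine_km(cand, p) >= spacing_km for p in pts):
            pts.append(cand)
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {k} centroids at {spacing_km} km spacing"
            )
    return pts


def _abundance_probs(spec: WorldSpec, s: int) -> np.ndarray:
    ranks = np.arange(s)
    if spec.abundance_model == "geometric":
        w = (1.0 - spec.abundance_param) ** ranks
    else:  # log_series
        w = spec.abundance_param ** (ranks + 1) / (ranks + 1)
    return w / w.sum()


def generate_world(spec: WorldSpec) -> World:
    """Generate one synthetic world; identical specs yield identical tables."""
    rng = np.random.default_rng(spec.seed)
    species_groups: dict[str, str] = {}
    region_pools: dict[str, dict[int, tuple[str, ...]]] = {}
    partitions: dict[str, dict[str, int]] = {}
    range_fractions: dict[str, dict[str, float | None]] = {}

    occ_rows: list[dict] = []
    coll_rows: list[dict] = []
    bin_rows: list[dict] = []
    next_species = 0
    next_coll = 0
    next_occ = 0

    n_endemic = round(spec.endemicity * spec.pool_size)
    n_shared = spec.pool_size - n_endemic
    whitelist = (
        set(range(spec.K))
        if spec.stem_region_whitelist is None
        else set(spec.stem_region_whitelist)
    )

    def new_species(batch: int) -> list[str]:
        nonlocal next_species
        names = []
        for _ in range(batch):
            gid = next_species
            name = f"Synthogenus{gid:04d} specimen{gid:04d}"
            group = "crown" if rng.random() < spec.group_split else "stem"
            species_groups[name] = group
            names.append(name)
            next_species += 1
        # guarantee each batch holds at least one crown species so that
        # whitelist-restricted regions still have something to sample
        if names and all(species_groups[n] == "stem" for n in names):
            species_groups[names[0]] = "crown"
        return names

    for b in range(spec.n_bins):
        older = 250.0 - 10.0 * b
        younger = older - 10.0
        bin_name = f"bin{b:02d}"
        bin_rows.append({"name": bin_name, "older_ma": older, "younger_ma": younger})

        centroids = _place_centroids(rng, spec.K, spec.centroid_spacing_km)
        shared_pool = new_species(n_shared)
        pools: dict[int, tuple[str, ...]] = {}
        partition: dict[str, int] = {}
        coords: dict[str, tuple[float, float]] = {}
        group_colls: dict[str, set[str]] = {"crown": set(), "stem": set()}

        for r in range(spec.K):
            pool = list(shared_pool) + new_species(n_endemic)
            # abundance rank should not correlate with endemic/shared status
            pool = [pool[i] for i in rng.permutation(len(pool))]
            pools[r] = tuple(pool)
            probs = _abundance_probs(spec, len(pool))
            if r not in whitelist:
                keep = [i for i, sp in enumerate(pool) if species_groups[sp] == "crown"]
                pool = [pool[i] for i in keep]
                probs = probs[keep] / probs[keep].sum()

            for _ in range(spec.collections_per_region):
                cid = f"c{next_coll:05d}"
                next_coll += 1
                bearing = float(rng.uniform(0.0, 360.0))
                dist = spec.region_radius_km * math.sqrt(float(rng.uniform()))
                lat, lon = _destination(*centroids[r], bearing, dist)
                age_mid = float(rng.uniform(younger + 1.0, older - 1.0))
                coll_rows.append(
                    {
                        "collection_no": cid,
                        "paleolat": round(lat, 6),
                        "paleolng": round(lon, 6),
                        "max_ma": round(age_mid + 0.5, 3),
                        "min_ma": round(age_mid - 0.5, 3),
                    }
                )
                partition[cid] = r + 1
                coords[cid] = (lat, lon)

                if isinstance(spec.occurrences_per_collection, tuple):
                    lo, hi = spec.occurrences_per_collection
                    n_occ = int(rng.integers(lo, hi + 1))
                else:
                    n_occ = int(spec.occurrences_per_collection)
                picks = rng.choice(len(pool), size=n_occ, p=probs)
                for k in picks:
                    sp = pool[int(k)]
                    group = species_groups[sp]
                    group_colls[group].add(cid)
                    genus = sp.split()[0]
                    if rng.random() < spec.genus_indeterminate_rate:
                        name, rank = genus, "genus"
                    else:
                        name, rank = sp, "species"
                    occ_rows.append(
                        {
                            "occurrence_no": f"o{next_occ:06d}",
                            "collection_no": cid,
                            "accepted_name": name,
                            "accepted_rank": rank,
                            "family": f"{genus}idae",
                            "order": "Multituberculata" if group == "crown" else "Docodonta",
                            "class": "Mammalia" if group == "crown" else "Osteichthyes",
                            "paleolat": round(coords[cid][0], 6),
                            "paleolng": round(coords[cid][1], 6),
                            "max_ma": coll_rows[-1]["max_ma"],
                            "min_ma": coll_rows[-1]["min_ma"],
                        }
                    )
                    next_occ += 1

        partitions[bin_name] = partition
        region_pools[bin_name] = pools

        # planted range fractions from whitelist membership (crown occurs in
        # every region, stem only in whitelisted regions)
        total = spatial.mst_length(list(coords.values()))
        planted_stem = [coords[c] for c, r in partition.items() if (r - 1) in whitelist]
        if total > 0:
            range_fractions[bin_name] = {
                "crown": 1.0,
                "stem": spatial.mst_length(planted_stem) / total,
            }
        else:
            range_fractions[bin_name] = {"crown": None, "stem": None}

    truth = WorldTruth(
        partitions=partitions,
        species_groups=species_groups,
        region_pools=region_pools,
        range_fractions=range_fractions,
    )
    return World(
        occurrences=pd.DataFrame(occ_rows),
        collections=pd.DataFrame(coll_rows),
        bins=pd.DataFrame(bin_rows),
        truth=truth,
    )


def score_partition(
    estimated: Mapping[str, int], truth: Mapping[str, int]
) -> float:
    """Chance-adjusted agreement (adjusted Rand) between two partitions.

    Both partitions must label the same collections; 1 iff identical up to
    relabelling.
    """
    common = sorted(set(estimated) & set(truth))
    if not common:
        raise ValueError("partitions share no labelled collections")
    est = [estimated[c] for c in common]
    tru = [truth[c] for c in common]
    return float(adjusted_rand_score(tru, est))
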