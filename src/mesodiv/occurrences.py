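"""Reading, validation and annotation of PBDB-style occurrence tables.

The expected input is a flat, comma-separated occurrence download: one row
per occurrence, each row carrying its collection's paleocoordinates and age
range alongside the taxon name, rank and higher taxonomy.  Column names are
configurable through a column map so that both raw PBDB downloads and
synthetic tables can be read with the same code path.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "TaxonRank",
    "Group",
    "Occurrence",
    "Collection",
    "TimeBin",
    "Scenario",
    "SchemaError",
    "RowError",
    "DEFAULT_COLUMN_MAP",
    "read_occurrences",
    "write_occurrences",
    "read_bins",
    "load_scenario",
    "available_scenarios",
    "assign_group",
    "assign_groups",
    "assign_bins",
]


class TaxonRank(str, enum.Enum):
    species = "species"
    genus = "genus"
    above_genus = "above_genus"


class Group(str, enum.Enum):
    crown = "crown"
    stem = "stem"
    excluded = "excluded"


class SchemaError(ValueError):
    """Raised when a mapped column is missing from the input table."""


class RowError(ValueError):
    """Raised when individual rows fail validation; lists offending rows."""

    def __init__(self, message: str, rows: Sequence[int]):
        self.rows = list(rows)
        super().__init__(f"{message} (rows: {self.rows})")


@dataclass(frozen=True)
class Occurrence:
    occurrence_id: str
    collection_id: str
    taxon_name: str
    taxon_rank: TaxonRank
    lineage: tuple[str, ...] = ()  # ordered most specific -> least specific
    group: Group | None = None  # assigned per scenario, not read from file

    def __post_init__(self):
        if not self.taxon_name:
            raise ValueError("taxon_name must be non-empty")
        if self.taxon_rank is TaxonRank.species and len(self.taxon_name.split()) < 2:
            raise ValueError(
                f"species-rank name {self.taxon_name!r} is not a binomial"
            )

    @property
    def genus_name(self) -> str | None:
        """Genus component of the name (first word for species/genus ranks)."""
        if self.taxon_rank is TaxonRank.above_genus:
            return None
        return self.taxon_name.split()[0]


@dataclass(frozen=True)
class Collection:
    collection_id: str
    paleo_lat: float
    paleo_lon: float
    max_ma: float
    min_ma: float

    def __post_init__(self):
        if not (math.isfinite(self.paleo_lat) and math.isfinite(self.paleo_lon)):
            raise ValueError("paleocoordinates must be finite")
        if not -90.0 <= self.paleo_lat <= 90.0:
            raise ValueError(f"paleo_lat {self.paleo_lat} out of [-90, 90]")
        if not -180.0 < self.paleo_lon <= 180.0:
            raise ValueError(f"paleo_lon {self.paleo_lon} out of (-180, 180]")
        if not self.max_ma >= self.min_ma > 0:
            raise ValueError(
                f"require max_ma >= min_ma > 0, got [{self.max_ma}, {self.min_ma}]"
            )

    @property
    def midpoint_ma(self) -> float:
        return 0.5 * (self.max_ma + self.min_ma)

    @property
    def point(self) -> tuple[float, float]:
        return (self.paleo_lat, self.paleo_lon)


@dataclass(frozen=True)
class TimeBin:
    name: str
    older_ma: float
    younger_ma: float

    def __post_init__(self):
        if not self.older_ma > self.younger_ma:
            raise ValueError(f"bin {self.name}: older_ma must exceed younger_ma")

    def contains(self, age_ma: float) -> bool:
        """Half-open containment (older bound inclusive, younger exclusive)."""
        return self.older_ma >= age_ma > self.younger_ma

    def overlap(self, max_ma: float, min_ma: float) -> float:
        return max(0.0, min(self.older_ma, max_ma) - max(self.younger_ma, min_ma))


@dataclass(frozen=True)
class Scenario:
    name: str
    crown_clades: frozenset[str]
    stem_clades: frozenset[str]

    def __post_init__(self):
        both = self.crown_clades & self.stem_clades
        if both:
            raise ValueError(
                f"scenario {self.name}: clades mapped to both groups: {sorted(both)}"
            )


DEFAULT_COLUMN_MAP: dict[str, str] = {
    "occurrence_id": "occurrence_no",
    "collection_id": "collection_no",
    "taxon_name": "accepted_name",
    "taxon_rank": "accepted_rank",
    "paleo_lat": "paleolat",
    "paleo_lon": "paleolng",
    "max_ma": "max_ma",
    "min_ma": "min_ma",
    "family": "family",
    "order": "order",
    "class": "class",
}

_REQUIRED_KEYS = (
    "occurrence_id",
    "collection_id",
    "taxon_name",
    "taxon_rank",
    "paleo_lat",
    "paleo_lon",
    "max_ma",
    "min_ma",
)
_LINEAGE_KEYS = ("family", "order", "class")  # most specific first

_SPECIES_RANKS = {"species", "subspecies"}
_GENUS_RANKS = {"genus", "subgenus"}


def _parse_rank(raw: str) -> TaxonRank:
    r = str(raw).strip().lower()
    if r in _SPECIES_RANKS:
        return TaxonRank.species
    if r in _GENUS_RANKS:
        return TaxonRank.genus
    return TaxonRank.above_genus


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    flag_column: str | None = None,
) -> tuple[list[Occurrence], list[Collection]]:
    """Read an occurrence CSV into occurrence and collection records.

    Parameters
    ----------
    path:
        CSV file in the flat PBDB download dialect.
    column_map:
        Mapping from canonical field names (``occurrence_id``,
        ``collection_id``, ``taxon_name``, ``taxon_rank``, ``paleo_lat``,
        ``paleo_lon``, ``max_ma``, ``min_ma`` and optionally ``family``,
        ``order``, ``class``) to the column names actually present.
        Defaults to the PBDB names.
    flag_column:
        Optional column; rows whose value contains ``trace``
        (case-insensitive) are dropped as trace fossils.

    Returns
    -------
    (occurrences, collections):
        One :class:`Collection` per distinct collection id; every
        occurrence references one of them.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    missing = [cmap[k] for k in _REQUIRED_KEYS if cmap[k] not in df.columns]
    if missing:
        raise SchemaError(f"mapped columns missing from {path}: {missing}")

    if flag_column is not None:
        if flag_column not in df.columns:
            raise SchemaError(f"flag column {flag_column!r} missing from {path}")
        df = df[~df[flag_column].str.lower().str.contains("trace", na=False)]

    lineage_cols = [cmap[k] for k in _LINEAGE_KEYS if cmap.get(k) in df.columns]

    occurrences: list[Occurrence] = []
    collections: dict[str, Collection] = {}
    seen_ids: set[str] = set()
    bad_rows: list[int] = []
    bad_detail: list[str] = []

    for idx, row in df.iterrows():
        occ_id = str(row[cmap["occurrence_id"]]).strip()
        if occ_id in seen_ids:
            raise RowError(f"duplicate occurrence_id {occ_id!r}", [int(idx)])
        seen_ids.add(occ_id)

        try:
            lat = float(row[cmap["paleo_lat"]])
            lon = float(row[cmap["paleo_lon"]])
            max_ma = float(row[cmap["max_ma"]])
            min_ma = float(row[cmap["min_ma"]])
        except (TypeError, ValueError):
            bad_rows.append(int(idx))
            bad_detail.append("unparsable coordinate/age")
            continue

        coll_id = str(row[cmap["collection_id"]]).strip()
        try:
            coll = Collection(coll_id, lat, lon, max_ma, min_ma)
        except ValueError as exc:
            bad_rows.append(int(idx))
            bad_detail.append(str(exc))
            continue
        collections.setdefault(coll_id, coll)

        lineage = tuple(
            str(row[c]).strip() for c in lineage_cols if str(row[c]).strip()
        )
        try:
            occurrences.append(
                Occurrence(
                    occurrence_id=occ_id,
                    collection_id=coll_id,
                    taxon_name=str(row[cmap["taxon_name"]]).strip(),
                    taxon_rank=_parse_rank(row[cmap["taxon_rank"]]),
                    lineage=lineage,
                )
            )
        except ValueError as exc:
            bad_rows.append(int(idx))
            bad_detail.append(str(exc))

    if bad_rows:
        raise RowError("; ".join(sorted(set(bad_detail))), bad_rows)

    return occurrences, list(collections.values())


def write_occurrences(
    path: str | Path,
    occurrences: Iterable[Occurrence],
    collections: Iterable[Collection],
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write occurrences back to the flat CSV dialect (round-trip safe)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    colls = {c.collection_id: c for c in collections}
    rows = []
    for occ in occurrences:
        coll = colls[occ.collection_id]
        lin = list(occ.lineage) + ["", "", ""]
        rows.append(
            {
                cmap["occurrence_id"]: occ.occurrence_id,
                cmap["collection_id"]: occ.collection_id,
                cmap["taxon_name"]: occ.taxon_name,
                cmap["taxon_rank"]: occ.taxon_rank.value,
                cmap["paleo_lat"]: repr(coll.paleo_lat),
                cmap["paleo_lon"]: repr(coll.paleo_lon),
                cmap["max_ma"]: repr(coll.max_ma),
                cmap["min_ma"]: repr(coll.min_ma),
                cmap["family"]: lin[0],
                cmap["order"]: lin[1],
                cmap["class"]: lin[2],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bins(path: str | Path) -> list[TimeBin]:
    """Read a stage table (columns name, older_ma, younger_ma), old to young.

    Bins must be non-overlapping and ordered from oldest to youngest.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("name", "older_ma", "younger_ma") if c not in df.columns]
    if missing:
        raise SchemaError(f"bin table missing columns: {missing}")
    bins = [
        TimeBin(str(r["name"]), float(r["older_ma"]), float(r["younger_ma"]))
        for _, r in df.iterrows()
    ]
    for prev, nxt in zip(bins, bins[1:]):
        if nxt.older_ma > prev.younger_ma + 1e-9:
            raise ValueError(
                f"bins {prev.name!r} and {nxt.name!r} overlap or are out of order"
            )
    return bins


# ---------------------------------------------------------------------------
# Scenario handling


def _scenario_config() -> dict:
    ref = resources.files("mesodiv.data").joinpath("scenarios.yaml")
    return yaml.safe_load(ref.read_text())


def available_scenarios() -> list[str]:
    return sorted(_scenario_config()["scenarios"])


def load_scenario(name: str, config_path: str | Path | None = None) -> Scenario:
    """Load a named crown/stem assignment scenario.

    The shipped configuration defines ``haramiyida_crown``,
    ``haramiyida_stem`` and ``haramiyida_polyphyletic``; a user-supplied
    YAML file with the same layout can override it.
    """
    cfg = (
        yaml.safe_load(Path(config_path).read_text())
        if config_path is not None
        else _scenario_config()
    )
    # common aliases for CLI convenience
    aliases = {
        "crown": "haramiyida_crown",
        "stem": "haramiyida_stem",
        "polyphyletic": "haramiyida_polyphyletic",
    }
    name = aliases.get(name, name)
    if name not in cfg["scenarios"]:
        raise KeyError(f"unknown scenario {name!r}; have {sorted(cfg['scenarios'])}")
    sc = cfg["scenarios"][name]
    crown = set(cfg["base"]["crown"]) | set(sc.get("crown") or [])
    stem = set(cfg["base"]["stem"]) | set(sc.get("stem") or [])
    return Scenario(name, frozenset(crown), frozenset(stem))


def assign_group(occ: Occurrence, scenario: Scenario) -> Group:
    """Resolve crown/stem membership from the most specific lineage match.

    The lineage is scanned from most to least specific (the taxon's own
    name first, when it is a higher taxon); the first entry found in either
    clade set decides.  Unmatched lineages are excluded.
    """
    names: list[str] = []
    if occ.taxon_rank is TaxonRank.above_genus:
        names.append(occ.taxon_name)
    names.extend(occ.lineage)
    for name in names:
        in_crown = name in scenario.crown_clades
        in_stem = name in scenario.stem_clades
        if in_crown and in_stem:  # unreachable while Scenario enforces disjointness
            raise ValueError(f"{name!r} mapped to both groups in {scenario.name}")
        if in_crown:
            return Group.crown
        if in_stem:
            return Group.stem
    return Group.excluded


def assign_groups(
    occurrences: Iterable[Occurrence], scenario: Scenario
) -> list[Occurrence]:
    """Return occurrences with ``group`` set under the given scenario."""
    return [replace(o, group=assign_group(o, scenario)) for o in occurrences]


def assign_bins(
    coll: Collection,
    bins: Sequence[TimeBin],
    rule: str = "midpoint",
) -> str | None:
    """Assign a collection to a time bin, or ``None`` when unassignable.

    ``midpoint``: the bin containing the midpoint of the collection's age
    range.  ``majority_overlap``: the bin with the largest intersection with
    the age range, ties broken toward the older bin.
    """
    if rule == "midpoint":
        mid = coll.midpoint_ma
        for i, b in enumerate(bins):
            # oldest bin is closed at its older bound
            if b.contains(mid) or (i == 0 and mid == b.older_ma):
                return b.name
        return None
    if rule == "majority_overlap":
        best: str | None = None
        best_ov = 0.0
        for b in bins:  # bins ordered old -> young, so ties keep the older bin
            ov = b.overlap(coll.max_ma, coll.min_ma)
            if ov > best_ov:
                best, best_ov = b.name, ov
        return best
    raise ValueError(f"unknown binning rule {rule!r}")
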