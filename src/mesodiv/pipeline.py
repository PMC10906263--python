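"""End-to-end orchestration: occurrences -> bioregions -> richness/ranges.

`run` executes the full per-scenario analysis and returns tidy tables from
which the per-bioregion richness, bin means, crown proportions and MST
range-fraction series can be plotted or compared.  Every excluded
occurrence or skipped estimate is recorded in the run log with a reason
code so that inputs are fully accounted for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import bioregions as br
from . import richness as rich
from . import spatial
from .occurrences import (
    Collection,
    Group,
    Occurrence,
    Scenario,
    TimeBin,
    assign_bins,
    assign_groups,
    load_scenario,
    read_bins,
    read_occurrences,
)

__all__ = ["RunConfig", "ResultBundle", "run", "run_tables", "default_bins"]


@dataclass(frozen=True)
class RunConfig:
    occurrence_path: str | Path
    bin_path: str | Path | None = None  # None -> shipped Mesozoic stage table
    scenario: str = "haramiyida_crown"
    quorum: float = 0.9
    geo_height_km: float = 100.0
    tax_height: float = 0.5
    linkage: str = "average"
    binning_rule: str = "midpoint"
    min_n: int = 5
    max_extrapolation_factor: float = 2.0
    flag_column: str | None = None
    out_dir: str | Path | None = None
    stages: tuple[str, ...] | None = None  # restrict to named bins


@dataclass
class ResultBundle:
    bioregions: pd.DataFrame  # bin, collection_id, bioregion_id
    richness: pd.DataFrame  # bin, bioregion_id, group, n, coverage, richness, mode, status
    bin_means: pd.DataFrame  # bin, group, mean_richness, n_bioregions
    proportions: pd.DataFrame  # bin, bioregion_id, n_crown_taxa, n_stem_taxa, crown_proportion
    ranges: pd.DataFrame  # bin, group, n_collections, mst_km, total_mst_km, fraction, present
    log: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.bioregions.to_csv(out / "bioregions.csv", index=False)
        self.richness.to_csv(out / "richness.csv", index=False)
        self.bin_means.to_csv(out / "bin_means.csv", index=False)
        self.proportions.to_csv(out / "crown_proportions.csv", index=False)
        self.ranges.to_csv(out / "range_fractions.csv", index=False)
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def default_bins() -> list[TimeBin]:
    """The shipped Mesozoic stage table (current ICS ages)."""
    ref = resources.files("mesodiv.data").joinpath("mesozoic_stages.csv")
    with resources.as_file(ref) as p:
        return read_bins(p)


def run(config: RunConfig) -> ResultBundle:
    """Run the full analysis from CSV inputs under one scenario."""
    occurrences, collections = read_occurrences(
        config.occurrence_path, flag_column=config.flag_column
    )
    bins = read_bins(config.bin_path) if config.bin_path else default_bins()
    scenario = load_scenario(config.scenario)
    bundle = run_tables(occurrences, collections, bins, scenario, config)
    if config.out_dir is not None:
        bundle.write(config.out_dir)
    return bundle


def run_tables(
    occurrences: Sequence[Occurrence],
    collections: Sequence[Collection],
    bins: Sequence[TimeBin],
    scenario: Scenario,
    config: RunConfig | None = None,
) -> ResultBundle:
    """Run the analysis on already-parsed records (used by tests and CLI)."""
    cfg = config or RunConfig(occurrence_path="<memory>")
    log: list[str] = [f"scenario={scenario.name} n_occurrences={len(occurrences)}"]

    occurrences = assign_groups(occurrences, scenario)
    used = [o for o in occurrences if o.group is not Group.excluded]
    for o in occurrences:
        if o.group is Group.excluded:
            log.append(
                f"excluded\tunmatched_lineage\toccurrence={o.occurrence_id}"
                f"\ttaxon={o.taxon_name}"
            )
    log.append(
        f"groups\tcrown={sum(o.group is Group.crown for o in used)}"
        f"\tstem={sum(o.group is Group.stem for o in used)}"
        f"\texcluded={len(occurrences) - len(used)}"
    )

    colls = {c.collection_id: c for c in collections}
    coll_bin: dict[str, str | None] = {
        cid: assign_bins(c, bins, cfg.binning_rule) for cid, c in colls.items()
    }
    occ_by_bin: dict[str, list[Occurrence]] = {}
    for o in used:
        b = coll_bin[o.collection_id]
        if b is None:
            log.append(f"excluded\tunassigned_bin\toccurrence={o.occurrence_id}")
            continue
        occ_by_bin.setdefault(b, []).append(o)

    bin_order = [b.name for b in bins if b.name in occ_by_bin]
    if cfg.stages is not None:
        bin_order = [b for b in bin_order if b in cfg.stages]

    region_rows, richness_rows, prop_rows, range_rows = [], [], [], []

    for bin_name in bin_order:
        occs = occ_by_bin[bin_name]
        bin_colls = sorted({o.collection_id for o in occs})
        assemblages: dict[str, set[str]] = {c: set() for c in bin_colls}
        for o in occs:
            assemblages[o.collection_id].add(o.taxon_name)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            partition = br.delineate_bioregions(
                [colls[c] for c in bin_colls],
                assemblages,
                geo_height_km=cfg.geo_height_km,
                tax_height=cfg.tax_height,
                linkage=cfg.linkage,
            )
        for cid in sorted(partition):
            region_rows.append(
                {"bin": bin_name, "collection_id": cid, "bioregion_id": partition[cid]}
            )

        by_region: dict[int, list[Occurrence]] = {}
        for o in occs:
            if o.collection_id in partition:
                by_region.setdefault(partition[o.collection_id], []).append(o)

        for region in sorted(by_region):
            rocc = by_region[region]
            filtered = {
                Group.crown: rich.filter_taxa(
                    [o for o in rocc if o.group is Group.crown]
                ),
                Group.stem: rich.filter_taxa(
                    [o for o in rocc if o.group is Group.stem]
                ),
            }
            for group, counts in filtered.items():
                if not counts:
                    continue
                av = rich.AbundanceVector(counts)
                est = rich.richness_at_coverage(
                    av,
                    quorum=cfg.quorum,
                    max_extrapolation_factor=cfg.max_extrapolation_factor,
                    min_n=cfg.min_n,
                )
                if est.status is rich.EstimateStatus.insufficient:
                    log.append(
                        f"skipped\tinsufficient_sampling\tbin={bin_name}"
                        f"\tbioregion={region}\tgroup={group.value}\tn={av.n}"
                    )
                richness_rows.append(
                    {
                        "bin": bin_name,
                        "bioregion_id": region,
                        "group": group.value,
                        "n": av.n,
                        "coverage": rich.sample_coverage(av),
                        "richness": est.value,
                        "mode": est.mode.value if est.mode else None,
                        "status": est.status.value,
                    }
                )
            prop = rich.crown_proportion(filtered[Group.crown], filtered[Group.stem])
            if prop is not None:
                prop_rows.append(
                    {
                        "bin": bin_name,
                        "bioregion_id": region,
                        "n_crown_taxa": len(filtered[Group.crown]),
                        "n_stem_taxa": len(filtered[Group.stem]),
                        "crown_proportion": prop,
                    }
                )

        coords = {c: colls[c].point for c in bin_colls}
        group_sets = {
            "crown": {o.collection_id for o in occs if o.group is Group.crown},
            "stem": {o.collection_id for o in occs if o.group is Group.stem},
        }
        for rr in spatial.range_fraction(bin_name, coords, group_sets):
            range_rows.append(
                {
                    "bin": rr.bin,
                    "group": rr.group,
                    "n_collections": rr.n_collections,
                    "mst_km": rr.mst_km,
                    "total_mst_km": rr.total_mst_km,
                    "fraction": rr.fraction,
                    "present": rr.present,
                }
            )

    richness_df = pd.DataFrame(
        richness_rows,
        columns=["bin", "bioregion_id", "group", "n", "coverage", "richness", "mode", "status"],
    )
    bin_means = rich.bin_summaries(richness_df) if len(richness_df) else pd.DataFrame(
        columns=["bin", "group", "mean_richness", "n_bioregions"]
    )
    return ResultBundle(
        bioregions=pd.DataFrame(
            region_rows, columns=["bin", "collection_id", "bioregion_id"]
        ),
        richness=richness_df,
        bin_means=bin_means,
        proportions=pd.DataFrame(
            prop_rows,
            columns=["bin", "bioregion_id", "n_crown_taxa", "n_stem_taxa", "crown_proportion"],
        ),
        ranges=pd.DataFrame(
            range_rows,
            columns=["bin", "group", "n_collections", "mst_km", "total_mst_km", "fraction", "present"],
        ),
        log=log,
    )
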