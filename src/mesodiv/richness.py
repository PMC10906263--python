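"""Coverage-based (quorum) species-richness estimation per bioregion.

Occurrence counts per taxon are the abundance unit.  Richness is compared
at a fixed sample coverage (Good-Turing estimated), interpolating by exact
hypergeometric rarefaction below the observed sample size and extrapolating
with a Chao1-type unseen-taxon estimate up to a bounded multiple of it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .occurrences import Group, Occurrence, TaxonRank

__all__ = [
    "AbundanceVector",
    "EstimateMode",
    "EstimateStatus",
    "RichnessEstimate",
    "filter_taxa",
    "sample_coverage",
    "coverage_at_size",
    "richness_at_size",
    "richness_at_coverage",
    "bin_summaries",
    "crown_proportion",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Taxon -> occurrence-count map for one (bioregion, group)."""

    counts: Mapping[str, int]

    def __post_init__(self):
        if any(c < 1 or c != int(c) for c in self.counts.values()):
            raise ValueError("abundance counts must be positive integers")

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def f1(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)

    @property
    def f2(self) -> int:
        return sum(1 for c in self.counts.values() if c == 2)

    def as_array(self) -> np.ndarray:
        return np.asarray(sorted(self.counts.values()), dtype=float)


class EstimateMode(str, enum.Enum):
    interpolated = "interpolated"
    observed = "observed"
    extrapolated = "extrapolated"


class EstimateStatus(str, enum.Enum):
    ok = "ok"
    insufficient = "insufficient"


@dataclass(frozen=True)
class RichnessEstimate:
    value: float | None
    achieved_coverage: float | None
    n: int
    mode: EstimateMode | None
    status: EstimateStatus


def filter_taxa(occurrences: Iterable[Occurrence]) -> dict[str, int]:
    """Collapse one bioregion's occurrences to taxon occurrence counts.

    Species-rank occurrences are always retained.  A genus-rank occurrence
    is retained as its own taxon only when no species of that genus is
    retained in the same bioregion, and an above-genus occurrence only when
    no retained taxon descends from it — otherwise the coarser record is
    discarded as potentially redundant.
    """
    occs = list(occurrences)
    species = [o for o in occs if o.taxon_rank is TaxonRank.species]
    genera = [o for o in occs if o.taxon_rank is TaxonRank.genus]
    higher = [o for o in occs if o.taxon_rank is TaxonRank.above_genus]

    counts: dict[str, int] = {}
    retained: list[Occurrence] = []
    for o in species:
        counts[o.taxon_name] = counts.get(o.taxon_name, 0) + 1
        retained.append(o)

    retained_genus_names = {o.genus_name for o in retained}
    for o in genera:
        if o.genus_name not in retained_genus_names:
            counts[o.taxon_name] = counts.get(o.taxon_name, 0) + 1
            retained.append(o)

    # above-genus taxa, most specific first so that e.g. a family blocks its
    # order: U precedes T when T appears in U's lineage
    names = {o.taxon_name for o in higher}

    def depth(name: str) -> int:
        return sum(1 for o in higher if name in o.lineage and o.taxon_name != name)

    for name in sorted(names, key=lambda t: (depth(t), t)):
        group = [o for o in higher if o.taxon_name == name]
        blocked = any(
            name in r.lineage or name == r.genus_name for r in retained
        )
        if not blocked:
            counts[name] = counts.get(name, 0) + len(group)
            retained.extend(group)
    return counts


def sample_coverage(av: AbundanceVector) -> float:
    """Good-Turing coverage estimate of the full sample."""
    n = av.n
    if n < 1:
        raise ValueError("empty abundance vector")
    f1, f2 = av.f1, av.f2
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2))


def _log_comb(a: float, b: float) -> float:
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def _interp_coverage(counts: np.ndarray, n: int, m: int) -> float:
    """Exact expected coverage of a size-m subsample (0 <= m < n)."""
    if m == 0:
        return 0.0
    total = 0.0
    for x in counts:
        if n - x >= m:
            total += (x / n) * math.exp(_log_comb(n - x, m) - _log_comb(n - 1, m))
    return 1.0 - total


def _interp_richness(counts: np.ndarray, n: int, m: int) -> float:
    """Exact expected distinct-taxon count of a size-m subsample (m <= n)."""
    if m == 0:
        return 0.0
    missing = 0.0
    for x in counts:
        if n - x >= m:
            missing += math.exp(_log_comb(n - x, m) - _log_comb(n, m))
    return len(counts) - missing


def _extrapolation_slope(av: AbundanceVector) -> float:
    """Decay base B with extrapolated coverage 1 - (f1/n) B^(m*+1)."""
    n, f1, f2 = av.n, av.f1, av.f2
    if f2 > 0:
        return (n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2)
    return (n - 1) * f1 / ((n - 1) * f1 + 2.0)  # f2 -> 1 substitution


def _unseen_taxa(av: AbundanceVector) -> float:
    n, f1, f2 = av.n, av.f1, av.f2
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


def coverage_at_size(av: AbundanceVector, m: float) -> float:
    """Expected coverage at (possibly non-integer) subsample size m.

    Interpolates linearly between exact integer rarefaction values below n
    and uses the smooth Good-Turing extrapolation above n.
    """
    n = av.n
    if n < 1:
        raise ValueError("empty abundance vector")
    if m < 0:
        raise ValueError("subsample size must be nonnegative")
    counts = av.as_array()
    if m <= n:
        lo, hi = int(math.floor(m)), int(math.ceil(m))
        clo = sample_coverage(av) if lo == n else _interp_coverage(counts, n, lo)
        if hi == lo:
            return clo
        chi = sample_coverage(av) if hi == n else _interp_coverage(counts, n, hi)
        return clo + (m - lo) * (chi - clo)
    f1 = av.f1
    if f1 == 0:
        return 1.0
    b = _extrapolation_slope(av)
    return 1.0 - (f1 / n) * b ** (m - n + 1.0)


def richness_at_size(av: AbundanceVector, m: float) -> float:
    """Expected taxon richness (Hill order 0) at subsample size m."""
    n = av.n
    if n < 1:
        raise ValueError("empty abundance vector")
    if m < 0:
        raise ValueError("subsample size must be nonnegative")
    counts = av.as_array()
    if m <= n:
        lo, hi = int(math.floor(m)), int(math.ceil(m))
        rlo = _interp_richness(counts, n, lo)
        if hi == lo:
            return rlo
        rhi = _interp_richness(counts, n, hi)
        return rlo + (m - lo) * (rhi - rlo)
    f0 = _unseen_taxa(av)
    if f0 == 0.0:
        return float(av.s_obs)
    f1 = av.f1
    return av.s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** (m - n))


def richness_at_coverage(
    av: AbundanceVector,
    quorum: float = 0.9,
    max_extrapolation_factor: float = 2.0,
    min_n: int = 1,
) -> RichnessEstimate:
    """Estimate richness at the sample size where coverage hits the quorum.

    The quorum is reached by exact rarefaction below the observed size n and
    by Good-Turing extrapolation above it, bounded at
    ``max_extrapolation_factor * n``; beyond that bound (or when the
    coverage estimate cannot rise, e.g. all-singleton samples) the estimate
    is flagged ``insufficient``.
    """
    if not 0.0 < quorum < 1.0:
        raise ValueError("quorum must lie in (0, 1)")
    n = av.n
    if n < 1:
        raise ValueError("empty abundance vector")
    if n < min_n:
        return RichnessEstimate(None, None, n, None, EstimateStatus.insufficient)

    chat_n = sample_coverage(av)
    eps = 1e-12
    if chat_n >= quorum - eps:
        # quorum reachable by rarefaction (or exactly at the full sample)
        if abs(chat_n - quorum) <= 1e-9:
            return RichnessEstimate(
                float(av.s_obs), chat_n, n, EstimateMode.observed, EstimateStatus.ok
            )
        counts = av.as_array()
        prev_c = _interp_coverage(counts, n, 1)
        if prev_c >= quorum:  # cannot rarefy below one occurrence
            return RichnessEstimate(
                richness_at_size(av, 1.0), prev_c, n,
                EstimateMode.interpolated, EstimateStatus.ok,
            )
        m_hi, c_hi = None, None
        for m in range(2, n + 1):
            c = sample_coverage(av) if m == n else _interp_coverage(counts, n, m)
            if c >= quorum:
                m_hi, c_hi = m, c
                break
            prev_c = c
        t = (quorum - prev_c) / (c_hi - prev_c) if c_hi > prev_c else 0.0
        m_star = (m_hi - 1) + t
        value = richness_at_size(av, m_star)
        mode = EstimateMode.observed if m_hi == n and t >= 1.0 - 1e-9 else EstimateMode.interpolated
        return RichnessEstimate(value, quorum, n, mode, EstimateStatus.ok)

    # extrapolation branch: chat_n < quorum guarantees f1 > 0 and b < 1 here
    f1 = av.f1
    if f1 == n:  # zero estimated coverage, no valid extrapolation
        return RichnessEstimate(None, None, n, None, EstimateStatus.insufficient)
    b = _extrapolation_slope(av)
    a = f1 / n
    extra = math.log((1.0 - quorum) / a) / math.log(b) - 1.0  # solves 1 - a b^(x+1) = quorum
    if extra <= 0:
        extra = 0.0
    m_star = n + extra
    if m_star > max_extrapolation_factor * n + eps:
        return RichnessEstimate(None, None, n, None, EstimateStatus.insufficient)
    value = richness_at_size(av, m_star)
    return RichnessEstimate(value, quorum, n, EstimateMode.extrapolated, EstimateStatus.ok)


def bin_summaries(estimates) -> "pd.DataFrame":
    """Mean richness per (bin, group) over successful estimates.

    ``estimates`` is a DataFrame with columns ``bin``, ``bioregion_id``,
    ``group``, ``richness``, ``status``; rows with status != "ok" are
    excluded, and groups with no usable estimate are absent from the
    summary.
    """
    import pandas as pd

    df = pd.DataFrame(estimates)
    ok = df[df["status"] == EstimateStatus.ok.value]
    if ok.empty:
        return pd.DataFrame(columns=["bin", "group", "mean_richness", "n_bioregions"])
    out = (
        ok.groupby(["bin", "group"], sort=False)["richness"]
        .agg(mean_richness="mean", n_bioregions="size")
        .reset_index()
    )
    return out


def crown_proportion(
    crown_counts: Mapping[str, int], stem_counts: Mapping[str, int]
) -> float | None:
    """Share of retained taxa belonging to the crown, or None.

    Defined only for bioregions where both groups are present (returns
    ``None`` otherwise).  Uses raw filtered taxon counts, no subsampling.
    """
    nc, ns = len(crown_counts), len(stem_counts)
    if nc == 0 or ns == 0:
        return None
    return nc / (nc + ns)
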