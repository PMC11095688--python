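"""Standardization of eDNA and trawl data onto a common footing.

Taxa are mapped into mutually exclusive "taxonomic groups" (vertebrates at
the order level, with fish series such as Ovalentaria used where the order
is incertae sedis; invertebrates into broad phylum/suborder bins).  eDNA
samples collected within one degree latitude and two degrees longitude of a
trawl site share that site's sampling zone, and samples are binned by depth.
Community composition is quantified as the proportional occurrence of each
group: the fraction of per-sample presences (ASVs for eDNA, taxa for
trawls) belonging to the group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .tables import (
    RANKS,
    AsvCountTable,
    SampleMetadataTable,
    TaxonomyTable,
    TrawlCatchTable,
)

UNASSIGNED = "unassigned"


@dataclass
class GroupRule:
    """One ordered rule of a grouping scheme.

    ``where`` restricts the rule to lineages carrying the given names at the
    given ranks (empty = match everything).  The group label is either the
    fixed ``group`` or, with ``group_from_rank``, the lineage's name at that
    rank (rule skipped if that rank is empty).
    """

    where: dict[str, str] = field(default_factory=dict)
    group: str | None = None
    group_from_rank: str | None = None

    def apply(self, lineage: pd.Series) -> str | None:
        for rank, name in self.where.items():
            if lineage.get(rank, "") != name:
                return None
        if self.group is not None:
            return self.group
        name = lineage.get(self.group_from_rank, "")
        return name or None


@dataclass
class GroupScheme:
    rules: list[GroupRule]

    def assign(self, lineage: pd.Series) -> str:
        for rule in self.rules:
            label = rule.apply(lineage)
            if label is not None:
                return label
        return UNASSIGNED

    @classmethod
    def from_config(cls, entries: list[dict]) -> "GroupScheme":
        rules = []
        for e in entries:
            where = dict(e.get("match", {}))
            for rank in where:
                if rank not in RANKS:
                    raise ValueError(f"group rule with unknown rank {rank!r}")
            rules.append(
                GroupRule(
                    where=where,
                    group=e.get("group"),
                    group_from_rank=e.get("group_from_rank"),
                )
            )
        return cls(rules)


def default_vertebrate_scheme() -> GroupScheme:
    """Vertebrates grouped at the order level; fish series (Ovalentaria,
    Eupercaria) used for orders incertae sedis."""
    return GroupScheme(
        [
            GroupRule(where={"series": "Ovalentaria", "order": ""}, group="Ovalentaria"),
            GroupRule(where={"series": "Eupercaria", "order": ""}, group="Eupercaria"),
            GroupRule(where={"subphylum": "Vertebrata"}, group_from_rank="order"),
        ]
    )


def default_invertebrate_scheme() -> GroupScheme:
    """Invertebrates binned into broad mutually exclusive groups.

    Arthropods and cnidarians are split one level below phylum (class /
    order), everything else kept at phylum; the first matching rule wins so
    the bins stay mutually exclusive.
    """
    return GroupScheme(
        [
            GroupRule(where={"phylum": "Arthropoda"}, group_from_rank="class"),
            GroupRule(where={"phylum": "Cnidaria"}, group_from_rank="order"),
            GroupRule(where={"phylum": "Cnidaria"}, group_from_rank="class"),
            GroupRule(group_from_rank="phylum"),
        ]
    )


def assign_groups(taxonomy: TaxonomyTable, scheme: GroupScheme) -> pd.Series:
    """Map every taxonomy record to exactly one group (or "unassigned")."""
    out = {rid: scheme.assign(row) for rid, row in taxonomy.lineages.iterrows()}
    return pd.Series(out, name="group")


# ---------------------------------------------------------------------------
# zones


@dataclass
class ZoneAssignment:
    assignments: pd.Series  # sample_id -> zone id or None
    zones: pd.DataFrame  # index: zone id; columns lat, lon, dlat, dlon

    def samples_in(self, zone: str) -> list[str]:
        return list(self.assignments.index[self.assignments == zone])


def assign_zones(
    metadata: SampleMetadataTable,
    trawl_sites: pd.DataFrame,
    dlat: float = 1.0,
    dlon: float = 2.0,
) -> ZoneAssignment:
    """Assign samples to the zone of any trawl site within +-dlat / +-dlon.

    ``trawl_sites`` is indexed by zone id with ``latitude``/``longitude``
    columns (one row per site).  When a sample falls inside several boxes the
    nearer center wins under the coordinate-normalized Chebyshev distance
    max(|dlat|/dlat, |dlon|/dlon), which makes the choice independent of
    site ordering.
    """
    if trawl_sites.empty:
        raise ValueError("trawl_sites must be non-empty")
    md = metadata.data
    result = {}
    for sid in md.index:
        lat, lon = md.at[sid, "latitude"], md.at[sid, "longitude"]
        best, best_d = None, math.inf
        for zone, site in trawl_sites.iterrows():
            d = max(
                abs(lat - site["latitude"]) / dlat,
                abs(lon - site["longitude"]) / dlon,
            )
            if d <= 1.0 and (d < best_d or (d == best_d and str(zone) < str(best))):
                best, best_d = zone, d
        result[sid] = best
    zones = trawl_sites[["latitude", "longitude"]].copy()
    zones["dlat"] = dlat
    zones["dlon"] = dlon
    return ZoneAssignment(
        assignments=pd.Series(result, name="zone"), zones=zones
    )


# ---------------------------------------------------------------------------
# depth bins


@dataclass
class DepthBinScheme:
    """Ordered, non-overlapping (lower, upper] depth bins covering (0, inf).

    Intervals are lower-open/upper-closed, so 200 m falls in a 0-200 bin and
    600 m in a 200-600 bin, with a final strictly-greater-than bin.
    """

    bins: list[tuple[str, float, float]]  # (label, lower, upper]

    def __post_init__(self) -> None:
        lows = [b[1] for b in self.bins]
        ups = [b[2] for b in self.bins]
        if lows[0] != 0 or not math.isinf(ups[-1]):
            raise ValueError("bins must cover (0, inf)")
        for (_, _, u1), (_, l2, _) in zip(self.bins, self.bins[1:]):
            if u1 != l2:
                raise ValueError("bins must be contiguous and ordered")

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bins]

    def bin(self, depth: float) -> str:
        if depth < 0:
            raise ValueError("depth must be >= 0")
        for label, lo, up in self.bins:
            if (depth > lo or depth == 0) and depth <= up:
                return label
        raise AssertionError("unreachable: bins cover (0, inf)")


INF = math.inf

#: shallow/deep scheme used when comparing eDNA with trawl nets
COMPARISON_BINS = DepthBinScheme([("shallow", 0.0, 200.0), ("deep", 200.0, INF)])

#: three depth groups bounded by the daytime / nighttime deep scattering
#: layer depths (~200 m and ~600 m)
PROFILE_BINS = DepthBinScheme(
    [("0-200", 0.0, 200.0), ("200-600", 200.0, 600.0), (">600", 600.0, INF)]
)

#: mapping bins used for the cluster distribution contours, per marker
MAPPING_BINS_12S = DepthBinScheme([("shallow", 0.0, 120.0), ("deep", 120.0, INF)])
MAPPING_BINS_COI = DepthBinScheme([("shallow", 0.0, 120.0), ("deep", 120.0, INF)])


def bin_depth(depth: float, scheme: DepthBinScheme) -> str:
    return scheme.bin(depth)


# ---------------------------------------------------------------------------
# diel classification


def classify_diel(
    timestamp: datetime,
    sunrise: datetime | None,
    sunset: datetime | None,
    margin_minutes: float = 90.0,
) -> str:
    """Classify a collection time as night, day, transitional or unknown.

    Night runs from ``margin_minutes`` after sunset to ``margin_minutes``
    before sunrise; day from the same margin after sunrise to the margin
    before sunset; the crepuscular windows in between are transitional.
    Times are compared modulo 24 h so the classification is invariant to
    representing the same clock time on either side of midnight.
    """
    if sunrise is None or sunset is None or pd.isna(sunrise) or pd.isna(sunset):
        return "unknown"
    margin = timedelta(minutes=margin_minutes)
    day = timedelta(days=1)

    def tod(t: datetime) -> timedelta:
        return timedelta(hours=t.hour, minutes=t.minute, seconds=t.second)

    t = tod(timestamp)
    rise, sett = tod(sunrise), tod(sunset)
    night_start = (sett + margin) % day
    night_end = (rise - margin) % day
    day_start = (rise + margin) % day
    day_end = (sett - margin) % day

    def in_window(x: timedelta, start: timedelta, end: timedelta) -> bool:
        if start <= end:
            return start <= x <= end
        return x >= start or x <= end  # window wraps midnight

    if in_window(t, night_start, night_end):
        return "night"
    if in_window(t, day_start, day_end):
        return "day"
    return "transitional"


def classify_diel_samples(metadata: SampleMetadataTable) -> pd.Series:
    md = metadata.data
    out = {
        sid: classify_diel(
            md.at[sid, "timestamp"], md.at[sid, "sunrise"], md.at[sid, "sunset"]
        )
        for sid in md.index
    }
    return pd.Series(out, name="diel")


# ---------------------------------------------------------------------------
# proportional occurrence


@dataclass
class ProportionalOccurrenceMatrix:
    values: pd.DataFrame  # unit ids x group labels, fractions summing to 1
    unit_kind: str = "sample"

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and ((v < -1e-12) | (v > 1 + 1e-12)).any():
            raise ValueError("proportional occurrences must lie in [0, 1]")

    @property
    def groups(self) -> list[str]:
        return list(self.values.columns)


def proportional_occurrence_edna(
    table: AsvCountTable, group_map: pd.Series
) -> ProportionalOccurrenceMatrix:
    """Per-sample fraction of present ASVs belonging to each group.

    Presence means count > 0.  ASVs mapping to "unassigned" (or missing from
    the group map) are excluded from both numerator and denominator.
    Samples with zero grouped presences are dropped (flagged downstream).
    """
    groups = group_map.reindex(table.counts.index).fillna(UNASSIGNED)
    keep = groups != UNASSIGNED
    presence = (table.counts.loc[keep] > 0).astype(float)
    tallies = presence.groupby(groups[keep]).sum().T  # samples x groups
    totals = tallies.sum(axis=1)
    tallies = tallies.loc[totals > 0]
    po = tallies.div(tallies.sum(axis=1), axis=0)
    return ProportionalOccurrenceMatrix(values=po, unit_kind="sample")


def proportional_occurrence_trawl(
    trawl: TrawlCatchTable, group_map: pd.Series
) -> ProportionalOccurrenceMatrix:
    """Per-net fraction of present taxa belonging to each group."""
    d = trawl.data[trawl.data["count"] > 0]
    g = group_map.reindex(d["taxon_id"]).fillna(UNASSIGNED).to_numpy()
    d = d.assign(group=g)
    d = d[d["group"] != UNASSIGNED]
    # taxa, not individuals, are the counting unit
    tallies = (
        d.drop_duplicates(["net_id", "taxon_id"])
        .groupby(["net_id", "group"], sort=False)
        .size()
        .unstack(fill_value=0)
        .astype(float)
    )
    po = tallies.div(tallies.sum(axis=1), axis=0)
    return ProportionalOccurrenceMatrix(values=po, unit_kind="net")


def aggregate_units(
    po: ProportionalOccurrenceMatrix,
    unit_of: pd.Series,
    mode: str = "mean",
    presence_source: pd.DataFrame | None = None,
) -> ProportionalOccurrenceMatrix:
    """Aggregate sample rows into method x zone x depth-bin units.

    ``unit_of`` maps sample/net id to a unit label (NaN rows are dropped
    with a note).  Mode "mean" averages rows then renormalizes; "pool"
    recomputes fractions from pooled group presence counts, which requires
    ``presence_source`` (per-sample group presence counts).
    """
    units = unit_of.reindex(po.values.index)
    keep = units.notna()
    if mode == "mean":
        agg = po.values.loc[keep].groupby(units[keep]).mean()
        agg = agg.div(agg.sum(axis=1), axis=0)
    elif mode == "pool":
        if presence_source is None:
            raise ValueError("pool mode needs per-sample presence counts")
        src = presence_source.reindex(po.values.index).loc[keep]
        agg = src.groupby(units[keep]).sum()
        agg = agg.div(agg.sum(axis=1), axis=0)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    agg = agg.dropna(how="all")
    return ProportionalOccurrenceMatrix(values=agg, unit_kind="aggregate")


def method_group_overlap(
    po_edna: ProportionalOccurrenceMatrix, po_trawl: ProportionalOccurrenceMatrix
) -> tuple[set[str], set[str], set[str]]:
    """Partition groups into (shared, eDNA-only, trawl-only) by any nonzero
    occurrence per method."""
    e = {g for g in po_edna.groups if (po_edna.values[g] > 0).any()}
    t = {g for g in po_trawl.groups if (po_trawl.values[g] > 0).any()}
    return e & t, e - t, t - e
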