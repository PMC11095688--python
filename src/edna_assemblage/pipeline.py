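"""End-to-end orchestration of the analysis stages.

These functions connect the modules into the study's three analyses:

* method comparison — proportional-occurrence composition of eDNA and
  trawl units aggregated per zone and depth bin, compared with a Mantel
  test on Morisita-Horn dissimilarities;
* depth profiles — per-sample eDNA metrics tested across depth groups;
* assemblage biogeography — night-only species-presence clustering with
  Ward's criterion on Jaccard dissimilarities, silhouette cohesion, and
  per-cluster summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as cl
from . import stats as st
from .decontam import DecontaminationConfig, DecontaminationReport, decontaminate
from .depth import DepthComparison, depth_comparison, depth_metrics_table
from .standardize import (
    COMPARISON_BINS,
    PROFILE_BINS,
    DepthBinScheme,
    GroupScheme,
    ZoneAssignment,
    aggregate_units,
    assign_groups,
    assign_zones,
    classify_diel_samples,
    default_invertebrate_scheme,
    default_vertebrate_scheme,
    method_group_overlap,
    proportional_occurrence_edna,
    proportional_occurrence_trawl,
)
from .tables import (
    AsvCountTable,
    SampleMetadataTable,
    TaxonomyTable,
    TrawlCatchTable,
)


def combined_group_scheme() -> GroupScheme:
    """Vertebrate order-level rules first, then invertebrate bins."""
    v = default_vertebrate_scheme()
    i = default_invertebrate_scheme()
    return GroupScheme(v.rules + i.rules)


@dataclass
class MethodComparisonResult:
    mantel: st.MantelResult
    units: list[str]
    po_edna: pd.DataFrame
    po_trawl: pd.DataFrame
    shared_groups: set[str]
    edna_only: set[str]
    trawl_only: set[str]
    zones: ZoneAssignment


def compare_methods(
    tables: list[AsvCountTable],
    trawl: TrawlCatchTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadataTable,
    bin_scheme: DepthBinScheme = COMPARISON_BINS,
    n_perm: int = 999,
    seed: int | None = None,
) -> MethodComparisonResult:
    """Mantel comparison of eDNA and trawl communities on shared units.

    eDNA samples within one degree latitude / two degrees longitude of a
    trawl site share its zone; within zones both methods are aggregated
    into shallow/deep depth bins.  Composition is the proportional
    occurrence over the combined taxonomic-group scheme; the correlation
    between the two methods' Morisita-Horn dissimilarity structures is
    tested by permutation.
    """
    scheme = combined_group_scheme()
    group_map = assign_groups(taxonomy, scheme)

    # zone sites: one per trawl zone (mean net position per zone label)
    sites = trawl.net_sites()
    sites["zone"] = [
        f"zone{i}" for i in pd.factorize(
            sites[["latitude", "longitude"]].apply(tuple, axis=1)
        )[0]
    ]
    zone_sites = sites.groupby("zone")[["latitude", "longitude"]].mean()
    zones = assign_zones(metadata, zone_sites)

    # eDNA: pool group-presence tallies across markers per water sample
    tallies = []
    for t in tables:
        po = proportional_occurrence_edna(t, group_map)
        # recover integer tallies for cross-marker pooling
        groups = group_map.reindex(t.counts.index).fillna("unassigned")
        keep = groups != "unassigned"
        pres = (t.counts.loc[keep] > 0).astype(float)
        tallies.append(pres.groupby(groups[keep]).sum().T)
    tally = pd.concat(tallies, axis=1).T.groupby(level=0).sum().T
    tally = tally.loc[tally.sum(axis=1) > 0]
    po_samples = tally.div(tally.sum(axis=1), axis=0)

    md = metadata.data
    def edna_unit(sid: str):
        z = zones.assignments.get(sid)
        if z is None or pd.isna(md.at[sid, "depth"]):
            return np.nan
        return f"{z}|{bin_scheme.bin(float(md.at[sid, 'depth']))}"

    unit_of = pd.Series({sid: edna_unit(sid) for sid in po_samples.index})
    from .standardize import ProportionalOccurrenceMatrix

    po_e = aggregate_units(
        ProportionalOccurrenceMatrix(po_samples), unit_of, mode="mean"
    )

    po_t_nets = proportional_occurrence_trawl(trawl, group_map)
    net_zone = sites["zone"]
    net_bin = sites.apply(lambda r: bin_scheme.bin(float(r["depth_mid"])), axis=1)
    net_unit = pd.Series(
        {n: f"{net_zone[n]}|{net_bin[n]}" for n in po_t_nets.values.index}
    )
    po_t = aggregate_units(po_t_nets, net_unit, mode="mean")

    units = sorted(set(po_e.values.index) & set(po_t.values.index))
    if len(units) < 3:
        raise ValueError(
            f"only {len(units)} shared method units; need >= 3 for a Mantel test"
        )
    all_groups = sorted(set(po_e.values.columns) | set(po_t.values.columns))
    e = po_e.values.reindex(index=units, columns=all_groups, fill_value=0.0)
    t = po_t.values.reindex(index=units, columns=all_groups, fill_value=0.0)
    d_e = st.pairwise(e, "morisita-horn")
    d_t = st.pairwise(t, "morisita-horn")
    mantel_res = st.mantel(d_e, d_t, n_perm=n_perm, seed=seed)

    shared, e_only, t_only = method_group_overlap(
        ProportionalOccurrenceMatrix(e), ProportionalOccurrenceMatrix(t)
    )
    return MethodComparisonResult(
        mantel=mantel_res,
        units=units,
        po_edna=e,
        po_trawl=t,
        shared_groups=shared,
        edna_only=e_only,
        trawl_only=t_only,
        zones=zones,
    )


@dataclass
class ClusteringResult:
    marker: str
    presence: cl.PresenceMatrix
    dendrogram: cl.Dendrogram
    wss: pd.Series
    silhouette_by_k: pd.Series
    k: int
    k_source: str  # "elbow" | "override"
    solution: cl.ClusterSolution
    summary: dict
    accumulation: dict  # cluster -> AccumulationCurve
    regions: dict = field(default_factory=dict)  # (cluster, bin) -> DensityRegion
    notes: list[str] = field(default_factory=list)


def cluster_assemblages(
    table: AsvCountTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadataTable,
    k: int | None = None,
    min_samples: int = 3,
    k_max: int = 8,
    diel_filter: str | None = "night",
    drop_clades: list[tuple[str, str]] | None = None,
    accumulation_perms: int = 100,
    seed: int | None = None,
    compute_regions: bool = False,
    mapping_bins: DepthBinScheme | None = None,
) -> ClusteringResult:
    """Night-only, species-level presence clustering of one marker.

    Mammal and bird ASVs are dropped from the 12S dataset by default to
    focus on fishes and zooplankton.  The number of clusters comes from the
    elbow (maximum second difference) of the within-cluster sum-of-squares
    curve, cross-checked against the mean-silhouette curve, unless ``k``
    overrides it.
    """
    if drop_clades is None and table.marker == "12S":
        drop_clades = [("class", "Mammalia"), ("class", "Aves")]
    diel = classify_diel_samples(metadata)
    presence = cl.build_presence_matrix(
        table,
        taxonomy,
        diel=diel,
        min_samples=min_samples,
        drop_clades=drop_clades or [],
        diel_filter=diel_filter,
    )
    d = st.pairwise(presence.values.astype(int), "jaccard")
    dend = cl.ward_cluster(d)
    k_max_eff = min(k_max, len(presence.sample_ids) - 1)
    wss = cl.wss_curve(d, dend, k_max_eff)
    sil_by_k = {}
    for kk in range(2, k_max_eff + 1):
        labels = cl.cut_clusters(dend, kk)
        sil_by_k[kk] = float(cl.silhouette_widths(d, labels).mean())
    sil_by_k = pd.Series(sil_by_k, name="mean_silhouette")

    notes: list[str] = []
    if k is None:
        k_wss, warn = cl.choose_k_elbow(wss)
        notes += warn
        # elbow on the silhouette curve: maximize mean width
        k_sil = int(sil_by_k.idxmax()) if len(sil_by_k) else k_wss
        if k_sil != k_wss:
            notes.append(
                f"WSS elbow k={k_wss} and silhouette optimum k={k_sil} disagree; "
                "using the WSS elbow (override with k=)"
            )
        k = max(k_wss, 2)
        k_source = "elbow"
    else:
        k_source = "override"

    solution = cl.solve_clusters(d, dend, k)
    summary = cl.cluster_summary(presence, solution.labels)
    accumulation = {}
    for c in sorted(solution.labels.unique()):
        sub = presence.values.loc[solution.labels == c]
        accumulation[int(c)] = st.species_accumulation(
            sub.to_numpy(), n_perm=accumulation_perms, seed=seed
        )

    result = ClusteringResult(
        marker=table.marker,
        presence=presence,
        dendrogram=dend,
        wss=wss,
        silhouette_by_k=sil_by_k,
        k=k,
        k_source=k_source,
        solution=solution,
        summary=summary,
        accumulation=accumulation,
        notes=notes,
    )
    if compute_regions:
        bins = mapping_bins or DepthBinScheme(
            [("shallow", 0.0, 120.0), ("deep", 120.0, float("inf"))]
        )
        md = metadata.data
        for c, ok in solution.cohesive.items():
            if not ok:
                continue
            members = solution.labels.index[solution.labels == c]
            for lab in bins.labels:
                pts = np.array(
                    [
                        (md.at[s, "longitude"], md.at[s, "latitude"])
                        for s in members
                        if not pd.isna(md.at[s, "depth"])
                        and bins.bin(float(md.at[s, "depth"])) == lab
                    ]
                )
                if len(pts) >= 5 and np.ptp(pts[:, 0]) > 0 and np.ptp(pts[:, 1]) > 0:
                    try:
                        result.regions[(int(c), lab)] = cl.density_region_50(pts)
                    except (ValueError, AssertionError) as exc:
                        result.notes.append(
                            f"cluster {c} bin {lab}: no density region ({exc})"
                        )
    return result


@dataclass
class PipelineResult:
    cleaned: dict  # marker -> AsvCountTable
    reports: dict  # marker -> DecontaminationReport
    comparison: MethodComparisonResult | None
    depth: dict  # marker -> dict[str, DepthComparison]
    clustering: dict  # marker -> ClusteringResult


def run_pipeline(
    asv_tables: list[AsvCountTable],
    taxonomy: TaxonomyTable,
    metadata: SampleMetadataTable,
    trawl: TrawlCatchTable | None = None,
    seed: int | None = None,
    k: int | None = None,
    decontam_config: DecontaminationConfig | None = None,
) -> PipelineResult:
    """Decontaminate each marker then run the three analyses."""
    cleaned, reports = {}, {}
    for t in asv_tables:
        c, r = decontaminate(t, taxonomy, metadata, decontam_config)
        cleaned[t.marker] = c
        reports[t.marker] = r

    comparison = None
    if trawl is not None and len(trawl.data):
        try:
            comparison = compare_methods(
                list(cleaned.values()), trawl, taxonomy, metadata, seed=seed
            )
        except ValueError:
            comparison = None

    depth_results = {}
    for marker, t in cleaned.items():
        try:
            metrics = depth_metrics_table(t, taxonomy, metadata, PROFILE_BINS)
            depth_results[marker] = depth_comparison(metrics, PROFILE_BINS)
        except ValueError:
            depth_results[marker] = {}

    clustering = {}
    for marker, t in cleaned.items():
        try:
            clustering[marker] = cluster_assemblages(
                t, taxonomy, metadata, k=k, seed=seed
            )
        except ValueError:
            clustering[marker] = None
    return PipelineResult(
        cleaned=cleaned,
        reports=reports,
        comparison=comparison,
        depth=depth_results,
        clustering=clustering,
    )
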