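"""Per-sample depth metrics and depth-group statistical comparisons.

Four metrics are computed per environmental sample after decontamination:
the volume-corrected DNA concentration (measured concentration scaled to a
1000 mL filtered volume), sequencing reads per mL, ASVs per mL, and the
proportion of present ASVs identified to species level.  Each metric is
then compared across depth groups through the rank-based test battery in
:mod:`edna_assemblage.stats` (Kruskal-Wallis when groups screen as
homoscedastic, otherwise Welch's ANOVA on ranks with Games-Howell post hoc
comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .standardize import PROFILE_BINS, DepthBinScheme
from .stats import DepthTestDecision, select_depth_test
from .tables import AsvCountTable, SampleMetadataTable, TaxonomyTable

METRICS = (
    "dna_concentration_per_l",
    "reads_per_ml",
    "asvs_per_ml",
    "prop_asvs_to_species",
)


def volume_corrected_concentration(measured: float, volume: float) -> float:
    """Measured DNA concentration scaled to a standard 1000 mL volume.

    ``measured * (1000 mL / volume)``; identity at 1000 mL.  Below-detection
    samples must be excluded before calling (they are excluded from the
    analysis, never zeroed).
    """
    if not volume > 0:
        raise ValueError("volume must be positive")
    if measured is None or np.isnan(measured):
        raise ValueError("measured concentration unavailable (below detection?)")
    return float(measured) * 1000.0 / float(volume)


def per_ml_metrics(
    table: AsvCountTable, metadata: SampleMetadataTable
) -> pd.DataFrame:
    """Reads per mL and present-ASVs per mL for every sample in the table.

    Samples missing a filtered volume are excluded with a note column.
    """
    md = metadata.data
    rows = {}
    for sid in table.sample_ids:
        if sid not in md.index or pd.isna(md.at[sid, "volume"]):
            continue
        vol = float(md.at[sid, "volume"])
        col = table.counts[sid]
        rows[sid] = {
            "reads_per_ml": float(col.sum()) / vol,
            "asvs_per_ml": float((col > 0).sum()) / vol,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def proportion_asvs_to_species(
    table: AsvCountTable, taxonomy: TaxonomyTable
) -> pd.Series:
    """Fraction of present ASVs per sample with a species-level assignment.

    ASVs missing from the taxonomy count as not species-level; samples with
    zero present ASVs are omitted (the ratio is undefined).
    """
    deepest = taxonomy.deepest_ranks.reindex(table.counts.index)
    is_species = (deepest == "species").to_numpy()
    out = {}
    for sid in table.sample_ids:
        present = (table.counts[sid] > 0).to_numpy()
        n = int(present.sum())
        if n == 0:
            continue
        out[sid] = float((present & is_species).sum()) / n
    return pd.Series(out, name="prop_asvs_to_species")


def asvs_per_species(
    table: AsvCountTable, taxonomy: TaxonomyTable, group_map: pd.Series
) -> pd.DataFrame:
    """Mean +- sd of the number of ASVs per species, per taxonomic group.

    A species' ASV count is the number of distinct ASVs assigned to it
    anywhere in the table.  The sd is the n-1 sample standard deviation;
    single-species groups report sd 0 with ``sd_defined`` False.
    """
    lin = taxonomy.lineages
    known = table.counts.index.intersection(lin.index)
    species_of = lin.loc[known, "species"]
    species_of = species_of[species_of != ""]
    counts = species_of.groupby(species_of).size()  # ASVs per species
    group_of_species = {}
    for asv, sp in species_of.items():
        group_of_species.setdefault(sp, group_map.get(asv, "unassigned"))
    rows = []
    df = pd.DataFrame(
        {
            "species": counts.index,
            "n_asvs": counts.to_numpy(),
            "group": [group_of_species[s] for s in counts.index],
        }
    )
    for group, sub in df.groupby("group"):
        if group == "unassigned":
            continue
        vals = sub["n_asvs"].to_numpy(dtype=float)
        rows.append(
            {
                "group": group,
                "n_species": len(vals),
                "mean_asvs_per_species": float(vals.mean()),
                "sd_asvs_per_species": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "sd_defined": len(vals) > 1,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def depth_metrics_table(
    table: AsvCountTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadataTable,
    bin_scheme: DepthBinScheme = PROFILE_BINS,
) -> pd.DataFrame:
    """Assemble the per-sample metric table with depth-group labels.

    Uses only environmental samples present in the (decontaminated,
    read-thresholded) count table.  DNA concentration is volume-corrected;
    below-detection samples carry NaN there and are excluded from that
    metric's comparison, never zeroed.
    """
    md = metadata.data
    per_ml = per_ml_metrics(table, metadata)
    prop = proportion_asvs_to_species(table, taxonomy)
    rows = {}
    for sid in table.sample_ids:
        if sid not in md.index or md.at[sid, "is_control"]:
            continue
        depth = md.at[sid, "depth"]
        if pd.isna(depth):
            continue
        conc = np.nan
        if not md.at[sid, "below_detection"] and not pd.isna(
            md.at[sid, "dna_concentration"]
        ):
            conc = volume_corrected_concentration(
                float(md.at[sid, "dna_concentration"]), float(md.at[sid, "volume"])
            )
        rows[sid] = {
            "depth": float(depth),
            "depth_group": bin_scheme.bin(float(depth)),
            "dna_concentration_per_l": conc,
            "reads_per_ml": per_ml["reads_per_ml"].get(sid, np.nan),
            "asvs_per_ml": per_ml["asvs_per_ml"].get(sid, np.nan),
            "prop_asvs_to_species": prop.get(sid, np.nan),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class DepthComparison:
    metric: str
    decision: DepthTestDecision
    group_sizes: dict[str, int]
    excluded: int


def depth_comparison(
    metrics: pd.DataFrame,
    bin_scheme: DepthBinScheme = PROFILE_BINS,
    alpha: float = 0.05,
) -> dict[str, DepthComparison]:
    """Compare every metric across depth groups.

    Samples with an undefined value for a metric are excluded from that
    metric only (and counted).  A metric observed in fewer than two depth
    groups raises, naming the metric.
    """
    out = {}
    for metric in METRICS:
        if metric not in metrics.columns:
            continue
        sub = metrics[["depth_group", metric]].dropna()
        groups = {
            lab: sub.loc[sub["depth_group"] == lab, metric].to_numpy()
            for lab in bin_scheme.labels
            if (sub["depth_group"] == lab).any()
        }
        if len(groups) < 2:
            raise ValueError(
                f"metric {metric!r}: need >=2 non-empty depth groups, got {len(groups)}"
            )
        decision = select_depth_test(groups, alpha=alpha)
        out[metric] = DepthComparison(
            metric=metric,
            decision=decision,
            group_sizes={k: len(v) for k, v in groups.items()},
            excluded=int(len(metrics) - len(sub)),
        )
    return out


def depth_comparison_to_dict(comparisons: dict[str, DepthComparison]) -> dict:
    """JSON-ready summary mirroring the global + post hoc test layout."""
    out = {}
    for metric, comp in comparisons.items():
        d = comp.decision
        block = {
            "test": d.chosen,
            "statistic": d.result.statistic,
            "df": d.result.df,
            "p": d.result.p,
            "group_sizes": comp.group_sizes,
            "excluded_samples": comp.excluded,
            "shapiro_p": d.shapiro_p,
            "brown_forsythe_p": d.levene_p,
            "notes": d.notes,
        }
        if d.posthoc:
            block["pairwise"] = [
                {
                    "groups": list(r.groups),
                    "t": r.statistic,
                    "df": r.df,
                    "p": r.p,
                }
                for r in d.posthoc
            ]
        out[metric] = block
    return out
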