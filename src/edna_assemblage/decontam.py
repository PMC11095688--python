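"""Post-denoising sample and ASV filters.

The canonical order is: low-read sample threshold, non-marine blocklist,
clade removal (vertebrates from COI), negative-control ASV removal per
cruise, and finally exclusion of samples whose measured DNA concentration
was below detection.  Each step logs how many samples, ASVs and reads it
removed, and the report checks read/ASV/sample conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    RANKS,
    AsvCountTable,
    SampleMetadataTable,
    TableFormatError,
    TaxonomyTable,
)

#: Non-marine taxa removed from the 12S dataset as likely contamination.
DEFAULT_BLOCKLIST_12S = (
    ("order", "Primates"),
    ("order", "Galliformes"),
    ("order", "Rodentia"),
    ("family", "Bovidae"),
    ("family", "Suidae"),
    ("order", "Chiroptera"),
    ("order", "Cypriniformes"),
)

#: Bivalve species observed at high read counts in samples and controls of
#: the COI dataset but not known from the study region.
DEFAULT_BLOCKLIST_COI = (
    ("species", "Bathymodiolus japonicus"),
    ("species", "Saccostrea malabonensis"),
    ("species", "Abyssogena phaseoliformis"),
)


@dataclass
class Blocklist:
    marker: str
    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for rank, name in self.entries:
            if rank not in RANKS:
                raise TableFormatError(f"blocklist rank {rank!r} not recognized")
            if not name:
                raise TableFormatError("blocklist entry with empty name")


def default_blocklist(marker: str) -> Blocklist:
    entries = DEFAULT_BLOCKLIST_12S if marker == "12S" else DEFAULT_BLOCKLIST_COI
    return Blocklist(marker=marker, entries=entries)


@dataclass
class StepReport:
    label: str
    samples_removed: int = 0
    asvs_removed: int = 0
    reads_removed: int = 0
    notes: list[str] = field(default_factory=list)


@dataclass
class DecontaminationReport:
    marker: str
    initial_samples: int
    initial_asvs: int
    initial_reads: int
    steps: list[StepReport] = field(default_factory=list)
    final_samples: int = 0
    final_asvs: int = 0
    final_reads: int = 0
    excluded_samples: list[str] = field(default_factory=list)

    def conserved(self) -> bool:
        """Initial totals minus per-step removals must equal final totals."""
        reads = self.initial_reads - sum(s.reads_removed for s in self.steps)
        asvs = self.initial_asvs - sum(s.asvs_removed for s in self.steps)
        samples = self.initial_samples - sum(s.samples_removed for s in self.steps)
        return (
            reads == self.final_reads
            and asvs == self.final_asvs
            and samples == self.final_samples
        )

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "initial": {
                "samples": self.initial_samples,
                "asvs": self.initial_asvs,
                "reads": self.initial_reads,
            },
            "steps": [
                {
                    "label": s.label,
                    "samples_removed": s.samples_removed,
                    "asvs_removed": s.asvs_removed,
                    "reads_removed": s.reads_removed,
                    "notes": s.notes,
                }
                for s in self.steps
            ],
            "final": {
                "samples": self.final_samples,
                "asvs": self.final_asvs,
                "reads": self.final_reads,
            },
            "excluded_samples": self.excluded_samples,
        }


def _step(label: str, before: AsvCountTable, after: AsvCountTable) -> StepReport:
    return StepReport(
        label=label,
        samples_removed=len(before.sample_ids) - len(after.sample_ids),
        asvs_removed=len(before.asv_ids) - len(after.asv_ids),
        reads_removed=before.total_reads - after.total_reads,
    )


def drop_low_read_samples(
    table: AsvCountTable, threshold: int = 1000
) -> tuple[AsvCountTable, StepReport]:
    """Remove samples with fewer than ``threshold`` total reads.

    The comparison is strict: a sample with exactly ``threshold`` reads is
    kept.  ASV rows are left untouched even if they become all-zero.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sums = table.counts.sum(axis=0)
    drop = list(sums.index[sums < threshold])
    after = table.drop_samples(drop)
    return after, _step("low-read-samples", table, after)


def remove_blocklisted_taxa(
    table: AsvCountTable, taxonomy: TaxonomyTable, blocklist: Blocklist
) -> tuple[AsvCountTable, StepReport]:
    """Remove every ASV whose lineage matches any blocklist (rank, name)."""
    if blocklist.marker != table.marker:
        raise ValueError(
            f"blocklist marker {blocklist.marker!r} != table marker {table.marker!r}"
        )
    hit: set[str] = set()
    known = set(taxonomy.lineages.index)
    for rank, name in blocklist.entries:
        hit.update(taxonomy.records_matching(rank, name))
    hit &= set(table.asv_ids) & known
    after = table.drop_asvs(hit)
    return after, _step("blocklist", table, after)


def remove_clade(
    table: AsvCountTable, taxonomy: TaxonomyTable, rank: str, name: str
) -> tuple[AsvCountTable, StepReport]:
    """Remove all ASVs belonging to a named clade (zero matches allowed)."""
    if rank not in RANKS:
        raise TableFormatError(f"unrecognized rank {rank!r}")
    hit = set(taxonomy.records_matching(rank, name)) & set(table.asv_ids)
    after = table.drop_asvs(hit)
    rep = _step(f"remove-clade:{rank}={name}", table, after)
    return after, rep


def remove_control_asvs(
    table: AsvCountTable, metadata: SampleMetadataTable, scope: str = "cruise"
) -> tuple[AsvCountTable, StepReport]:
    """Remove ASVs detected in negative controls; drop control columns.

    With ``scope="cruise"`` an ASV with at least one read in any control of
    a cruise is removed from that cruise's environmental samples only (its
    reads in other cruises are zeroed per-cruise, and the ASV row is dropped
    when it becomes absent everywhere).  ``scope="global"`` removes
    control-detected ASVs from all samples.
    """
    md = metadata.data
    in_table = [s for s in table.sample_ids if s in md.index]
    controls = [s for s in in_table if md.at[s, "is_control"]]
    counts = table.counts.copy()
    notes: list[str] = []

    if scope == "global":
        hit = counts.index[(counts[controls].sum(axis=1) > 0)] if controls else []
        counts = counts.drop(index=list(hit))
    elif scope == "cruise":
        cruises = {md.at[s, "cruise"] for s in in_table}
        for cruise in sorted(cruises):
            cr_samples = [s for s in in_table if md.at[s, "cruise"] == cruise]
            cr_controls = [s for s in cr_samples if md.at[s, "is_control"]]
            cr_env = [s for s in cr_samples if not md.at[s, "is_control"]]
            if cr_env and not cr_controls:
                notes.append(f"cruise {cruise}: no negative controls, no removal")
                continue
            if not cr_controls:
                continue
            hit = counts.index[counts[cr_controls].sum(axis=1) > 0]
            counts.loc[hit, cr_env] = 0
    else:
        raise ValueError(f"unknown control scope {scope!r}")

    counts = counts.drop(columns=controls)
    counts = counts.loc[counts.sum(axis=1) > 0]
    after = AsvCountTable(table.marker, counts)
    rep = _step("control-asvs", table, after)
    rep.notes = notes
    return after, rep


def drop_below_detection_samples(
    metadata: SampleMetadataTable,
) -> tuple[list[str], StepReport]:
    """Environmental samples whose DNA concentration was below detection.

    Returns the excluded sample ids; controls with below-detection
    concentrations are retained (exclusion applies to environmental samples
    only).
    """
    md = metadata.data
    excl = list(md.index[md["below_detection"] & ~md["is_control"]])
    rep = StepReport(label="below-detection", samples_removed=len(excl))
    return excl, rep


@dataclass
class DecontaminationConfig:
    min_reads: int = 1000
    blocklist: Blocklist | None = None  # None -> marker default
    remove_vertebrates_from_coi: bool = True
    control_scope: str = "cruise"
    apply_low_read: bool = True
    apply_blocklist: bool = True
    apply_control_removal: bool = True
    apply_below_detection: bool = True


def decontaminate(
    asv: AsvCountTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadataTable,
    config: DecontaminationConfig | None = None,
) -> tuple[AsvCountTable, DecontaminationReport]:
    """Run the full filter chain and return the cleaned table plus report."""
    cfg = config or DecontaminationConfig()
    report = DecontaminationReport(
        marker=asv.marker,
        initial_samples=len(asv.sample_ids),
        initial_asvs=len(asv.asv_ids),
        initial_reads=asv.total_reads,
    )
    table = asv

    if cfg.apply_low_read:
        table, step = drop_low_read_samples(table, cfg.min_reads)
        report.steps.append(step)
    if cfg.apply_blocklist:
        bl = cfg.blocklist or default_blocklist(table.marker)
        table, step = remove_blocklisted_taxa(table, taxonomy, bl)
        report.steps.append(step)
    if cfg.remove_vertebrates_from_coi and table.marker == "COI":
        table, step = remove_clade(table, taxonomy, "subphylum", "Vertebrata")
        report.steps.append(step)
    if cfg.apply_control_removal:
        table, step = remove_control_asvs(table, metadata, cfg.control_scope)
        report.steps.append(step)
    if cfg.apply_below_detection:
        excl, step = drop_below_detection_samples(metadata)
        present = [s for s in excl if s in table.sample_ids]
        before = table
        table = table.drop_samples(present)
        s2 = _step("below-detection", before, table)
        s2.notes = [f"excluded below-detection sample {s}" for s in present]
        report.steps.append(s2)
        report.excluded_samples = excl

    report.final_samples = len(table.sample_ids)
    report.final_asvs = len(table.asv_ids)
    report.final_reads = table.total_reads
    assert report.conserved(), "decontamination bookkeeping failed conservation"
    return table, report
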