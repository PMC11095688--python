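"""Domain tables for eDNA metabarcoding community analysis.

The pipeline works from four plain-text tables:

* an ASV read-count table per marker (amplicon sequence variants x samples,
  tab-separated),
* a taxonomy table mapping each ASV or trawl taxon to a ranked lineage,
* per-sample metadata (position, depth, filtered volume, timestamp,
  negative-control flag, measured DNA concentration),
* a trawl catch table (net x taxon individual counts).

Every writer emits a ``#schema=edna-assemblage/v1`` comment as its first
line; readers tolerate and skip any leading ``#`` comment lines.  ASV
tables are stored ASVs-as-rows by default; a ``#orientation=samples-as-rows``
comment lets the reader transpose alternative exports.

DNA concentrations below the assay's quantification floor are encoded on
disk as the literal token ``BD`` and carried in memory as a boolean
``below_detection`` flag next to a NaN concentration — such samples are
excluded from concentration analyses rather than treated as zero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_LINE = "#schema=edna-assemblage/v1"

MARKERS = ("12S", "COI")

#: Recognized taxonomic ranks, highest to lowest.  ``series`` sits between
#: order and family to accommodate fish series such as Ovalentaria that are
#: used as grouping levels when the order is incertae sedis.
RANKS = (
    "kingdom",
    "phylum",
    "subphylum",
    "class",
    "order",
    "series",
    "family",
    "genus",
    "species",
)

#: Intermediate ranks that many lineages legitimately omit; an empty value
#: here never counts as a lineage gap.
OPTIONAL_RANKS = frozenset({"subphylum", "series"})

METADATA_COLUMNS = (
    "sample_id",
    "cruise",
    "latitude",
    "longitude",
    "depth",
    "volume",
    "timestamp",
    "is_control",
    "dna_concentration",
)

TRAWL_COLUMNS = (
    "net_id",
    "taxon_id",
    "count",
    "depth_min",
    "depth_max",
    "latitude",
    "longitude",
    "timestamp",
)


class TableFormatError(ValueError):
    """Raised when an input file violates the table contract."""


@dataclass
class AsvCountTable:
    """Read counts of ASVs (rows) across samples (columns) for one marker."""

    marker: str
    counts: pd.DataFrame  # index: asv ids, columns: sample ids, int

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise TableFormatError(
                f"unknown marker {self.marker!r}; expected one of {MARKERS}"
            )
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate ASV ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].tolist()
            raise TableFormatError(f"duplicate sample ids: {dup}")
        if (c.to_numpy() < 0).any():
            r, s = np.argwhere(c.to_numpy() < 0)[0]
            raise TableFormatError(
                f"negative count at ASV {c.index[r]!r}, sample {c.columns[s]!r}"
            )
        self.counts = c.astype(np.int64)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def drop_samples(self, sample_ids) -> "AsvCountTable":
        keep = [s for s in self.counts.columns if s not in set(sample_ids)]
        return AsvCountTable(self.marker, self.counts[keep])

    def drop_asvs(self, asv_ids) -> "AsvCountTable":
        keep = ~self.counts.index.isin(set(asv_ids))
        return AsvCountTable(self.marker, self.counts.loc[keep])


@dataclass
class TaxonomyTable:
    """Ranked lineages for ASVs and trawl taxa.

    ``lineages`` has one row per record id and one column per rank in
    :data:`RANKS`; empty string means unassigned.  ``deepest_rank`` is the
    lowest rank carrying a name.  A name below an empty higher rank is
    accepted with a warning (reference-library lineages are often sparse);
    the empty rank is treated as unranked.
    """

    lineages: pd.DataFrame  # index: record_id, columns: RANKS, str
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lin = self.lineages
        unknown = [c for c in lin.columns if c not in RANKS]
        if unknown:
            raise TableFormatError(f"unknown rank columns: {unknown}")
        if lin.index.has_duplicates:
            dup = lin.index[lin.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate taxonomy record ids: {dup}")
        lin = lin.reindex(columns=list(RANKS), fill_value="").fillna("").astype(str)
        self.lineages = lin
        warns = []
        for rid, row in lin.iterrows():
            filled = [r for r in RANKS if row[r]]
            if not filled:
                continue
            deepest = filled[-1]
            above = RANKS[: RANKS.index(deepest)]
            gaps = [r for r in above if not row[r] and r not in OPTIONAL_RANKS]
            if gaps:
                warns.append(
                    f"{rid}: rank(s) {gaps} empty above {deepest} "
                    f"({row[deepest]!r}); treated as unranked"
                )
        self.warnings.extend(warns)

    def deepest_rank(self, record_id: str) -> str | None:
        """Lowest named rank for a record, or None if fully unassigned."""
        row = self.lineages.loc[record_id]
        filled = [r for r in RANKS if row[r]]
        return filled[-1] if filled else None

    @property
    def deepest_ranks(self) -> pd.Series:
        arr = self.lineages.to_numpy()
        out = []
        for row in arr:
            filled = [RANKS[i] for i, v in enumerate(row) if v]
            out.append(filled[-1] if filled else None)
        return pd.Series(out, index=self.lineages.index, name="deepest_rank")

    def name_at(self, record_id: str, rank: str) -> str:
        return str(self.lineages.at[record_id, rank])

    def records_matching(self, rank: str, name: str) -> list[str]:
        """Record ids whose lineage carries ``name`` at ``rank``."""
        if rank not in RANKS:
            raise TableFormatError(f"unrecognized rank {rank!r}")
        col = self.lineages[rank]
        return list(self.lineages.index[col == name])


@dataclass
class SampleMetadataTable:
    """Per-sample collection metadata, including negative controls."""

    data: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            dup = d.index[d.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate sample ids: {dup}")
        bad_lat = d.index[(d["latitude"] < -90) | (d["latitude"] > 90)]
        if len(bad_lat):
            raise TableFormatError(f"latitude out of [-90, 90] for {list(bad_lat)}")
        bad_lon = d.index[(d["longitude"] < -180) | (d["longitude"] > 180)]
        if len(bad_lon):
            raise TableFormatError(f"longitude out of [-180, 180] for {list(bad_lon)}")
        env = d[~d["is_control"]]
        bad_vol = env.index[~(env["volume"] > 0)]
        if len(bad_vol):
            raise TableFormatError(
                f"non-positive filtered volume for environmental sample(s) {list(bad_vol)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def control_ids(self) -> list[str]:
        return list(self.data.index[self.data["is_control"]])

    @property
    def environmental_ids(self) -> list[str]:
        return list(self.data.index[~self.data["is_control"]])

    def cruise_of(self, sample_id: str) -> str:
        return str(self.data.at[sample_id, "cruise"])


@dataclass
class TrawlCatchTable:
    """Individual counts per depth-discrete trawl net and taxon."""

    data: pd.DataFrame  # columns: TRAWL_COLUMNS

    def __post_init__(self) -> None:
        d = self.data
        if (d["count"] < 0).any():
            raise TableFormatError("negative trawl counts")
        if (d["depth_min"] > d["depth_max"]).any():
            bad = d.loc[d["depth_min"] > d["depth_max"], "net_id"].tolist()
            raise TableFormatError(f"depth_min > depth_max for net(s) {bad}")

    @property
    def net_ids(self) -> list[str]:
        return list(pd.unique(self.data["net_id"]))

    def net_sites(self) -> pd.DataFrame:
        """One row per net: latitude, longitude, mid depth."""
        g = self.data.groupby("net_id", sort=False).first()
        g["depth_mid"] = (g["depth_min"] + g["depth_max"]) / 2.0
        return g[["latitude", "longitude", "depth_min", "depth_max", "depth_mid"]]


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        for tag, items in (("ERROR", self.errors), ("WARN", self.warnings)):
            lines += [f"  {tag} {t}[{loc}] {rule}: {msg}" for t, loc, rule, msg in items]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# readers / writers


def _strip_comments(path: Path) -> tuple[str, dict[str, str]]:
    """Return file body without leading # lines plus parsed #key=value pairs."""
    meta: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines(keepends=True)
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        if "=" in line:
            k, _, v = line[1:].strip().partition("=")
            meta[k] = v
    else:
        i = len(lines)
    return "".join(lines[i:]), meta


def read_asv_table(path, marker: str) -> AsvCountTable:
    """Read a tab-separated ASV x sample read-count table.

    First column holds ASV ids, remaining columns one sample each; cells are
    non-negative integers.  Input ordering is preserved.
    """
    body, meta = _strip_comments(Path(path))
    df = pd.read_csv(io.StringIO(body), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        counts = df.apply(pd.to_numeric).astype(np.int64)
    except (ValueError, TypeError) as exc:
        for col in df.columns:
            num = pd.to_numeric(df[col], errors="coerce")
            if num.isna().any():
                row = df.index[num.isna()][0]
                raise TableFormatError(
                    f"{path}: non-integer cell at ASV {row!r}, sample {col!r}"
                ) from exc
        raise
    if meta.get("orientation") == "samples-as-rows":
        counts = counts.T
    counts.index.name = None
    counts.columns.name = None
    return AsvCountTable(marker=marker, counts=counts)


def write_asv_table(table: AsvCountTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_LINE + "\n")
        fh.write(f"#marker={table.marker}\n")
        out = table.counts.copy()
        out.index.name = "asv_id"
        out.to_csv(fh, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy CSV: record_id plus one column per recognized rank."""
    body, _ = _strip_comments(Path(path))
    df = pd.read_csv(io.StringIO(body), index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return TaxonomyTable(lineages=df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_LINE + "\n")
        out = tax.lineages.copy()
        out.index.name = "record_id"
        out.to_csv(fh)


BD_TOKEN = "BD"


def read_sample_metadata(path) -> SampleMetadataTable:
    body, _ = _strip_comments(Path(path))
    df = pd.read_csv(io.StringIO(body), dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing metadata column(s) {missing}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index)
    out["cruise"] = df["cruise"]
    for col in ("latitude", "longitude"):
        out[col] = pd.to_numeric(df[col])
    out["depth"] = pd.to_numeric(df["depth"].replace("", np.nan))
    out["volume"] = pd.to_numeric(df["volume"].replace("", np.nan))
    out["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    out["is_control"] = df["is_control"].str.lower().isin(("true", "1", "yes"))
    conc = df["dna_concentration"].str.strip()
    out["below_detection"] = conc == BD_TOKEN
    out["dna_concentration"] = pd.to_numeric(
        conc.mask(out["below_detection"] | (conc == ""), np.nan)
    )
    for opt in ("sunrise", "sunset"):
        if opt in df.columns:
            out[opt] = pd.to_datetime(df[opt].replace("", np.nan), utc=True)
        else:
            out[opt] = pd.NaT
    return SampleMetadataTable(data=out)


def write_sample_metadata(meta: SampleMetadataTable, path) -> None:
    d = meta.data.copy()
    conc = d["dna_concentration"].map(
        lambda v: "" if pd.isna(v) else format(float(v), ".10g")
    )
    conc[d["below_detection"]] = BD_TOKEN
    out = pd.DataFrame(index=d.index)
    out["cruise"] = d["cruise"]
    for col in ("latitude", "longitude", "depth", "volume"):
        out[col] = d[col].map(lambda v: "" if pd.isna(v) else format(float(v), ".10g"))
    out["timestamp"] = d["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out["is_control"] = d["is_control"].map({True: "true", False: "false"})
    out["dna_concentration"] = conc
    for opt in ("sunrise", "sunset"):
        out[opt] = d[opt].dt.strftime("%Y-%m-%dT%H:%M:%S%z").fillna("")
    out.index.name = "sample_id"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_LINE + "\n")
        out.to_csv(fh)


def read_trawl_table(path, taxonomy: TaxonomyTable | None = None) -> TrawlCatchTable:
    body, _ = _strip_comments(Path(path))
    df = pd.read_csv(io.StringIO(body), dtype=str, keep_default_na=False)
    missing = [c for c in TRAWL_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing trawl column(s) {missing}")
    out = pd.DataFrame()
    out["net_id"] = df["net_id"].astype(str)
    out["taxon_id"] = df["taxon_id"].astype(str)
    out["count"] = pd.to_numeric(df["count"]).astype(np.int64)
    for col in ("depth_min", "depth_max", "latitude", "longitude"):
        out[col] = pd.to_numeric(df[col])
    out["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    table = TrawlCatchTable(data=out)
    if taxonomy is not None:
        unknown = set(out["taxon_id"]) - set(taxonomy.lineages.index)
        if unknown:
            raise TableFormatError(
                f"{path}: trawl taxa missing from taxonomy: {sorted(unknown)}"
            )
    return table


def write_trawl_table(trawl: TrawlCatchTable, path) -> None:
    d = trawl.data.copy()
    d["timestamp"] = d["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    for col in ("depth_min", "depth_max", "latitude", "longitude"):
        d[col] = d[col].map(lambda v: format(float(v), ".10g"))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_LINE + "\n")
        d.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# cross-table validation


def validate_dataset(
    asv: AsvCountTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadataTable,
    trawl: TrawlCatchTable | None = None,
) -> ValidationReport:
    """Cross-reference ids across tables.

    ASVs absent from the taxonomy are a warning (they are treated as fully
    unassigned downstream); sample columns absent from the metadata are an
    error because no filter or metric can be computed for them.  The check is
    pure: identical inputs always yield an identical report.
    """
    rep = ValidationReport()
    tax_ids = set(taxonomy.lineages.index)
    meta_ids = set(metadata.sample_ids)
    for asv_id in asv.asv_ids:
        if asv_id not in tax_ids:
            rep.warnings.append(
                ("asv", asv_id, "taxonomy-missing",
                 "no taxonomy record; treated as fully unassigned")
            )
    for sid in asv.sample_ids:
        if sid not in meta_ids:
            rep.errors.append(
                ("asv", sid, "metadata-missing", "sample column not in metadata")
            )
    if trawl is not None:
        for tid in pd.unique(trawl.data["taxon_id"]):
            if tid not in tax_ids:
                rep.errors.append(
                    ("trawl", str(tid), "taxonomy-missing",
                     "trawl taxon not in taxonomy")
                )
    for w in taxonomy.warnings:
        rep.warnings.append(("taxonomy", w.split(":")[0], "lineage-gap", w))
    return rep
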