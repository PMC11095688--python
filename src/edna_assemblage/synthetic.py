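"""Ground-truth-annotated synthetic eDNA metabarcoding datasets.

The generator emulates the statistical structure the analysis pipeline
assumes: planted spatial species assemblages with depth niches, a
species-to-many-ASV mapping (inflated for the COI marker), negative-control
contamination shared with environmental samples, non-marine bycatch taxa,
vertebrate bycatch in the COI table, negative-binomial per-sample read
totals allocated by a Dirichlet-multinomial over each occupied species'
ASVs, DNA concentration decaying roughly an order of magnitude from the
epipelagic to below 600 m, and depth-discrete trawl nets sampling the same
latent communities with group-specific catchability.

Every random draw comes from one :class:`numpy.random.Generator` seeded by
the config, so a seed fixes the entire dataset byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    RANKS,
    AsvCountTable,
    SampleMetadataTable,
    TaxonomyTable,
    TrawlCatchTable,
    write_asv_table,
    write_sample_metadata,
    write_taxonomy,
    write_trawl_table,
)

#: Vertebrate orders used for planted 12S species (grouped at order level).
VERTEBRATE_ORDERS = (
    "Myctophiformes",
    "Clupeiformes",
    "Stomiiformes",
    "Argentiniformes",
    "Perciformes",
    "Gadiformes",
)

#: Invertebrate (phylum, class, order) lineage stubs for planted COI
#: species; grouping bins arthropods at class and cnidarians at order level.
INVERTEBRATE_CLADES = (
    ("Arthropoda", "Copepoda", "Calanoida"),
    ("Arthropoda", "Malacostraca", "Euphausiacea"),
    ("Arthropoda", "Ostracoda", "Halocyprida"),
    ("Cnidaria", "Hydrozoa", "Siphonophorae"),
    ("Cnidaria", "Hydrozoa", "Trachymedusae"),
    ("Chaetognatha", "Sagittoidea", "Aphragmophora"),
    ("Mollusca", "Gastropoda", "Pteropoda"),
    ("Ctenophora", "Tentaculata", "Lobata"),
)

#: Non-marine bycatch planted in the 12S table (order-level blocklist hits).
NONMARINE_12S = (
    ("Primates", "Hominidae", "Homo", "Homo sapiens"),
    ("Galliformes", "Phasianidae", "Gallus", "Gallus gallus"),
    ("Rodentia", "Muridae", "Mus", "Mus musculus"),
)

#: Non-marine bivalves planted in the COI table (species-level blocklist).
NONMARINE_COI = (
    "Bathymodiolus japonicus",
    "Saccostrea malabonensis",
    "Abyssogena phaseoliformis",
)


@dataclass
class AssemblageSpec:
    """One planted assemblage: where it lives and how deep."""

    name: str
    lon: float
    lat: float
    depth_center: float
    depth_width: float
    n_species_12s: int
    n_species_coi: int


@dataclass
class SyntheticConfig:
    seed: int = 0
    assemblages: list[AssemblageSpec] = field(default_factory=list)
    #: (cruise, n_stations, depths) blocks; station positions scatter around
    #: assemblage centers, cycling through the assemblage list
    station_blocks: list[tuple[str, int, tuple[float, ...]]] = field(
        default_factory=list
    )
    station_scatter: float = 0.4  # degrees sd around the assemblage center
    controls_per_cruise: int = 4
    # occurrence model
    p_in: float = 0.75  # detection prob inside the assemblage at its core depth
    p_out: float = 0.03  # background detection prob elsewhere
    # ASV multiplicity per species: 1 + Poisson(mean-1) for 12S,
    # 1 + floor(lognormal) for COI
    multiplicity_mean_12s: float = 2.1
    multiplicity_lognormal_mu_coi: float = 2.3
    multiplicity_lognormal_sigma_coi: float = 1.2
    dirichlet_asv_alpha: float = 0.8
    # per-sample read totals (negative binomial)
    read_mean_12s: float = 24000.0
    read_mean_coi: float = 32000.0
    read_dispersion: float = 1.5  # NB shape; smaller = more overdispersed
    low_read_fraction: float = 0.12  # fraction of failed (near-zero-read) samples
    # contamination
    n_contaminant_asvs_12s: int = 7
    n_contaminant_asvs_coi: int = 20
    n_unassigned_control_asvs: int = 3
    contaminant_prevalence: float = 0.6  # env-sample prevalence of contaminants
    contaminant_read_mean: float = 1500.0
    nonmarine_prevalence: float = 0.3
    nonmarine_read_mean: float = 400.0
    vertebrate_bycatch_coi: int = 4  # vertebrate ASVs planted into COI
    # species-level assignment probability: shallow vs >600 m niches
    species_level_p_shallow_12s: float = 0.9
    species_level_p_deep_12s: float = 0.85
    species_level_p_shallow_coi: float = 0.5
    species_level_p_deep_coi: float = 0.15
    # DNA concentration model: surface * exp(-depth/efold) * lognormal noise
    dna_surface_mean: float = 3.6
    dna_efold_m: float = 300.0
    dna_noise_sigma: float = 0.35  # log-scale sd (multiplicative noise)
    dna_bd_threshold: float = 0.05
    # diel mix of cast times (fractions; remainder transitional)
    night_fraction: float = 0.6
    day_fraction: float = 0.16
    # trawl sampling
    trawl_zones: int = 3  # zones = first assemblages in order
    nets_per_zone: int = 5
    trawl_strata: tuple[tuple[float, float], ...] = (
        (0, 200),
        (200, 600),
        (600, 1000),
        (1000, 1400),
        (1400, 1750),
    )
    trawl_effort: float = 9.0
    catchability: dict = field(
        default_factory=lambda: {"default": 1.0, "Siphonophorae": 0.3,
                                 "Trachymedusae": 0.3, "Lobata": 0.2}
    )
    volume_range: tuple[float, float] = (360.0, 1800.0)


@dataclass
class SyntheticTruth:
    """Planted ground truth for every generated dataset."""

    sample_assemblage: dict  # env sample id -> assemblage name
    species: dict  # species name -> marker, group, assemblage, asvs, ...
    contaminant_asvs: dict  # marker -> [asv ids] (incl. unassigned controls)
    nonmarine_asvs: dict  # marker -> [asv ids]
    vertebrate_asvs_in_coi: list
    station_assemblage: dict  # station id -> assemblage name

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    asv_12s: AsvCountTable
    asv_coi: AsvCountTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadataTable
    trawl: TrawlCatchTable
    truth: SyntheticTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# presets


def preset(name: str) -> SyntheticConfig:
    """Named study designs.

    ``paper-like``: two cruises, 40 casts, 436 environmental samples from
    1-2200 m with depth-skewed effort, three assemblages, read means near
    24k (12S) / 32k (COI).  ``separable-3``: three well-separated shallow
    assemblages for recovery tests.  ``null``: a single spatially
    unstructured assemblage for calibration tests.
    """
    if name == "paper-like":
        shallow8 = (1, 10, 20, 40, 80, 120, 170, 300)
        shallow9 = shallow8 + (500,)
        deep24 = (
            1, 10, 20, 30, 50, 75, 100, 125, 150, 170, 190, 200,
            250, 300, 400, 500, 600, 700, 800, 1000, 1250, 1500, 1800, 2200,
        )
        return SyntheticConfig(
            assemblages=[
                AssemblageSpec("coastal", -118.6, 33.6, 60, 120, 18, 40),
                AssemblageSpec("offshore", -122.8, 31.6, 120, 200, 16, 40),
                AssemblageSpec("mesopelagic", -120.8, 32.8, 650, 350, 14, 40),
            ],
            station_blocks=[
                ("SR2111", 29, shallow8),
                ("SR2111", 4, shallow9),
                ("RR2104", 7, deep24),
            ],
            controls_per_cruise=4,
        )
    if name == "separable-3":
        return SyntheticConfig(
            assemblages=[
                AssemblageSpec("A", -118.0, 34.0, 60, 500, 14, 22),
                AssemblageSpec("B", -121.5, 32.0, 60, 500, 14, 22),
                AssemblageSpec("C", -124.5, 30.0, 60, 500, 14, 22),
            ],
            station_blocks=[("SIM1", 24, (10, 50, 100))],
            station_scatter=0.25,
            p_in=0.9,
            p_out=0.01,
            read_mean_12s=12000.0,
            read_mean_coi=15000.0,
            low_read_fraction=0.05,
            night_fraction=1.0,
            day_fraction=0.0,
            multiplicity_lognormal_mu_coi=1.2,
            multiplicity_lognormal_sigma_coi=0.8,
            n_contaminant_asvs_coi=8,
            trawl_zones=3,
            nets_per_zone=3,
            trawl_strata=((0, 200), (200, 600)),
        )
    if name == "null":
        return SyntheticConfig(
            assemblages=[AssemblageSpec("flat", -121.0, 32.5, 100, 4000, 12, 24)],
            station_blocks=[("SIM1", 12, (10, 100, 400, 800))],
            station_scatter=2.5,
            p_in=0.35,
            p_out=0.35,
            read_mean_12s=4000.0,
            read_mean_coi=5000.0,
            low_read_fraction=0.05,
            multiplicity_lognormal_mu_coi=1.0,
            multiplicity_lognormal_sigma_coi=0.8,
            n_contaminant_asvs_coi=5,
            trawl_zones=3,
            nets_per_zone=2,
            trawl_strata=((0, 200), (200, 1750)),
        )
    raise ValueError(f"unknown preset {name!r}; choose from paper-like, separable-3, null")


# ---------------------------------------------------------------------------
# generation helpers


def _negbin(rng: np.random.Generator, mean: float, shape: float, size=None):
    # NB as gamma-Poisson mixture
    lam = rng.gamma(shape, mean / shape, size=size)
    return rng.poisson(lam)


def _species_lineage_12s(order: str, idx: int, species_level: bool) -> dict:
    genus = f"Genus{order[:4]}{idx:03d}"
    lin = {
        "kingdom": "Animalia",
        "phylum": "Chordata",
        "subphylum": "Vertebrata",
        "class": "Actinopteri",
        "order": order,
        "family": f"{order[:-6]}idae",
        "genus": genus,
        "species": f"{genus} marinus" if species_level else "",
    }
    return lin


def _species_lineage_coi(clade: tuple[str, str, str], idx: int, species_level: bool) -> dict:
    phylum, cls, order = clade
    genus = f"Genus{order[:4]}{idx:03d}"
    lin = {
        "kingdom": "Animalia",
        "phylum": phylum,
        "class": cls,
        "order": order,
        "family": f"{order[:4]}idae",
        "genus": genus,
        "species": f"{genus} pelagicus" if species_level else "",
    }
    return lin


class _SpeciesPool:
    """Planted species with lineages, niches and ASV assignments."""

    def __init__(self) -> None:
        self.rows: list[dict] = []  # taxonomy rows keyed by record_id
        self.species: list[dict] = []  # per-species truth entries

    def add(self, record_rows: dict[str, dict], entry: dict) -> None:
        for rid, row in record_rows.items():
            self.rows.append({"record_id": rid, **row})
        self.species.append(entry)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete dataset plus its planted ground truth."""
    if not config.assemblages:
        raise ValueError("config needs at least one assemblage")
    rng = np.random.default_rng(config.seed)
    t0 = datetime(2021, 10, 31, tzinfo=timezone.utc)

    # ---- stations ---------------------------------------------------------
    stations = []  # (station_id, cruise, lon, lat, assemblage idx, depths)
    k = len(config.assemblages)
    s_idx = 0
    for cruise, n_st, depths in config.station_blocks:
        for _ in range(n_st):
            a_idx = s_idx % k
            a = config.assemblages[a_idx]
            lon = a.lon + rng.normal(0, config.station_scatter)
            lat = a.lat + rng.normal(0, config.station_scatter)
            stations.append(
                {
                    "station_id": f"st{s_idx:03d}",
                    "cruise": cruise,
                    "lon": float(lon),
                    "lat": float(lat),
                    "assemblage": a.name,
                    "a_idx": a_idx,
                    "depths": depths,
                }
            )
            s_idx += 1

    # ---- species pools ----------------------------------------------------
    pool = _SpeciesPool()
    asv_serial = {"12S": 0, "COI": 0}

    def new_asvs(marker: str, n: int) -> list[str]:
        start = asv_serial[marker]
        asv_serial[marker] += n
        return [f"{marker.lower()}_asv{start + i:05d}" for i in range(n)]

    sp_serial = 0
    for a_idx, a in enumerate(config.assemblages):
        for marker, n_sp in (("12S", a.n_species_12s), ("COI", a.n_species_coi)):
            for j in range(n_sp):
                sp_serial += 1
                depth_center = float(
                    np.clip(rng.normal(a.depth_center, a.depth_width / 2), 1, 2200)
                )
                if marker == "12S":
                    p_shal, p_deep = (
                        config.species_level_p_shallow_12s,
                        config.species_level_p_deep_12s,
                    )
                else:
                    p_shal, p_deep = (
                        config.species_level_p_shallow_coi,
                        config.species_level_p_deep_coi,
                    )
                # linear interpolation of the species-level assignment
                # probability between the surface and 600 m niches
                frac = min(depth_center, 600.0) / 600.0
                p_sp_level = p_shal + (p_deep - p_shal) * frac
                species_level = bool(rng.random() < p_sp_level)
                if marker == "12S":
                    order = VERTEBRATE_ORDERS[sp_serial % len(VERTEBRATE_ORDERS)]
                    lin = _species_lineage_12s(order, sp_serial, species_level)
                    group = order
                    mult = 1 + rng.poisson(config.multiplicity_mean_12s - 1)
                else:
                    clade = INVERTEBRATE_CLADES[sp_serial % len(INVERTEBRATE_CLADES)]
                    lin = _species_lineage_coi(clade, sp_serial, species_level)
                    group = clade[2] if clade[0] in ("Arthropoda",) else (
                        clade[2] if clade[0] == "Cnidaria" else clade[0]
                    )
                    if clade[0] == "Arthropoda":
                        group = clade[1]
                    mult = 1 + int(
                        rng.lognormal(
                            config.multiplicity_lognormal_mu_coi,
                            config.multiplicity_lognormal_sigma_coi,
                        )
                    )
                sp_name = lin["species"] or f"{lin['genus']} indet"
                asvs = new_asvs(marker, mult)
                rows = {rid: lin for rid in asvs}
                # one trawl-taxon record sharing the lineage
                trawl_tid = f"tx_{marker.lower()}_{sp_serial:04d}"
                rows[trawl_tid] = lin
                pool.add(
                    rows,
                    {
                        "name": sp_name,
                        "marker": marker,
                        "group": group,
                        "assemblage": a.name,
                        "a_idx": a_idx,
                        "depth_center": depth_center,
                        "species_level": species_level,
                        "asvs": asvs,
                        "trawl_taxon": trawl_tid,
                    },
                )

    # ---- bycatch / contamination ASVs ------------------------------------
    nonmarine = {"12S": [], "COI": []}
    for order, fam, genus, sp in NONMARINE_12S:
        rid = new_asvs("12S", 1)[0]
        pool.rows.append(
            {
                "record_id": rid,
                "kingdom": "Animalia",
                "phylum": "Chordata",
                "subphylum": "Vertebrata",
                "class": "Mammalia" if order != "Galliformes" else "Aves",
                "order": order,
                "family": fam,
                "genus": genus,
                "species": sp,
            }
        )
        nonmarine["12S"].append(rid)
    for sp in NONMARINE_COI:
        rid = new_asvs("COI", 1)[0]
        genus = sp.split()[0]
        pool.rows.append(
            {
                "record_id": rid,
                "kingdom": "Animalia",
                "phylum": "Mollusca",
                "class": "Bivalvia",
                "order": "Mytilida",
                "family": "Mytilidae",
                "genus": genus,
                "species": sp,
            }
        )
        nonmarine["COI"].append(rid)

    # vertebrate bycatch ASVs planted into the COI table
    vert_bycatch = []
    for i in range(config.vertebrate_bycatch_coi):
        rid = new_asvs("COI", 1)[0]
        order = VERTEBRATE_ORDERS[i % len(VERTEBRATE_ORDERS)]
        pool.rows.append(
            {
                "record_id": rid,
                "kingdom": "Animalia",
                "phylum": "Chordata",
                "subphylum": "Vertebrata",
                "class": "Actinopteri",
                "order": order,
                "family": f"{order[:-6]}idae",
                "genus": f"Bycatch{i}",
                "species": f"Bycatch{i} coi",
            }
        )
        vert_bycatch.append(rid)

    # unassigned control ASVs: no taxonomy record at all
    unassigned_ctrl = {
        "12S": new_asvs("12S", config.n_unassigned_control_asvs),
        "COI": new_asvs("COI", config.n_unassigned_control_asvs),
    }

    species_by_marker = {
        m: [s for s in pool.species if s["marker"] == m] for m in ("12S", "COI")
    }
    # marine contaminants: ASVs of real species shared with controls
    contaminant = {}
    for marker, n_cont in (
        ("12S", config.n_contaminant_asvs_12s),
        ("COI", config.n_contaminant_asvs_coi),
    ):
        all_asvs = [a for s in species_by_marker[marker] for a in s["asvs"]]
        n_cont = min(n_cont, len(all_asvs))
        chosen = list(rng.choice(all_asvs, size=n_cont, replace=False))
        contaminant[marker] = [str(a) for a in chosen]

    # ---- samples ----------------------------------------------------------
    meta_rows = []
    sample_assemblage = {}
    samples = []  # (sample_id, station dict, depth)
    smp_serial = 0
    for st in stations:
        # cast time of day drawn from the configured diel mix
        u = rng.random()
        if u < config.night_fraction:
            hour, minute = 22, 30
        elif u < config.night_fraction + config.day_fraction:
            hour, minute = 12, 0
        else:
            hour, minute = 5, 0  # within the 90 min pre-sunrise window
        day_offset = int(smp_serial // 24) % 14
        base = t0 + timedelta(days=day_offset)
        cast_time = base.replace(hour=hour, minute=minute)
        sunrise = base.replace(hour=6, minute=0)
        sunset = base.replace(hour=18, minute=0)
        for depth in st["depths"]:
            sid = f"s{smp_serial:04d}"
            smp_serial += 1
            vol = float(rng.integers(int(config.volume_range[0]),
                                     int(config.volume_range[1]) + 1))
            conc = (
                config.dna_surface_mean
                * np.exp(-depth / config.dna_efold_m)
                * np.exp(rng.normal(0, config.dna_noise_sigma))
            )
            below = conc < config.dna_bd_threshold
            meta_rows.append(
                {
                    "sample_id": sid,
                    "cruise": st["cruise"],
                    "latitude": st["lat"],
                    "longitude": st["lon"],
                    "depth": float(depth),
                    "volume": vol,
                    "timestamp": cast_time,
                    "is_control": False,
                    "below_detection": bool(below),
                    "dna_concentration": np.nan if below else float(conc),
                    "sunrise": sunrise,
                    "sunset": sunset,
                }
            )
            samples.append((sid, st, float(depth)))
            sample_assemblage[sid] = st["assemblage"]

    # negative controls, spread across cruises
    cruises = sorted({st["cruise"] for st in stations})
    control_ids = {c: [] for c in cruises}
    for cruise in cruises:
        for i in range(config.controls_per_cruise):
            sid = f"ctrl_{cruise}_{i:02d}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "cruise": cruise,
                    "latitude": 32.0,
                    "longitude": -120.0,
                    "depth": np.nan,
                    "volume": np.nan,
                    "timestamp": t0 + timedelta(days=i),
                    "is_control": True,
                    "below_detection": True,
                    "dna_concentration": np.nan,
                    "sunrise": pd.NaT,
                    "sunset": pd.NaT,
                }
            )
            control_ids[cruise].append(sid)

    meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = SampleMetadataTable(data=meta_df)

    # ---- read counts ------------------------------------------------------
    def occurrence_prob(sp: dict, st: dict, depth: float) -> float:
        if st["assemblage"] != sp["assemblage"]:
            return config.p_out
        a = config.assemblages[sp["a_idx"]]
        kern = np.exp(-((depth - sp["depth_center"]) ** 2) / (2 * a.depth_width**2))
        return config.p_out + (config.p_in - config.p_out) * kern

    tables = {}
    for marker, read_mean in (("12S", config.read_mean_12s), ("COI", config.read_mean_coi)):
        sp_list = species_by_marker[marker]
        asv_ids = [a for s in sp_list for a in s["asvs"]]
        asv_ids += nonmarine[marker]
        if marker == "COI":
            asv_ids += vert_bycatch
        asv_ids += unassigned_ctrl[marker]
        asv_pos = {a: i for i, a in enumerate(asv_ids)}
        env_ids = [sid for sid, _, _ in samples]
        ctrl_all = [c for cruise in cruises for c in control_ids[cruise]]
        counts = np.zeros((len(asv_ids), len(env_ids) + len(ctrl_all)), dtype=np.int64)

        # per-ASV Dirichlet weights within each species (fixed per dataset)
        asv_w = {
            s["name"]: rng.gamma(config.dirichlet_asv_alpha, 1.0, size=len(s["asvs"]))
            + 1e-9
            for s in sp_list
        }

        for col, (sid, st, depth) in enumerate(samples):
            probs = np.array([occurrence_prob(s, st, depth) for s in sp_list])
            present = rng.random(len(sp_list)) < probs
            if rng.random() < config.low_read_fraction:
                total = int(rng.integers(0, 900))
            else:
                total = int(_negbin(rng, read_mean, config.read_dispersion))
            if present.any() and total > 0:
                weights = []
                idxs = []
                for s, on in zip(sp_list, present):
                    if not on:
                        continue
                    w_sp = rng.gamma(1.0, 1.0) + 1e-9
                    w = asv_w[s["name"]]
                    weights.append(w_sp * w / w.sum())
                    idxs.extend(asv_pos[a] for a in s["asvs"])
                wv = np.concatenate(weights)
                draw = rng.multinomial(total, wv / wv.sum())
                counts[idxs, col] += draw
            # bycatch and contaminant reads scale with sequencing depth, so
            # failed (low-read) samples stay under the success threshold
            depth_factor = max(total / read_mean, 1e-3)
            for rid in nonmarine[marker]:
                if rng.random() < config.nonmarine_prevalence:
                    counts[asv_pos[rid], col] += 1 + _negbin(
                        rng, config.nonmarine_read_mean * depth_factor, 1.0
                    )
            if marker == "COI":
                for rid in vert_bycatch:
                    if rng.random() < config.nonmarine_prevalence / 2:
                        counts[asv_pos[rid], col] += 1 + _negbin(
                            rng, config.nonmarine_read_mean * depth_factor, 1.0
                        )
            # contaminant carry-over into environmental samples
            for rid in contaminant[marker] + unassigned_ctrl[marker]:
                if rng.random() < config.contaminant_prevalence:
                    counts[asv_pos[rid], col] += 1 + _negbin(
                        rng, config.contaminant_read_mean * depth_factor, 1.0
                    )

        # controls: reads only from contaminant + unassigned-control ASVs
        for j, cid in enumerate(ctrl_all):
            col = len(env_ids) + j
            for rid in contaminant[marker] + unassigned_ctrl[marker]:
                counts[asv_pos[rid], col] += 1 + _negbin(
                    rng, config.contaminant_read_mean / 2, 1.0
                )

        df = pd.DataFrame(counts, index=asv_ids, columns=env_ids + ctrl_all)
        tables[marker] = AsvCountTable(marker=marker, counts=df)

    # ---- taxonomy ---------------------------------------------------------
    tax_rows = {}
    for row in pool.rows:
        rid = row["record_id"]
        tax_rows[rid] = {r: row.get(r, "") for r in RANKS}
    tax_df = pd.DataFrame.from_dict(tax_rows, orient="index")
    taxonomy = TaxonomyTable(lineages=tax_df)

    # ---- trawl ------------------------------------------------------------
    trawl_rows = []
    n_zones = min(config.trawl_zones, len(stations))
    net_serial = 0
    for z in range(n_zones):
        # anchor each trawl zone to a distinct station so zones are spread
        # even when a single assemblage covers the whole study area
        zone_station = stations[z * len(stations) // n_zones]
        for rep in range((config.nets_per_zone + len(config.trawl_strata) - 1)
                         // len(config.trawl_strata)):
            for lo, hi in config.trawl_strata:
                if net_serial >= (z + 1) * config.nets_per_zone:
                    break
                net_id = f"net{net_serial:03d}"
                net_serial += 1
                mid = (lo + hi) / 2.0
                for sp in pool.species:
                    p = occurrence_prob(sp, zone_station, mid)
                    catch = config.catchability.get(
                        sp["group"], config.catchability.get("default", 1.0)
                    )
                    lam = config.trawl_effort * catch * p
                    n = int(rng.poisson(lam))
                    if n > 0:
                        trawl_rows.append(
                            {
                                "net_id": net_id,
                                "taxon_id": sp["trawl_taxon"],
                                "count": n,
                                "depth_min": float(lo),
                                "depth_max": float(hi),
                                "latitude": zone_station["lat"],
                                "longitude": zone_station["lon"],
                                "timestamp": t0 + timedelta(days=z, hours=20),
                            }
                        )
    if not trawl_rows:  # degenerate configs: keep the table well-formed
        trawl_rows.append(
            {
                "net_id": "net000",
                "taxon_id": pool.species[0]["trawl_taxon"],
                "count": 0,
                "depth_min": 0.0,
                "depth_max": 200.0,
                "latitude": config.assemblages[0].lat,
                "longitude": config.assemblages[0].lon,
                "timestamp": t0,
            }
        )
    trawl = TrawlCatchTable(data=pd.DataFrame(trawl_rows))

    truth = SyntheticTruth(
        sample_assemblage=sample_assemblage,
        species={
            s["name"]: {
                "marker": s["marker"],
                "group": s["group"],
                "assemblage": s["assemblage"],
                "depth_center": s["depth_center"],
                "species_level": s["species_level"],
                "asvs": s["asvs"],
                "trawl_taxon": s["trawl_taxon"],
            }
            for s in pool.species
        },
        contaminant_asvs={
            m: contaminant[m] + unassigned_ctrl[m] for m in ("12S", "COI")
        },
        nonmarine_asvs=nonmarine,
        vertebrate_asvs_in_coi=vert_bycatch,
        station_assemblage={st["station_id"]: st["assemblage"] for st in stations},
    )
    return SyntheticDataset(
        asv_12s=tables["12S"],
        asv_coi=tables["COI"],
        taxonomy=taxonomy,
        metadata=metadata,
        trawl=trawl,
        truth=truth,
        config=config,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the five input tables plus the planted truth as text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "asv_12s": out / "asv_12S.tsv",
        "asv_coi": out / "asv_COI.tsv",
        "taxonomy": out / "taxonomy.csv",
        "metadata": out / "metadata.csv",
        "trawl": out / "trawl.csv",
        "truth": out / "truth.json",
    }
    write_asv_table(ds.asv_12s, paths["asv_12s"])
    write_asv_table(ds.asv_coi, paths["asv_coi"])
    write_taxonomy(ds.taxonomy, paths["taxonomy"])
    write_sample_metadata(ds.metadata, paths["metadata"])
    write_trawl_table(ds.trawl, paths["trawl"])
    paths["truth"].write_text(ds.truth.to_json(), encoding="utf-8")
    return paths
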