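"""Assemblage biogeography: presence matrices, Ward clustering on Jaccard
dissimilarities, silhouette-based cluster cohesion, cluster summaries and
50% probability-density contours of cluster sample positions.

Only species-level identifications enter the clustering, collapsed from
ASVs (one species counts as present if any of its ASVs is present), and
analyses are restricted to night-collected samples so diel vertical
migration does not blur vertical structure.  Clusters are judged cohesive
when their mean silhouette width is >= 0.1 and fewer than 15% of their
members have negative widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.stats import gaussian_kde
from shapely.geometry import MultiPolygon, Polygon
from sklearn.metrics import silhouette_samples

from .stats import DissimilarityMatrix
from .tables import AsvCountTable, TaxonomyTable


@dataclass
class PresenceMatrix:
    values: pd.DataFrame  # samples x species, bool
    marker: str
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix, n-1 x 4
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if (heights < -1e-12).any():
            raise ValueError("negative merge heights")
        if (np.diff(heights) < -1e-9).any():
            raise ValueError("merge heights must be non-decreasing")


@dataclass
class ClusterSolution:
    k: int
    labels: pd.Series  # sample_id -> cluster label (1..k, size-ordered)
    silhouette: pd.Series  # sample_id -> width
    cluster_mean_width: dict[int, float]
    cluster_negative_fraction: dict[int, float]
    cohesive: dict[int, bool] = field(default_factory=dict)


@dataclass
class DensityRegion:
    mass: float
    polygons: MultiPolygon
    bandwidth: float
    grid_shape: tuple[int, int]
    enclosed_mass: float  # KDE mass actually enclosed on the grid


def build_presence_matrix(
    table: AsvCountTable,
    taxonomy: TaxonomyTable,
    diel: pd.Series | None = None,
    min_samples: int = 3,
    drop_clades: list[tuple[str, str]] | None = None,
    diel_filter: str | None = "night",
) -> PresenceMatrix:
    """Collapse ASVs to species presences and apply the clustering filters.

    Filters, in order: keep only ASVs identified to species level; drop
    ASVs in ``drop_clades`` (e.g. mammals and birds from 12S); keep only
    samples with the requested diel class; drop species present in fewer
    than ``min_samples`` samples; drop samples left without any species.
    """
    lin = taxonomy.lineages
    known = table.counts.index.intersection(lin.index)
    species_of = lin.loc[known, "species"]
    species_of = species_of[species_of != ""]

    if drop_clades:
        for rank, name in drop_clades:
            hit = set(taxonomy.records_matching(rank, name))
            species_of = species_of[~species_of.index.isin(hit)]

    counts = table.counts.loc[species_of.index]
    presence = (counts > 0).groupby(species_of).any().T  # samples x species

    if diel_filter is not None:
        if diel is None:
            raise ValueError("diel classifications required for a diel filter")
        d = diel.reindex(presence.index)
        presence = presence.loc[d == diel_filter]

    keep_species = presence.sum(axis=0) >= min_samples
    presence = presence.loc[:, keep_species]
    empty = presence.index[presence.sum(axis=1) == 0]
    presence = presence.drop(index=empty)
    if presence.empty:
        raise ValueError("no samples/species survive filters")
    return PresenceMatrix(
        values=presence, marker=table.marker, dropped_samples=list(empty)
    )


def ward_cluster(d: DissimilarityMatrix) -> Dendrogram:
    """Agglomerative clustering with Ward's minimum-variance criterion.

    Uses the squared-distance (ward.D2-equivalent) Lance-Williams update on
    the provided dissimilarities.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least 2 units to cluster")
    z = sch.linkage(d.condensed(), method="ward")
    return Dendrogram(linkage=z, leaf_ids=list(d.ids))


def cut_clusters(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the dendrogram into k clusters.

    Labels are renumbered 1..k by decreasing cluster size, ties broken by
    the lexicographically smallest member id, so labelling is deterministic.
    """
    n = len(dendrogram.leaf_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = sch.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    ids = dendrogram.leaf_ids
    order = sorted(
        set(raw),
        key=lambda c: (-(raw == c).sum(), min(ids[i] for i in np.where(raw == c)[0])),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=ids, name="cluster")


def silhouette_widths(d: DissimilarityMatrix, labels: pd.Series) -> pd.Series:
    """Per-sample silhouette widths on a precomputed dissimilarity matrix.

    s(i) = (b - a) / max(a, b); singleton clusters get width 0, as do
    samples where a = b = 0 (all-identical points).
    """
    lab = labels.reindex(d.ids)
    if lab.nunique() < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    w = silhouette_samples(d.values.to_numpy(), lab.to_numpy(), metric="precomputed")
    return pd.Series(w, index=d.ids, name="silhouette")


def wss_curve(d: DissimilarityMatrix, dendrogram: Dendrogram, k_max: int) -> pd.Series:
    """Total within-cluster sum of squares for k = 1..k_max.

    WSS(k) = sum over clusters c of sum_{i<j in c} d_ij^2 / |c|, the
    dispersion identity that Ward's criterion minimizes greedily.
    """
    n = len(dendrogram.leaf_ids)
    if k_max > n:
        raise ValueError("k_max cannot exceed the number of units")
    dm = d.values.to_numpy() ** 2
    out = {}
    for k in range(1, k_max + 1):
        labels = cut_clusters(dendrogram, k).to_numpy()
        total = 0.0
        for c in np.unique(labels):
            idx = np.where(labels == c)[0]
            total += dm[np.ix_(idx, idx)].sum() / (2 * len(idx))
        out[k] = total
    return pd.Series(out, name="wss")


def choose_k_elbow(curve: pd.Series) -> tuple[int, list[str]]:
    """Elbow rule: the interior k maximizing the discrete second difference
    of the separation curve.  Returns (k, warnings)."""
    ks = list(curve.index)
    if len(ks) < 3:
        raise ValueError("elbow needs a curve over at least 3 values of k")
    vals = curve.to_numpy(dtype=float)
    drops = -np.diff(vals)
    second = drops[:-1] - drops[1:]  # indexed by interior k
    if np.allclose(vals, vals[0]) or np.all(second <= 0):
        return ks[0], ["no elbow detected (flat or convex curve); k = minimum"]
    best = int(np.argmax(second))
    return ks[best + 1], []


def cohesive_clusters(
    solution: ClusterSolution,
    min_mean_width: float = 0.1,
    max_negative_fraction: float = 0.15,
) -> dict[int, bool]:
    """Cohesion rule: mean width >= 0.1 and < 15% negative-width members."""
    out = {}
    for c in solution.cluster_mean_width:
        out[c] = (
            solution.cluster_mean_width[c] >= min_mean_width
            and solution.cluster_negative_fraction[c] < max_negative_fraction
        )
    solution.cohesive = out
    return out


def solve_clusters(d: DissimilarityMatrix, dendrogram: Dendrogram, k: int) -> ClusterSolution:
    """Cut at k, compute silhouettes and the cohesion verdicts."""
    labels = cut_clusters(dendrogram, k)
    sil = silhouette_widths(d, labels)
    mean_w, neg_f = {}, {}
    for c in sorted(labels.unique()):
        w = sil[labels == c]
        mean_w[int(c)] = float(w.mean())
        neg_f[int(c)] = float((w < 0).mean())
    sol = ClusterSolution(
        k=k,
        labels=labels,
        silhouette=sil,
        cluster_mean_width=mean_w,
        cluster_negative_fraction=neg_f,
    )
    cohesive_clusters(sol)
    return sol


def cluster_summary(
    presence: PresenceMatrix, labels: pd.Series, top_n: int = 10
) -> dict[int, dict]:
    """Per-cluster top species by occurrence frequency plus richness stats.

    Frequencies are the fraction of the cluster's samples containing each
    species; ties break alphabetically.  Also reports species richness and
    mean +- sd species per sample (n-1 sd; 0 for single-sample clusters).
    """
    out = {}
    pv = presence.values
    lab = labels.reindex(pv.index)
    for c in sorted(lab.unique()):
        sub = pv.loc[lab == c]
        freq = sub.mean(axis=0)
        freq = freq[freq > 0]
        ranked = freq.sort_index(kind="stable").sort_values(
            ascending=False, kind="stable"
        )
        per_sample = sub.sum(axis=1)
        out[int(c)] = {
            "n_samples": int(len(sub)),
            "richness": int((sub.any(axis=0)).sum()),
            "mean_species_per_sample": float(per_sample.mean()),
            "sd_species_per_sample": (
                float(per_sample.std(ddof=1)) if len(sub) > 1 else 0.0
            ),
            "top_species": [
                {"species": s, "frequency": float(f)}
                for s, f in ranked.head(top_n).items()
            ],
        }
    return out


def density_region_50(
    points: np.ndarray,
    mass: float = 0.5,
    grid_size: int = 256,
    pad_bandwidths: float = 3.0,
) -> DensityRegion:
    """Highest-density region enclosing ``mass`` of a Gaussian KDE.

    ``points`` is an (n, 2) array of lon/lat treated as planar (adequate
    over a few degrees of extent).  A Scott-bandwidth Gaussian KDE is
    evaluated on a padded grid; the density threshold is chosen so cells at
    or above it capture the requested fraction of the total integrated
    density, and the polygons are traced at that threshold.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) lon/lat array")
    if len(pts) < 5:
        raise ValueError("need at least 5 points for a density region")
    if np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0:
        raise ValueError("points have zero spread in one coordinate")
    from skimage import measure

    kde = gaussian_kde(pts.T)  # Scott's rule by default
    bw = float(kde.factor * pts.std(axis=0, ddof=1).mean())
    pad_x = pad_bandwidths * kde.factor * pts[:, 0].std(ddof=1)
    pad_y = pad_bandwidths * kde.factor * pts[:, 1].std(ddof=1)
    gx = np.linspace(pts[:, 0].min() - pad_x, pts[:, 0].max() + pad_x, grid_size)
    gy = np.linspace(pts[:, 1].min() - pad_y, pts[:, 1].max() + pad_y, grid_size)
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)

    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat)
    total = cum[-1]
    idx = int(np.searchsorted(cum, mass * total))
    threshold = flat[min(idx, len(flat) - 1)]
    enclosed = float(dens[dens >= threshold].sum() / total)

    dx, dy = gx[1] - gx[0], gy[1] - gy[0]
    polys = []
    for contour in measure.find_contours(dens, threshold):
        # contour rows are (row, col) = (y-index, x-index)
        coords = np.column_stack(
            [gx[0] + contour[:, 1] * dx, gy[0] + contour[:, 0] * dy]
        )
        if len(coords) >= 4:
            poly = Polygon(coords)
            if not poly.is_valid:
                poly = poly.buffer(0)
            if not poly.is_empty:
                polys.append(poly)
    multi = MultiPolygon(
        [p for g in polys for p in (g.geoms if isinstance(g, MultiPolygon) else [g])]
    )
    cell_mass = float(flat.max() / total)  # upper bound on one cell's share
    if abs(enclosed - mass) > max(0.02, cell_mass):
        raise AssertionError(
            f"enclosed KDE mass {enclosed:.3f} deviates from nominal {mass}"
        )
    return DensityRegion(
        mass=mass,
        polygons=multi,
        bandwidth=bw,
        grid_shape=(grid_size, grid_size),
        enclosed_mass=enclosed,
    )
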