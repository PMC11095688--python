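"""Community dissimilarity and depth-group statistics.

Implements Morisita-Horn and binary Jaccard dissimilarities, a one-sided
Mantel permutation test, the rank-based depth-group test battery
(Kruskal-Wallis; Welch's heteroscedastic ANOVA on global mid-ranks with
Games-Howell post hoc comparisons), and species accumulation curves by the
random-accumulator method.

All rank-based procedures use global mid-ranks so results are invariant to
any monotone transform of the raw metric.  Permutation p-values include the
observed statistic in the null set, (1 + hits) / (n_perm + 1), so p is
always positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class DissimilarityMatrix:
    values: pd.DataFrame  # symmetric, zero diagonal
    metric: str  # "morisita-horn" | "jaccard"

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity diagonal must be zero")
        if ((v < -1e-12) | (v > 1 + 1e-12)).any():
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a flat vector (scipy order)."""
        from scipy.spatial.distance import squareform

        return squareform(self.values.to_numpy(), checks=False)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None


@dataclass
class RankTestResult:
    test: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    groups: tuple[str, ...]
    notes: list[str] = field(default_factory=list)


@dataclass
class AccumulationCurve:
    n_samples: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_permutations: int
    seed: int | None


# ---------------------------------------------------------------------------
# dissimilarities


def morisita_horn(x, y) -> float:
    """Morisita-Horn dissimilarity between two non-negative vectors.

    d = 1 - 2*sum(x_i y_i) / ((lx + ly) * Nx * Ny) with lx = sum(x^2)/Nx^2.
    Invariant to rescaling either vector; 0 for proportional vectors, 1 for
    disjoint supports.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("inputs must be non-negative")
    nx, ny = x.sum(), y.sum()
    if nx <= 0 or ny <= 0:
        raise ValueError("inputs must each have positive total")
    lx = (x**2).sum() / nx**2
    ly = (y**2).sum() / ny**2
    sim = 2.0 * (x * y).sum() / ((lx + ly) * nx * ny)
    return float(min(max(1.0 - sim, 0.0), 1.0))


def jaccard_binary(a, b) -> float:
    """1 - |intersection| / |union| on presence vectors."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    union = (a | b).sum()
    if union == 0:
        raise ValueError("both presence vectors are empty")
    return float(1.0 - (a & b).sum() / union)


_METRICS = {"morisita-horn": morisita_horn, "jaccard": jaccard_binary}


def pairwise(matrix: pd.DataFrame, metric: str) -> DissimilarityMatrix:
    """All-pairs dissimilarity between the rows of ``matrix``."""
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    ids = list(matrix.index)
    x = matrix.to_numpy()
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = fn(x[i], x[j])
            except ValueError as exc:
                raise ValueError(
                    f"dissimilarity undefined for pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
    return DissimilarityMatrix(
        values=pd.DataFrame(out, index=ids, columns=ids), metric=metric
    )


# ---------------------------------------------------------------------------
# Mantel test


def mantel(
    d1: DissimilarityMatrix,
    d2: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (greater) Mantel permutation test.

    r is the Pearson correlation of the strictly-lower-triangle vectors; the
    null distribution comes from simultaneous row/column permutations of the
    second matrix.
    """
    if d1.ids != d2.ids:
        raise ValueError("matrices must share unit ids in the same order")
    n = len(d1.ids)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 units")
    a = d1.values.to_numpy()
    b = d2.values.to_numpy()
    il = np.tril_indices(n, k=-1)
    va, vb = a[il], b[il]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in a distance triangle")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    za = (va - va.mean()) / va.std()
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = b[np.ix_(perm, perm)][il]
        r_perm = float(np.mean(za * (vp - vp.mean()) / vp.std()))
        if r_perm >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# rank-based depth-group tests


def _as_arrays(groups) -> tuple[list[np.ndarray], tuple[str, ...]]:
    if isinstance(groups, dict):
        labels = tuple(groups.keys())
        arrs = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrs = [np.asarray(v, dtype=float) for v in groups]
        labels = tuple(f"group{i + 1}" for i in range(len(arrs)))
    return arrs, labels


def _global_ranks(arrs: list[np.ndarray]) -> list[np.ndarray]:
    pooled = np.concatenate(arrs)
    ranks = sps.rankdata(pooled)  # mid-ranks
    out, i = [], 0
    for a in arrs:
        out.append(ranks[i : i + len(a)])
        i += len(a)
    return out


def kruskal_wallis(groups) -> RankTestResult:
    """Kruskal-Wallis H with mid-rank tie correction, chi-square p."""
    arrs, labels = _as_arrays(groups)
    if len(arrs) < 2 or sum(map(len, arrs)) < 3:
        raise ValueError("need >=2 groups and total n >= 3")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; H undefined")
    h, p = sps.kruskal(*arrs)
    return RankTestResult(
        test="kruskal-wallis",
        statistic=float(h),
        df=float(len(arrs) - 1),
        p=float(p),
        groups=labels,
    )


def welch_anova_ranks(groups) -> RankTestResult:
    """Welch's heteroscedastic one-way ANOVA computed on global mid-ranks."""
    arrs, labels = _as_arrays(groups)
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    ranked = _global_ranks(arrs)
    k = len(ranked)
    n = np.array([len(a) for a in ranked], dtype=float)
    m = np.array([a.mean() for a in ranked])
    s2 = np.array([a.var(ddof=1) for a in ranked])
    if (s2 == 0).any():
        raise ValueError("a group has zero rank variance")
    w = n / s2
    W = w.sum()
    mw = (w * m).sum() / W
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    tmp = ((1 - w / W) ** 2 / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    f = num / den
    df2 = (k**2 - 1) / (3 * tmp)
    p = sps.f.sf(f, k - 1, df2)
    return RankTestResult(
        test="welch-anova-ranks",
        statistic=float(f),
        df=(float(k - 1), float(df2)),
        p=float(p),
        groups=labels,
    )


def games_howell_ranks(groups) -> list[RankTestResult]:
    """Games-Howell pairwise comparisons computed on global mid-ranks.

    For each pair: t = |dm| / sqrt(s_i^2/n_i + s_j^2/n_j) with
    Welch-Satterthwaite df; p from the studentized range distribution with
    q = t*sqrt(2) and k = total number of groups.
    """
    arrs, labels = _as_arrays(groups)
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    ranked = _global_ranks(arrs)
    k = len(ranked)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = ranked[i], ranked[j]
            ni, nj = len(a), len(b)
            vi, vj = a.var(ddof=1), b.var(ddof=1)
            se2 = vi / ni + vj / nj
            if se2 == 0:
                raise ValueError(
                    f"zero pooled rank variance for pair ({labels[i]}, {labels[j]})"
                )
            t = abs(a.mean() - b.mean()) / np.sqrt(se2)
            df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
            p = sps.studentized_range.sf(t * np.sqrt(2.0), k, df)
            out.append(
                RankTestResult(
                    test="games-howell-ranks",
                    statistic=float(t),
                    df=float(df),
                    p=float(min(p, 1.0)),
                    groups=(labels[i], labels[j]),
                )
            )
    return out


@dataclass
class DepthTestDecision:
    chosen: str  # "kruskal-wallis" | "welch-anova-ranks"
    result: RankTestResult
    posthoc: list[RankTestResult] | None
    shapiro_p: dict[str, float]
    levene_p: float
    notes: list[str] = field(default_factory=list)


def select_depth_test(groups, alpha: float = 0.05) -> DepthTestDecision:
    """Route a depth-group comparison through the appropriate rank test.

    Normality is screened per group with Shapiro-Wilk and homoscedasticity
    with the Brown-Forsythe (median-centered Levene) test.  Heteroscedastic
    data go to Welch's ANOVA on ranks (with Games-Howell post hoc if
    significant); homoscedastic data go to Kruskal-Wallis.  Data passing
    both screens still route to Kruskal-Wallis, with a note, to keep the
    pipeline rank-based throughout.
    """
    arrs, labels = _as_arrays(groups)
    if len(arrs) < 2 or any(len(a) < 3 for a in arrs):
        raise ValueError("need >=2 groups with n >= 3 each")
    shapiro_p = {}
    notes: list[str] = []
    for lab, a in zip(labels, arrs):
        if np.ptp(a) == 0:
            shapiro_p[lab] = 0.0
            notes.append(f"group {lab} constant; treated as non-normal")
        else:
            shapiro_p[lab] = float(sps.shapiro(a).pvalue)
    levene_p = float(sps.levene(*arrs, center="median").pvalue)
    normal = all(p > alpha for p in shapiro_p.values())
    homoscedastic = levene_p > alpha
    if normal and homoscedastic:
        notes.append(
            "data screen as normal and homoscedastic; using Kruskal-Wallis to "
            "stay rank-based"
        )
    if homoscedastic:
        named = dict(zip(labels, arrs))
        res = kruskal_wallis(named)
        res = RankTestResult(res.test, res.statistic, res.df, res.p, labels)
        return DepthTestDecision("kruskal-wallis", res, None, shapiro_p, levene_p, notes)
    named = dict(zip(labels, arrs))
    res = welch_anova_ranks(named)
    posthoc = games_howell_ranks(named) if res.p < alpha else None
    return DepthTestDecision(
        "welch-anova-ranks", res, posthoc, shapiro_p, levene_p, notes
    )


# ---------------------------------------------------------------------------
# species accumulation


def species_accumulation(
    presence: pd.DataFrame | np.ndarray,
    n_perm: int = 100,
    seed: int | None = None,
    method: str = "random",
) -> AccumulationCurve:
    """Species accumulation curve.

    ``method="random"`` is the random-accumulator estimate: for each number
    of samples n = 1..N, the mean and sample sd of the cumulative richness
    over ``n_perm`` random orderings of the sample rows.

    ``method="exact"`` returns the analytic expectation over all N!
    orderings: E[S(n)] = sum_j [1 - C(N - N_j, n) / C(N, n)] where N_j is
    the number of samples containing species j (sd is reported as 0).
    """
    x = np.asarray(presence, dtype=bool)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("presence must be a samples x species matrix")
    n, _ = x.shape
    if method == "exact":
        from scipy.special import gammaln

        occ = x.sum(axis=0)  # samples per species

        def log_comb(a, b):
            return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

        mean = np.empty(n)
        for m in range(1, n + 1):
            with np.errstate(invalid="ignore"):
                miss = np.where(
                    n - occ >= m,
                    np.exp(log_comb(n - occ, m) - log_comb(n, m)),
                    0.0,
                )
            mean[m - 1] = (1.0 - miss).sum()
        return AccumulationCurve(
            n_samples=np.arange(1, n + 1),
            mean_richness=mean,
            sd_richness=np.zeros(n),
            n_permutations=0,
            seed=seed,
        )
    if method != "random":
        raise ValueError(f"unknown accumulation method {method!r}")
    rng = np.random.default_rng(seed)
    rich = np.empty((n_perm, n))
    for p in range(n_perm):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(x[order], axis=0)
        rich[p] = seen.sum(axis=1)
    return AccumulationCurve(
        n_samples=np.arange(1, n + 1),
        mean_richness=rich.mean(axis=0),
        sd_richness=rich.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n),
        n_permutations=n_perm,
        seed=seed,
    )
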