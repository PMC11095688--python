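"""Presence matrices, Ward clustering, silhouettes, cohesion, density regions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from edna_assemblage import cluster as cl
from edna_assemblage import stats as st


def _dmat(points):
    pts = np.asarray(points, dtype=float).reshape(-1, 1)
    d = cdist(pts, pts)
    d = d / max(d.max(), 1.0)
    ids = [f"u{i}" for i in range(len(pts))]
    return st.DissimilarityMatrix(
        values=pd.DataFrame(d, index=ids, columns=ids), metric="jaccard"
    )


def _wss_of_partition(d2, parts):
    total = 0.0
    for c in parts:
        idx = list(c)
        total += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return total


def _best_two_partition(d):
    """Exhaustive search over all 2-cluster partitions minimizing WSS."""
    n = d.shape[0]
    d2 = d**2
    best, best_val = None, np.inf
    for mask in range(1, 2 ** (n - 1)):
        a = [i for i in range(n) if mask >> i & 1]
        b = [i for i in range(n) if not mask >> i & 1]
        if not a or not b:
            continue
        val = _wss_of_partition(d2, [a, b])
        if val < best_val:
            best, best_val = (frozenset(a), frozenset(b)), val
    return frozenset(best)


class TestWard:
    def test_two_pairs_recovered(self):
        d = _dmat([0.0, 0.1, 10.0, 10.1])
        dend = cl.ward_cluster(d)
        labels = cl.cut_clusters(dend, 2)
        assert labels["u0"] == labels["u1"]
        assert labels["u2"] == labels["u3"]
        assert labels["u0"] != labels["u2"]

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_k2_cut_matches_exhaustive_partition_search(self, n, seed):
        """Ward's greedy k=2 cut agrees with the exhaustive minimum-WSS
        2-partition on small well-separated instances."""
        rng = np.random.default_rng(seed)
        # two separated 1-D clouds so the greedy merge order is safe
        pts = np.concatenate([rng.normal(0, 0.5, n // 2), rng.normal(8, 0.5, n - n // 2)])
        rng.shuffle(pts)
        d = _dmat(pts)
        labels = cl.cut_clusters(cl.ward_cluster(d), 2).to_numpy()
        mine = frozenset(
            frozenset(np.where(labels == c)[0]) for c in np.unique(labels)
        )
        oracle = _best_two_partition(d.values.to_numpy())
        assert mine == oracle

    def test_duplicate_leaves_merge_at_zero(self):
        d = _dmat([1.0, 1.0, 5.0])
        dend = cl.ward_cluster(d)
        assert dend.linkage[0, 2] == pytest.approx(0.0)

    def test_n2_single_merge(self):
        d = _dmat([0.0, 1.0])
        dend = cl.ward_cluster(d)
        assert dend.linkage.shape == (1, 4)

    def test_heights_monotone_and_cuts_nest(self):
        rng = np.random.default_rng(5)
        d = _dmat(rng.normal(0, 1, 12))
        dend = cl.ward_cluster(d)
        assert (np.diff(dend.linkage[:, 2]) >= -1e-9).all()
        for k in range(2, 12):
            fine = cl.cut_clusters(dend, k)
            coarse = cl.cut_clusters(dend, k - 1)
            # nesting: every fine cluster lies inside one coarse cluster
            for c in fine.unique():
                members = fine.index[fine == c]
                assert coarse[members].nunique() == 1

    def test_cut_extremes(self):
        d = _dmat([0.0, 1.0, 2.0, 5.0])
        dend = cl.ward_cluster(d)
        assert cl.cut_clusters(dend, 1).nunique() == 1
        assert cl.cut_clusters(dend, 4).nunique() == 4

    def test_labels_ordered_by_size(self):
        d = _dmat([0.0, 0.1, 0.2, 10.0])
        labels = cl.cut_clusters(cl.ward_cluster(d), 2)
        assert (labels[["u0", "u1", "u2"]] == 1).all()  # bigger cluster first
        assert labels["u3"] == 2


class TestSilhouette:
    def _two_cluster_fixture(self):
        # within-cluster distance 0.1, all cross distances 0.9
        v = np.full((4, 4), 0.9)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.1
        np.fill_diagonal(v, 0.0)
        ids = list("abcd")
        d = st.DissimilarityMatrix(
            values=pd.DataFrame(v, index=ids, columns=ids), metric="jaccard"
        )
        labels = pd.Series([1, 1, 2, 2], index=ids)
        return d, labels

    def test_hand_value_eight_ninths(self):
        d, labels = self._two_cluster_fixture()
        w = cl.silhouette_widths(d, labels)
        np.testing.assert_allclose(w, (0.9 - 0.1) / 0.9)

    def test_singleton_width_zero(self):
        v = np.array([[0.0, 0.2, 0.9], [0.2, 0.0, 0.9], [0.9, 0.9, 0.0]])
        ids = list("abc")
        d = st.DissimilarityMatrix(
            values=pd.DataFrame(v, index=ids, columns=ids), metric="jaccard"
        )
        w = cl.silhouette_widths(d, pd.Series([1, 1, 2], index=ids))
        assert w["c"] == pytest.approx(0.0)

    def test_identical_points_width_zero(self):
        v = np.zeros((4, 4))
        ids = list("abcd")
        d = st.DissimilarityMatrix(
            values=pd.DataFrame(v, index=ids, columns=ids), metric="jaccard"
        )
        w = cl.silhouette_widths(d, pd.Series([1, 1, 2, 2], index=ids))
        np.testing.assert_allclose(w, 0.0)

    def test_bounds(self):
        rng = np.random.default_rng(6)
        d = _dmat(rng.normal(0, 1, 10))
        labels = cl.cut_clusters(cl.ward_cluster(d), 3)
        w = cl.silhouette_widths(d, labels)
        assert ((w >= -1) & (w <= 1)).all()


class TestWss:
    def test_k_equals_n_is_zero(self):
        d = _dmat([0.0, 1.0, 3.0])
        dend = cl.ward_cluster(d)
        curve = cl.wss_curve(d, dend, 3)
        assert curve[3] == pytest.approx(0.0)

    def test_k1_formula_instance(self):
        d = _dmat([0.0, 1.0, 3.0])
        dend = cl.ward_cluster(d)
        curve = cl.wss_curve(d, dend, 1)
        d2 = d.values.to_numpy() ** 2
        expected = d2[np.triu_indices(3, 1)].sum() / 3
        assert curve[1] == pytest.approx(expected)

    def test_matches_brute_force_per_cluster_sums(self):
        rng = np.random.default_rng(7)
        d = _dmat(rng.normal(0, 1, 9))
        dend = cl.ward_cluster(d)
        curve = cl.wss_curve(d, dend, 5)
        d2 = d.values.to_numpy() ** 2
        for k in range(1, 6):
            labels = cl.cut_clusters(dend, k).to_numpy()
            parts = [np.where(labels == c)[0] for c in np.unique(labels)]
            assert curve[k] == pytest.approx(_wss_of_partition(d2, parts))
        assert (np.diff(curve.to_numpy()) <= 1e-12).all()


class TestElbow:
    def test_printed_example_k2(self):
        curve = pd.Series({1: 100.0, 2: 40.0, 3: 20.0, 4: 15.0, 5: 13.0})
        k, warns = cl.choose_k_elbow(curve)
        assert k == 2 and not warns

    def test_linear_decline_warns_k1(self):
        curve = pd.Series({1: 10.0, 2: 8.0, 3: 6.0, 4: 4.0})
        k, warns = cl.choose_k_elbow(curve)
        assert k == 1 and warns


class TestCohesion:
    def _solution(self, widths_by_cluster):
        labels, widths = {}, {}
        i = 0
        for c, ws in widths_by_cluster.items():
            for w in ws:
                labels[f"s{i}"] = c
                widths[f"s{i}"] = w
                i += 1
        lab = pd.Series(labels)
        wid = pd.Series(widths)
        sol = cl.ClusterSolution(
            k=len(widths_by_cluster),
            labels=lab,
            silhouette=wid,
            cluster_mean_width={
                c: float(np.mean(ws)) for c, ws in widths_by_cluster.items()
            },
            cluster_negative_fraction={
                c: float(np.mean(np.array(ws) < 0))
                for c, ws in widths_by_cluster.items()
            },
        )
        return sol

    def test_printed_width_sets(self):
        sol = self._solution({
            1: [0.3, 0.2, -0.05, 0.4],   # mean ok but 25% negative
            2: [0.3, 0.2, 0.1, 0.4],     # cohesive
            3: [0.05, 0.05, 0.05],       # mean below 0.1
        })
        flags = cl.cohesive_clusters(sol)
        assert flags == {1: False, 2: True, 3: False}


class TestSummary:
    def test_top_species_frequency_and_ties(self):
        values = pd.DataFrame(
            {"zeta": [1, 1, 1], "alpha": [1, 1, 0], "beta": [1, 1, 0]},
            index=["s1", "s2", "s3"],
        ).astype(bool)
        pm = cl.PresenceMatrix(values=values, marker="12S")
        labels = pd.Series(1, index=values.index)
        summary = cl.cluster_summary(pm, labels, top_n=2)
        tops = summary[1]["top_species"]
        assert tops[0]["species"] == "zeta" and tops[0]["frequency"] == 1.0
        assert tops[1]["species"] == "alpha"  # alphabetical among ties
        assert summary[1]["richness"] == 3
        assert summary[1]["mean_species_per_sample"] == pytest.approx(7 / 3)

    def test_top_n_larger_than_richness(self):
        values = pd.DataFrame({"a": [1], "b": [1]}, index=["s1"]).astype(bool)
        pm = cl.PresenceMatrix(values=values, marker="12S")
        summary = cl.cluster_summary(pm, pd.Series(1, index=["s1"]), top_n=10)
        assert len(summary[1]["top_species"]) == 2
        assert summary[1]["sd_species_per_sample"] == 0.0


class TestPresenceMatrix:
    def test_collapse_filters_and_planted_truth(self, separable_ds):
        from edna_assemblage.decontam import decontaminate
        from edna_assemblage.standardize import classify_diel_samples

        ds = separable_ds
        clean, _ = decontaminate(ds.asv_12s, ds.taxonomy, ds.metadata)
        diel = classify_diel_samples(ds.metadata)
        pm = cl.build_presence_matrix(clean, ds.taxonomy, diel=diel, min_samples=3)
        # every matrix species is a planted species-level 12S species
        truth_species = {
            name
            for name, s in ds.truth.species.items()
            if s["marker"] == "12S" and s["species_level"]
        }
        assert set(pm.species) <= truth_species
        # collapse semantics: species present iff any member ASV present
        lin = ds.taxonomy.lineages
        sid = pm.sample_ids[0]
        for sp in pm.species[:10]:
            member_asvs = [
                a for a in clean.asv_ids
                if a in lin.index and lin.at[a, "species"] == sp
            ]
            expected = bool((clean.counts.loc[member_asvs, sid] > 0).any())
            assert bool(pm.values.at[sid, sp]) == expected

    def test_min_samples_strictly_fewer_than(self):
        counts = pd.DataFrame(
            {"s1": [1, 1], "s2": [1, 0], "s3": [1, 0]}, index=["x1", "x2"]
        )
        from edna_assemblage.tables import AsvCountTable, TaxonomyTable

        tax = TaxonomyTable(
            lineages=pd.DataFrame.from_dict(
                {
                    "x1": {"phylum": "Chordata", "genus": "Ga", "species": "Ga a"},
                    "x2": {"phylum": "Chordata", "genus": "Gb", "species": "Gb b"},
                },
                orient="index",
            ).fillna("")
        )
        t = AsvCountTable("12S", counts)
        pm = cl.build_presence_matrix(
            t, tax, diel=None, min_samples=3, drop_clades=[], diel_filter=None
        )
        assert pm.species == ["Ga a"]  # Gb b present in only 2 samples

    def test_empty_result_raises(self):
        counts = pd.DataFrame({"s1": [1]}, index=["x1"])
        from edna_assemblage.tables import AsvCountTable, TaxonomyTable

        tax = TaxonomyTable(
            lineages=pd.DataFrame.from_dict(
                {"x1": {"phylum": "Chordata"}}, orient="index"
            ).fillna("")
        )
        with pytest.raises(ValueError, match="survive"):
            cl.build_presence_matrix(
                AsvCountTable("12S", counts), tax, diel=None,
                min_samples=1, drop_clades=[], diel_filter=None,
            )


class TestDensityRegion:
    def test_gaussian_coverage_and_radius(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1, size=(2000, 2))
        region = cl.density_region_50(pts)
        assert region.enclosed_mass == pytest.approx(0.5, abs=0.02)
        # for a round Gaussian the 50% HDR is a disk of radius sqrt(2 ln 2)
        area = region.polygons.area
        radius = np.sqrt(area / np.pi)
        assert radius == pytest.approx(np.sqrt(2 * np.log(2)), rel=0.1)
        # fraction of true-distribution draws inside the region; estimated
        # with enough points that Monte-Carlo error (~0.007 at 2 sd) is
        # small against the 0.05 band, which must absorb the KDE's
        # bandwidth-smoothing bias (~+0.04 at Scott bandwidth, n=2000)
        from shapely.geometry import Point
        from shapely.prepared import prep

        fresh = rng.normal(0, 1, size=(20000, 2))
        pp = prep(region.polygons)
        inside = np.mean([pp.contains(Point(*p)) for p in fresh])
        assert inside == pytest.approx(0.5, abs=0.05)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1, size=(400, 2))
        r1 = cl.density_region_50(pts)
        r2 = cl.density_region_50(pts + np.array([10.0, -5.0]))
        c1 = np.array(r1.polygons.centroid.coords[0])
        c2 = np.array(r2.polygons.centroid.coords[0])
        np.testing.assert_allclose(c2 - c1, [10.0, -5.0], atol=1e-6)
        assert r2.polygons.area == pytest.approx(r1.polygons.area, rel=1e-6)

    def test_two_separated_clouds_two_polygons(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 0.5, size=(300, 2))
        b = rng.normal(12, 0.5, size=(300, 2))
        region = cl.density_region_50(np.vstack([a, b]))
        assert len(region.polygons.geoms) >= 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cl.density_region_50(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            cl.density_region_50(np.column_stack([np.arange(10), np.zeros(10)]))
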