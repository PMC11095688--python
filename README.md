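# edna-assemblage

Community analysis of **low-volume eDNA metabarcoding samples** from the
deep pelagic ocean: decontamination of ASV tables, standardization against
depth-discrete trawl catches, proportional-occurrence community comparison,
depth-profile statistics, and presence-based assemblage biogeography via
cohesion-filtered hierarchical clustering.

The package is aimed at marine molecular ecologists working with
metabarcoding data (12S rRNA for vertebrates, COI for invertebrates) from
oceanographic surveys where seawater budgets limit filtration volumes to a
few hundred mL to ~2 L, and where a net-based sampler (e.g. a MOCNESS
multi-net trawl) provides the morphological comparison. Because no
sequence-read abundance is comparable across taxa, every analysis here is
presence-based.

## What it computes

**Decontamination.** Samples with fewer than 1,000 reads are treated as
failed sequencing; ASVs matching non-marine taxa (for 12S: Primates,
Galliformes, Rodentia, Bovidae, Suidae, Chiroptera, Cypriniformes; for COI:
three non-native bivalves) are removed; vertebrate ASVs are stripped from
COI; and, per cruise, any ASV detected in a negative control is removed
from that cruise's environmental samples. Samples whose DNA concentration
was below detection are excluded, never zeroed.

**Method comparison.** Composition is the *proportional occurrence* of
mutually exclusive taxonomic groups: for eDNA sample *j* and group *g*,

    p_gj = (# present ASVs in g) / (# present ASVs in any group),

with taxa instead of ASVs for trawl nets. Samples within 1° latitude and
2° longitude of a trawl site share its zone; zone × depth-bin aggregates of
the two methods are compared with a one-sided Mantel permutation test on
Morisita–Horn dissimilarities,

    d_MH(x, y) = 1 − 2 Σᵢ xᵢyᵢ / [(λx + λy) Nx Ny],  λx = Σᵢ xᵢ² / Nx².

**Depth profiles.** Per sample: volume-corrected DNA concentration
(measured × 1000 mL / volume), reads/mL, ASVs/mL, and the proportion of
present ASVs assigned to species. Each metric is compared across depth
groups (0–200 m, 200–600 m, >600 m — the approximate daytime and nighttime
deep-scattering-layer boundaries) with a Kruskal–Wallis test when groups
screen as homoscedastic (Brown–Forsythe) or Welch's ANOVA on global
mid-ranks otherwise, followed by Games–Howell pairwise tests on ranks.

**Assemblage biogeography.** Night-collected samples (from 90 min after
sunset to 90 min before sunrise) are clustered on Jaccard dissimilarities
of species-level presences (species in <3 samples dropped; mammals and
birds dropped from 12S) with Ward's minimum-variance criterion. The number
of clusters comes from the elbow (maximum second difference) of the
within-cluster sum-of-squares curve, cross-checked against mean silhouette
widths. A cluster is *cohesive* when its mean silhouette width is ≥ 0.1 and
fewer than 15% of members have negative widths; cohesive clusters are
summarized by their top-10 most frequent species, species accumulation
curves, and 50% probability-density contours of member positions.

**Synthetic data.** `edna_assemblage.synthetic` generates complete input
datasets with planted ground truth — spatial assemblages with depth niches,
species→many-ASV multiplicity (inflated for COI), negative-control
contamination, non-marine bycatch, negative-binomial read totals allocated
via Dirichlet-multinomials, and DNA concentration decaying an order of
magnitude from the epipelagic to below 600 m — so every pipeline stage is
testable against known truth without any downloads.

## Worked example

```sh
edna-assemblage simulate --preset paper-like --seed 42 --out demo/inputs
edna-assemblage decontaminate --in demo/inputs --out demo/decontam
edna-assemblage depth-profile  --in demo/inputs --out demo/depth
edna-assemblage compare-methods --in demo/inputs --out demo/methods --seed 42
edna-assemblage cluster --in demo/inputs --out demo/clusters --marker 12S --seed 42
```

prints (abridged):

```
[12S] low-read-samples: -33 samples, -0 ASVs, -16772 reads
[12S] blocklist: -0 samples, -3 ASVs, -132308 reads
[12S] control-asvs: -8 samples, -10 ASVs, -3953159 reads
[12S] below-detection: -22 samples, -0 ASVs, -344133 reads
[12S] dna_concentration_per_l: welch-anova-ranks stat=303.89 p=3.61e-40
[12S] reads_per_ml: kruskal-wallis stat=3.38 p=0.185
Mantel r = -0.040, p = 0.539
[12S] k=3 (elbow), 2 cohesive cluster(s)
```

Reading this: 33 of 444 samples failed sequencing (<1,000 reads); 3 ASVs
hit the non-marine blocklist; 10 ASVs seen in the cruise's negative
controls were removed along with the 8 control samples; 22 deep samples
had below-detection DNA. The planted exponential concentration decay is
recovered as a strongly significant Welch's ANOVA on ranks, while reads/mL
shows no depth effect. eDNA and trawl compositions are uncorrelated across
zone × depth units (Mantel p = 0.539), and the elbow picks 3 clusters of
which 2 pass the silhouette cohesion rule on this draw. The same pipeline
is available as one command, `edna-assemblage run --config run.yaml`, which
also writes a Markdown report.

Library use mirrors the CLI:

```python
import edna_assemblage as ea

cfg = ea.preset("separable-3"); cfg.seed = 42
ds = ea.generate(cfg)
clean, report = ea.decontaminate(ds.asv_12s, ds.taxonomy, ds.metadata)
res = ea.cluster_assemblages(clean, ds.taxonomy, ds.metadata, seed=42)
print(res.k, res.solution.cohesive)   # -> 3 {1: True, 2: True, 3: True}
```

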