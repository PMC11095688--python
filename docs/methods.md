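# Methods

This note documents the models, statistical procedures, numerical choices
and known limitations of the `edna_assemblage` pipeline, in the order the
stages run.

## Input model and conventions

Four tables drive everything: an ASV × sample read-count table per marker
(12S for vertebrates, COI for invertebrates), a taxonomy table giving each
ASV or trawl taxon a ranked lineage over
{kingdom, phylum, subphylum, class, order, series, family, genus, species},
per-sample metadata (position, depth, filtered volume, UTC timestamp,
control flag, measured DNA concentration, local sunrise/sunset), and a
trawl catch table. Conventions that matter downstream:

* **Below-detection DNA** is the literal token `BD` on disk and a boolean
  flag in memory, distinct from zero: such samples are excluded from
  concentration analyses, never imputed.
* **Lineage gaps.** A name below an empty rank is accepted with a warning
  and the empty rank treated as unranked; the intermediate ranks
  `subphylum` and `series` are optional and never flagged (most lineages
  legitimately omit them).
* ASVs absent from the taxonomy are retained and treated as fully
  unassigned: they survive taxon-based filters (they cannot be matched) but
  are excluded from group-based metrics. This keeps unassignable
  contamination visible rather than silently dropped.
* Coordinates are decimal degrees, west negative. All ids are
  case-sensitive opaque strings.

## Decontamination

Filters run in a fixed, tested order: (1) drop samples with **fewer than
1,000 reads** (strict `<`; the threshold judges sequencing success on the
raw post-denoising totals); (2) remove ASVs whose lineage matches the
marker's non-marine blocklist; (3) for COI only, remove subphylum
Vertebrata (the 12S primers cover vertebrates better); (4) per cruise,
remove every ASV with ≥1 read in any of that cruise's negative controls
from that cruise's environmental samples, and drop the control columns
(a `global` scope is available for sensitivity analysis); (5) exclude
environmental samples whose DNA concentration was below detection.

Each step logs samples/ASVs/reads removed and the report asserts exact
conservation (initial − removed = final). The steps that remove ASVs are
individually idempotent. The chain as a whole is *not* exactly idempotent:
re-running it re-applies the read threshold to cleaned totals, which can
drop samples whose reads were dominated by removed contaminants. This is
inherent to thresholding on pre-filter totals (the convention used here)
and is documented and pinned by a regression test rather than hidden.

## Standardization

**Taxonomic groups** are assigned by an ordered first-match-wins rule list,
which makes groups mutually exclusive by construction. Defaults: vertebrates
at the order level, except fish series (Ovalentaria, Eupercaria) where the
order is incertae sedis; invertebrates with arthropods split at class,
cnidarians at order, and all other phyla kept whole. Custom schemes load
from YAML rule lists.

**Zones.** A sample joins the zone of a trawl site when it lies within
±1° latitude and ±2° longitude of it. Where synthetic zone boxes overlap,
ties break to the nearest center under the coordinate-normalized Chebyshev
distance max(Δlat/1°, Δlon/2°), so assignment is independent of site
ordering.

**Depth bins** are lower-open/upper-closed: 200 m falls in 0–200 and 600 m
in 200–600, with a strictly-greater-than final bin. Three presets:
shallow/deep at 200 m for the method comparison, 0–200/200–600/>600 for the
depth profiles (the ~daytime and nighttime deep-scattering-layer
boundaries), and shallow/deep at 120 m for mapping cluster distributions.

**Diel class.** Night runs from 90 min after sunset to 90 min before
sunrise; day is the mirror-image window; everything else is transitional.
Comparison is modulo 24 h, so classifications are invariant to representing
a time on either side of midnight. Sunrise/sunset are metadata inputs, not
computed — solar geometry is out of scope and fixtures control it exactly.

**Proportional occurrence.** Per unit (sample or net), the fraction of
presences (ASVs for eDNA, taxa for trawls) belonging to each group.
Unassigned records are excluded from numerator *and* denominator; rows sum
to 1. Zone × bin aggregation defaults to averaging sample rows then
renormalizing (the metric is defined per sample); a `pool` mode recomputes
from pooled presence counts for sensitivity.

## Community statistics

* **Morisita–Horn** d = 1 − 2Σxᵢyᵢ/[(λx+λy)NxNy] with λx = Σxᵢ²/Nx²;
  invariant to rescaling either vector, clamped to [0, 1] against rounding.
* **Jaccard (binary)** d = 1 − |a∩b|/|a∪b|; an error when both sets are
  empty.
* **Mantel test:** Pearson correlation of strictly-lower-triangle vectors;
  one-sided (greater) with simultaneous row/column permutation of the
  second matrix; 999 permutations by default. p = (1 + hits)/(n_perm + 1),
  so p is never zero. Defaults follow the common ecology convention since
  the analysis this reimplements reports only r and p.
* **Depth-group battery.** All tests operate on global mid-ranks so results
  are invariant to monotone transforms of the metric. Routing: Shapiro–Wilk
  per group and Brown–Forsythe (median-centered Levene) at α = 0.05;
  heteroscedastic data go to Welch's heteroscedastic ANOVA on the ranks
  (Welch–Satterthwaite df), with Games–Howell pairwise tests
  (t = |Δm̄|/√(s²ᵢ/nᵢ + s²ⱼ/nⱼ), p from the studentized range with
  q = t√2) when the global test is significant; homoscedastic data go to
  Kruskal–Wallis with the standard tie correction. Data screening as both
  normal and homoscedastic still route to Kruskal–Wallis, with a logged
  note — staying rank-based keeps the whole battery monotone-invariant, and
  real eDNA metrics essentially never take that branch. Welch's ANOVA is
  computed on raw mid-ranks (no normal-scores transform).
* **Species accumulation:** the random-accumulator estimate (mean ± n−1 sd
  of cumulative richness over random sample orderings; 100 by default) plus
  an exact mode using the closed form E[S(n)] = Σⱼ [1 − C(N−Nⱼ, n)/C(N, n)],
  which the tests verify against exhaustive enumeration at N = 5.

## Clustering and cohesion

ASVs collapse to species (present if any member ASV is present); only
species-level identifications enter, so labels are mutually exclusive.
Species in fewer than 3 samples are dropped, as are mammals and birds from
12S and all non-night samples. Ward's minimum-variance clustering uses the
squared-distance (ward.D2-equivalent) update on the Jaccard matrix; cluster
labels are renumbered by size then smallest member id, making solutions
platform-reproducible. WSS(k) = Σ_c Σ_{i<j∈c} d²ᵢⱼ/n_c is evaluated on
dendrogram cuts for k = 1..8 (or n−1 if smaller).

The elbow is formalized as the interior k maximizing the discrete second
difference of the WSS curve; the mean-silhouette curve is computed
alongside, a disagreement between the two criteria is logged, and `--k`
overrides both (the visual elbow in the original workflow is a judgment
call, so the choice must be inspectable). Silhouette widths use the
standard (b−a)/max(a,b) definition with singleton clusters — and 0/0 for
coincident points — scored 0. A cluster is cohesive iff its mean width is
≥ 0.1 *and* strictly fewer than 15% of members have negative widths.

**50% density regions.** Member positions (lon/lat treated as planar,
adequate over a few degrees of extent) feed a Scott-bandwidth Gaussian KDE
evaluated on a 256×256 grid padded by 3 bandwidths; the threshold is the
density level at which cells at or above it capture 50% of the integrated
density, and polygons are traced at that level. Every call asserts the
enclosed KDE mass is within max(0.02, one cell's share) of nominal. Note
the *true-distribution* mass enclosed exceeds 0.5 by the KDE's smoothing
bias (≈ +0.04 for a round Gaussian at n = 2000, Scott bandwidth); the
calibration tests measure and bound this.

## Synthetic data generator

The generator emulates the survey structure the pipeline assumes; its
defaults are the study conditions, not tuning knobs.

* **Assemblages** have spatial centers and Gaussian depth niches. A species
  belongs to one assemblage; detection probability is p_out = 0.03
  background everywhere and rises to p_in = 0.75 at the assemblage's core
  depth (Gaussian kernel in depth). Between-assemblage mixing is therefore
  governed by p_out, and the recoverability tests degrade recovery by
  raising it.
* **Reads.** Per-sample totals are negative-binomial (gamma–Poisson, shape
  1.5) around 24k (12S) / 32k (COI); ~12% of samples draw failed-sequencing
  totals under 900 reads, exercising the 1,000-read filter. Occupied
  species receive Dirichlet(1) weights and spread reads over their ASVs by
  a symmetric Dirichlet(0.8)-multinomial, so presence-collapse to species
  is invariant to ASV multiplicity — the reason the clustering collapses
  ASVs in the first place.
* **Multiplicity.** ASVs per species: 1 + Poisson(1.1) for 12S (mean ≈ 2.1)
  and 1 + ⌊lognormal(2.3, 1.2)⌋ for COI (heavy-tailed, mean ≈ 20 at the
  paper-like scale — large enough to inflate COI richness by an order of
  magnitude while keeping desk-scale runtimes).
* **Contamination.** Per marker, a fixed number of marine ASVs (7 for 12S,
  20 for COI) plus 3 taxonomy-less ASVs receive reads in every negative
  control and, with prevalence 0.6, in environmental samples; controls
  receive reads from *only* these ASVs. Non-marine bycatch ASVs (blocklist
  taxa) and vertebrate bycatch in COI appear at moderate prevalence.
  Added reads scale with the sample's sequencing depth so failed samples
  stay failed.
* **DNA concentration** = 3.6 ng/µl × exp(−depth/300 m) × lognormal(0,
  0.35) noise, floored at the 0.05 ng/µl detection limit. The multiplicative
  noise makes shallow samples more variable in absolute terms — the
  heteroscedasticity that routes the real concentration comparison to
  Welch's ANOVA — and yields the order-of-magnitude shallow (<200 m) to
  deep (>600 m) contrast. Samples whose draw falls below the floor are
  written as `BD`.
* **Trawl nets** sample the same latent communities at zone sites with
  depth-stratified nets and group-specific catchability (gelatinous groups
  down-weighted), Poisson counts at effort 9 individuals per fully
  detected species.
* **Presets.** `paper-like`: 2 cruises, 40 casts, 436 environmental samples
  from 1–2200 m (~70% shallower than 200 m), 8 negative controls, three
  overlapping-depth assemblages. `separable-3`: three well-separated
  shallow assemblages, all-night sampling, for recovery tests. `null`: one
  spatially flat assemblage (p_in = p_out) for calibration. A single seed
  fixes every byte of a generated dataset.

What the generator does *not* emulate: sequence-level error (chimeras, PCR
and primer bias), spatial autocorrelation within assemblages, seasonal or
diel changes in the latent community, tag-jumping between samples, and
reference-library growth. Passing recovery tests therefore demonstrate the
*pipeline's* correctness on data satisfying its assumptions, not field
performance of eDNA methods.

## Problem sizes and calibration checks

The test suite and the acceptance script run entirely on generated data:
clustering recovery uses ~70-sample, ~40-species datasets; the Mantel
calibration uses 1,500 null replicates of 10-unit matrices at 99
permutations; the rank-test calibrations use 2,000 replicates of 3×20
draws (beyond the 500-replicate minimum, so Monte-Carlo noise is small
against the ±0.02 tolerance of the nominal 0.05 level — the rank tests
are mildly conservative, with true levels ≈ 0.040–0.044 at these group
sizes); density-region coverage uses 2,000 KDE points and 20,000
Monte-Carlo evaluation points. The full suite runs in well under a minute
on one CPU.

## Known limitations

* Planar treatment of lon/lat in the KDE distorts areas poleward; fine for
  a ~5°×8° study box, wrong for basin scales.
* The elbow rule on a discrete second difference can be unstable on flat
  WSS curves; the solver then logs a warning and falls back to k = 1, and
  the CLI exposes `--k` for manual override.
* Games–Howell p-values rely on the studentized-range distribution, which
  is asymptotic; at group sizes below ~5 the familywise control is
  approximate.
* The per-cruise control rule removes an entire ASV on a single control
  read; prevalence- or concentration-based decontamination models are
  deliberately out of scope.
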