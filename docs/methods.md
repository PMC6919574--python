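# Methods

## Data model

An isolate's genotype is a map from 12 microsatellite loci to sets of
integer allele sizes (bp). The markers are codominant: every allele an
individual carries is observed, so the set size at a locus reflects the
local copy number. An empty set is a missing datum (failed amplification
or sizing). Canonical genotype identity is a string key — loci in panel
order, alleles ascending, missing marked `.` — so two genotypes are equal
iff their keys are equal.

Putative ploidy is the maximum set size over loci: ≤2 → possible diploid,
3 → possible triploid. A locus with one allele is read as homozygous, not
haploid, so ploidy is never reported below 2. This is an upper-bound-style
inference (a triploid homozygous everywhere would pass as diploid); it is
the standard reading of codominant marker counts and is used as-is.

## Plate normalization

Fragment-sizing runs drift by whole repeat units between microplates. A
control strain genotyped on every plate anchors the correction: per plate
and per locus, the offset is the modal element-wise difference between the
plate's sorted control alleles and the reference plate's, and that integer
is subtracted from every allele on the plate. The mode is robust to a
single discordant control allele; ties break to the smallest-magnitude
offset. A locus where the control's allele count differs between plates
cannot be aligned element-wise and is skipped with a warning. Missing
cells pass through unchanged, and the operation is idempotent. Because a
table's strain ids are unique, the per-plate control replicates are named
`<control>@<plate>`; they must be dropped (`drop_plate_controls`) before
population analyses, or the replicated control masquerades as a clone.

## Group assignment

The six genetic groups of this species were delimited once, on the full
multi-substrate collection, by a prior clustering that is not re-derived
here. Instead each isolate is assigned to the group of its nearest
reference genotype — a supervised, fully reproducible stand-in flagged as
such in reports. The default distance is the shared-allele (Dice)
dissimilarity, 1 − 2|A∩B|/(|A|+|B|) per locus, averaged over mutually
non-missing loci; it is size-agnostic, which matches the observation that
groups separate on which alleles they carry rather than how many. A
Bruvo-style alternative (per-allele cost 1 − 2^(−Δ/step), minimum-cost
allele matching, unmatched alleles cost 1) is provided for users who want
stepwise-mutation awareness, but is not the default. Missing loci are
excluded pairwise, never imputed, for assignment; ties go to the first
group in panel order and the runner-up margin is reported as a confidence
proxy. Isolates with no comparable locus are labelled `unassigned`.

## Ordination and the 2N control

Missing cells are replaced only for ordination. The donor for a missing
(isolate, locus) cell is the nearest other isolate *with data at that
locus*; the donor's whole allele set is copied. Choosing the donor
per locus (rather than one global nearest neighbour regardless of its own
missingness) guarantees a complete table whenever any comparable donor
exists; ties break to the smallest strain id, which is unique, so the
seed argument never actually influences the result.

Complete tables are encoded as binary presence of each observed
(locus, allele) pair — one column per allele, so diploids and triploids
are handled uniformly. PCA is an SVD of the column-centred matrix; the
sign of each component is fixed by making its largest-magnitude loading
positive, so scores are reproducible snapshot-to-snapshot. The minimum
spanning tree is built by Kruskal's algorithm on Euclidean distances in
the first two component scores (configurable); equal-weight edges are
taken in lexicographic strain-id order, making the tree deterministic
even with duplicated coordinates (clones collapse to zero-weight edges).
Kruskal is implemented directly because the deterministic tie-break is
part of the contract; library MSTs serve as independent cross-checks in
the tests.

The 2N-constrained control deletes one allele, uniformly at random, from
every 3-allele cell, then repeats assignment/ordination. Each cell's draw
comes from its own RNG stream keyed by (seed, strain id, locus), so
edits elsewhere in a table never shift a given cell's outcome. High label
concordance between the full and constrained analyses indicates the
group structure rests on allele identity, not allele count.

## Diversity statistics

Per genetic group, on the genotype frequency spectrum: richness R,
Shannon H = −Σ pᵢ ln pᵢ (natural log), evenness H/ln R, inverse Simpson
D = 1/Σ pᵢ², equitability D/R. The natural-log Shannon and the inverse
form of Simpson are fixed by internal consistency: published evenness and
equitability columns reproduce exactly as H/ln R and D/R under these
conventions and under no others tried. Estimators are plug-in
(maximum-likelihood) with no bias correction, matching the printed
arithmetic. CIs are percentile bootstrap — isolates (not genotypes)
resampled with replacement within the group, 100 replicates, 2.5th/97.5th
percentiles — so an observed value may coincide with a CI bound. Groups
with a single isolate are reported NR (not relevant); evenness is
undefined at R = 1.

Note that richness counts *distinct genotype keys*, and a missing cell
makes a key unique; on data with ~6% missing cells richness therefore
overstates the number of distinct underlying genotypes.

## Clones, persistence, dispersal, time

A clone group is an equivalence class of isolates identical at all 12
loci, computed on the raw (non-imputed, normalized) table. The identity
rule is read strictly: an isolate with any missing locus cannot be proven
identical to another and is excluded from multi-member groups (counted in
a warning). This may under-group slightly relative to a tolerant rule,
but it cannot fabricate clones.

Persistence: for each (winery, clone) with ≥2 distinct vintages, the
sorted vintages and the interval max − min. Dispersal: great-circle
(haversine) distances on a sphere of radius 6371.0088 km (IUGG mean; no
ellipsoid) between all unordered member pairs of each clone with both
coordinates present — including same-sample pairs, which drag the
distribution toward zero by design. Distances fall in half-open classes
[0,1), [1,100), [100,750), [750,1000), [1000,∞) km; the first two classes
together are "local clone pairs". The class edges are declared
conventions, half-open on the right, so exactly 100 km falls in the
100–750 class.

Temporal dynamics use the vintage (year of wine production), not the
isolation year, because isolates are routinely cultured from bottles
decades later. Vintages fall into 20-year bins anchored so that 1981–2000
and 2001–2020 are bins. Per bin, group proportions get percentile-
bootstrap CIs from resampling isolates within the bin.

## Synthetic cohorts

The generator emits tables with the statistical structure the analysis
assumes, plus a per-isolate truth sidecar, and is the basis of the
end-to-end recovery suite. Defaults are fixed at the study conditions:

* five genetic groups with (isolates, genotypes) = (521, 58), (69, 50),
  (229, 88), (551, 118), (40, 26) — 1410 isolates, 340 genotypes — and
  ploidies (2, 2, 3, 3, 3);
* founders rejection-sampled on a 2 bp allele grid (100–320 bp) until all
  pairwise Dice distances ≥ 0.6; within-group genotypes derived by
  stepwise mutation (allele ± one repeat unit, per-allele rate 0.05 per
  derivation, collisions re-drawn) from a random existing genotype, so
  groups are tight relative to the founder separation;
* clonal expansion via deterministic Zipf(1.5) apportionment of each
  group's isolates over its genotypes (largest planted clone ≈ 10^2);
* 20 wineries at plausible wine-region coordinates (mostly Europe, plus
  USA/South Africa/Australia/Brazil so dispersal reaches the >1000 km
  class); each genotype has a home winery, and each isolate relocates to
  a random other winery with probability 0.03 (planted dispersal recorded
  in the truth); coordinates jitter by ±0.005°;
* vintages 1900–2020; triploid groups start at their planted onsets
  (1990, 1994, 1995), diploid groups reach back with a configured
  old-vintage share, so pre-1990 wines are diploid-only;
* 96-well plates (94 cohort wells + control), per-plate/per-locus offsets
  drawn from {−2, 0, +2} with probabilities (0.15, 0.7, 0.15), reference
  plate unshifted; the control replicate on each plate carries the
  offsets but is never punched missing;
* missing cells punched independently at rate 0.06 after truth is
  recorded.

What the generator does *not* emulate: genotyping error other than plate
shift (no allele dropout correlated with ploidy, no stutter/binning
error), linkage between loci, within-winery population turnover, uneven
sampling effort across regions and decades, or any selection dynamics.
Recovery tests passing on these cohorts therefore demonstrate that the
pipeline's bookkeeping and statistics are correct under the stated
generative assumptions — not that real cohorts are this easy; in real
data group boundaries are fuzzier and clone identity is upper-bounded by
marker resolution.

## Problem sizes and determinism

The test suite exercises cohorts between ~100 and 1410 isolates; the
recovery experiment in the acceptance script runs at the full default
scale (1410 isolates, 16 plates), which completes in seconds. All
stochastic steps (generator, bootstraps, 2N constraint, imputation ties)
are seed-pinned; a pipeline rerun with the same config reproduces
byte-identical outputs, which the suite checks via manifest checksums.

## Known limitations

* Nearest-reference assignment cannot discover new groups; peripheral
  isolates get a label regardless, with only the runner-up margin to
  flag poor resolution.
* The strict clone rule excludes ~half of isolates at 6% missingness
  (P(no missing locus) ≈ 0.94¹² ≈ 0.48), shrinking the pair set for
  dispersal statistics.
* Bootstrap CIs are percentile-based with 100 replicates; tail coverage
  is approximate at small group sizes.
* Coordinates are taken at face value; when only a region centroid is
  available the distances inherit its precision.
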