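# clonalscope

Population-genetic analysis of mixed-ploidy microsatellite genotypes, built
for clonal yeast collections such as the wine-spoilage yeast
*Brettanomyces bruxellensis*. Isolates are genotyped at 12 codominant
microsatellite loci, so each isolate carries a *set* of integer allele
sizes (bp) per locus; diploids show at most 2 distinct alleles per locus
and allotriploids up to 3. From such a table `clonalscope` infers putative
ploidy, assigns isolates to reference-anchored genetic groups, ordinates
the population (PCA + minimum spanning tree), detects clones, and
quantifies how long clones persist in wineries and how far they disperse.

## What it computes

* **Putative ploidy** — max distinct alleles at any locus (2 → possible
  diploid, 3 → possible triploid).
* **Genetic-group assignment** — nearest-reference classification under the
  shared-allele (Dice) distance, averaged over mutually non-missing loci:
  d(A,B) = 1 − 2|A∩B| / (|A|+|B|) per locus. A stepwise-mutation-aware
  (Bruvo-style) distance is available as an option.
* **Structure** — closest-neighbour imputation of missing cells (ordination
  only), binary allele-presence encoding, PCA, and a minimum spanning tree
  on the first two principal components. A 2N-constrained control (one
  allele deleted at random from every 3-allele cell) tests whether the
  clustering depends on allele quantity rather than identity.
* **Clonal diversity** per group — richness R, Shannon H = −Σ pᵢ ln pᵢ,
  evenness H/ln R, inverse Simpson D = 1/Σ pᵢ², equitability D/R, each with
  a 95% percentile-bootstrap CI (100 replicates, resampling isolates).
* **Clones in space and time** — clone groups (isolates identical at all 12
  loci), winery persistence intervals across vintages, great-circle
  distances between clone members binned into distance classes
  ([0,1), [1,100), [100,750), [750,1000), ≥1000 km; <100 km = "local clone
  pairs"), regional group distributions, and group proportions over
  20-year vintage bins with bootstrap CIs.
* **Synthetic cohorts** — a generator that emulates the study conditions
  (five genetic groups with realistic sizes and richness, clonal
  expansion, plate-size offsets, ~6% missing data, planted dispersal and
  diploid-only old vintages) with full ground truth, used by the recovery
  test-suite.

## Worked example

```python
import clonalscope as cs

cfg = cs.SimulationConfig()                       # study-scale synthetic cohort
table, truth = cs.simulate_population(cfg, seed=1)
ctrl = cfg.plate_control()
table = cs.drop_plate_controls(cs.normalize_plates(table, ctrl), ctrl)
cs.assign_groups(table, truth.founders)

rep = cs.diversity_report(table, n_boot=100, seed=1,
                          group_order=truth.founders.group_names())
print(rep[["group", "n_isolates", "richness", "shannon",
           "inverse_simpson"]].round(3).to_string(index=False))

groups = cs.find_clone_groups(table)
pairs = cs.clone_pair_distances(groups, table)
dist = cs.bin_distances([km for _, km in pairs])
print("clone groups:", len(groups), "largest:", groups[0].size)
print("local clone-pair fraction:", round(dist.local_fraction, 3))
```

prints

```
           group  n_isolates  richness  shannon  inverse_simpson
         Wine 2N         521       211    4.362           18.621
Wine/Kombucha 2N          69        58    3.936           39.347
    Wine/Beer 3N         229       154    4.665           46.367
     1st Wine 3N         551       279    4.816           32.670
     2nd Wine 3N          40        33    3.384           24.242
clone groups: 69 largest: 109
local clone-pair fraction: 0.909
```

Each row is one genetic group: `n_isolates` members, `richness` distinct
multilocus genotypes (missing cells make a genotype unmatchable, which
inflates richness relative to the planted genotype count), Shannon and
inverse-Simpson diversity of the genotype frequencies. The largest clone
group holds 109 isolates, and ~91% of within-clone pairs sit less than
100 km apart — the clonal, mostly-local dispersal regime the method is
designed to quantify.

The same analysis runs from the shell:

```bash
clonalscope simulate --scale 0.1 --seed 5 --out sim.csv --truth truth.csv
clonalscope load --in sim.csv --out clean.csv --normalize-control CTRL --ref-plate P01
clonalscope run --config analysis.json --out results/
```

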