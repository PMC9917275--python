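# wrenprey

Tools for linking insectivorous-bird nestling diet, habitat-resolved
arthropod availability, and nesting performance at the territory scale.

The package grew out of territory-scale food-limitation work on the Coastal
Cactus Wren (*Campylorhynchus brunneicapillus sandiegensis*), an at-risk
resident of southern-California coastal sage scrub, but every component is
parameterized and reusable: it is aimed at molecular ecologists and avian
conservation biologists who have (i) COI-metabarcoding diet data as an
OTU-by-sample read table plus reference-database match tables, (ii) field
samples of counted-and-measured arthropods from defined habitat elements
and strata, (iii) vegetation percent cover per territory, and (iv) nest
monitoring records, and who want a tested, reproducible chain from raw
tables to availability–performance correlations.

## What it computes

**Diet (`wrenprey.diet`).** OTUs are resolved through a similarity-threshold
cascade: best-match similarity *s* caps the assignable rank (species at
*s* ≥ 99.3, genus ≥ 94.9, family ≥ 91, order ≥ 85.9), equal-similarity
conflicts fall back to the lowest common ancestor, and regional-knowledge
overrides (e.g. Armadillidiidae → *Armadillidium vulgare*) apply last.
Diet composition per order is summarized as frequency of occurrence
FO = 100 · (samples containing the order) / (samples with arthropod DNA),
relative read abundance (mean per-sample read proportion), OTU counts and
minimum species richness. Orders found in more than one sample are
designated prey taxa.

**Biomass (`wrenprey.allometry`).** Each record of *n* arthropods of body
length *L* (mm) becomes mass *n·a·L^b* using order/suborder power-law
coefficients from an editable registry; cell biomass is averaged over
spatial blocks and totaled over time blocks, with unsampled element × block
units treated as missing, not zero.

**Community statistics (`wrenprey.community`).** Habitat-element × territory
marginal means of log(biomass + 1) (the balanced-design cell-mean estimator,
with an optional mixed-model refit); Bray–Curtis dissimilarity
BC(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ); one-way PERMANOVA with Anderson's
pseudo-F and a seeded permutation null; column-centered PCA of relative
prey-order biomass with a deterministic sign convention.

**Territory upscaling (`wrenprey.scaling`).** Availability(order, territory,
stratum) = Σ_elements (cover%/100) · mean biomass · A, with A = πr² the
standard territory area (31,416 m² for the 100 m nest buffer). Hymenoptera
(≈95% invasive Argentine ant in this system) is carried as an independent
axis, never inside the prey total.

**Performance links (`wrenprey.performance`).** Across-territory summaries
of nesting outcomes (mean ± SE; clutch size as per-territory eggs/attempts),
Pearson/linear links of first egg date to availability metrics, Poisson
log-link GLMs for fledgling counts, and diet-rank vs availability-rank
discordance reports.

**Synthetic studies (`wrenprey.synthetic`).** A seeded generator reproduces
the whole study design (3 sites / 8 territories / 2 blocks / 9 habitat
elements / 2 strata / 5 time blocks) with negative-binomial counts, a
dominant invasive ant, lognormal body lengths, Dirichlet cover, and nesting
outcomes causally tied to a configurable Lepidoptera-availability effect —
with the latent truth recorded, so every downstream estimator can be scored.

## Worked example

```python
from wrenprey import (generate_study, nominal_config, load_packaged_nesting,
                      summarize_nesting, relate)
import pandas as pd

summary = summarize_nesting(load_packaged_nesting())
for metric, (mean, se) in summary.metrics.items():
    print(f"{metric}: {mean:.1f} ({se:.2f})")

bundle = generate_study(nominal_config(seed=1))
lep = pd.Series(bundle.truth["lepidoptera_relative_availability"], name="lep")
avail = lep.rename_axis("territory").reset_index().assign(stratum="all")
r = relate(avail, bundle.nesting_table, "lep", "first_egg_julian")
print(f"slope={r.slope:.1f}, R2={r.r_squared:.2f}, p={r.p_value:.3f}")
```

prints

```
first_egg_julian: 99.5 (8.91)
nest_attempts: 1.9 (0.35)
total_eggs: 6.4 (1.39)
fledglings: 2.8 (0.92)
clutch_size: 3.3 (0.25)
slope=-29259.9, R2=0.88, p=0.001
```

The first block is the packaged eight-territory 2012 nesting season — on
average 1.9 nesting attempts, clutches of 3.3 eggs, 6.4 eggs and 2.8
fledglings per pair. The second block fits first egg date against each
territory's latent Lepidoptera relative availability in a synthetic study
generated with a known negative effect (more caterpillars → earlier
laying): the fitted slope recovers the generating sign with R² = 0.88.

The `examples/` directory holds one short script per capability
(simulation, diet profiling, biomass and availability, composition tests,
performance links); each prints its results with a line on what they mean.
A thin CLI mirrors the pipeline stages:

```bash
wrenprey simulate --seed 1 --out bundle/
wrenprey validate bundle/
wrenprey run-all bundle/ --seed 1 --out run/
```

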