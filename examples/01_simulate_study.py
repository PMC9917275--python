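"""Generate a synthetic territory-scale food-limitation study.

Builds the nominal design — 3 sites, 8 territories, 2 spatial blocks, 9
habitat elements sampled in canopy and ground strata over 5 time blocks —
and writes the four data streams (diet OTU/match tables, arthropod records,
vegetation cover, nesting outcomes) plus the latent truth record.
"""

from wrenprey import generate_study, nominal_config
from wrenprey.io import write_bundle

cfg = nominal_config(seed=1)
bundle = generate_study(cfg)
paths = write_bundle(bundle, "scratch/example_bundle")

print(f"territories: {cfg.n_territories} across {cfg.n_sites} sites")
print(f"arthropod records: {len(bundle.arthropod_table)}")
print(f"diet samples: {len(bundle.otu_table)} ({int((bundle.otu_table.sum(axis=1) > 0).sum())} with arthropod reads)")
print(f"OTUs: {bundle.otu_table.shape[1]}")
print("first egg dates:", bundle.nesting_table["first_egg_julian"].tolist())
# The truth record holds each territory's latent Lepidoptera relative
# availability and the generating date slope, so estimators can be scored.
print("true date slope per SD of Lepidoptera availability:",
      bundle.truth["date_slope_per_sd"])
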