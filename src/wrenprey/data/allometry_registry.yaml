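# Default length->biomass power-law registry: mass_mg = a * (length_mm ** b).
# These are editable literature-style defaults at the order / suborder level,
# shipped so the pipeline runs out of the box. They are NOT authoritative:
# substitute coefficients from your own allometry source for real analyses.
Araneae: {a: 0.050, b: 2.74}
Blattodea: {a: 0.032, b: 2.50}
Coleoptera: {a: 0.040, b: 2.64}
Dermaptera: {a: 0.025, b: 2.60}
Diptera: {a: 0.025, b: 2.27}
Hemiptera: {a: 0.016, b: 2.60}
Heteroptera: {a: 0.008, b: 2.90}
Auchenorrhyncha: {a: 0.011, b: 2.70}
Sternorrhyncha: {a: 0.021, b: 2.30}
Hymenoptera: {a: 0.025, b: 2.62}
Isopoda: {a: 0.050, b: 2.60}
Lepidoptera: {a: 0.003, b: 2.90}
Mantodea: {a: 0.020, b: 2.60}
Neuroptera: {a: 0.019, b: 2.45}
Orthoptera: {a: 0.030, b: 2.55}
Psocoptera: {a: 0.007, b: 2.60}
Thysanoptera: {a: 0.005, b: 2.30}
Zygentoma: {a: 0.020, b: 2.50}
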