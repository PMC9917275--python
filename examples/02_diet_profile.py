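"""Taxonomy assignment and diet profiling from OTU match tables.

Resolves each OTU through the similarity-threshold cascade (species >= 99.3%,
genus >= 94.9%, family >= 91%, order >= 85.9%, equal-similarity conflicts to
the lowest common ancestor), then summarizes diet composition as frequency
of occurrence among samples with arthropod DNA.
"""

from wrenprey import assign_taxonomy, designate_prey, diet_profile, generate_study, nominal_config
from wrenprey.io import match_table_to_otu_matches

bundle = generate_study(nominal_config(seed=1))
matches = match_table_to_otu_matches(bundle.match_table)
assignments = [assign_taxonomy(m) for m in matches]

by_rank = {}
for a in assignments:
    by_rank[a.resolved_rank] = by_rank.get(a.resolved_rank, 0) + 1
print("resolution mix:", dict(sorted(by_rank.items())))

profile = diet_profile(assignments, bundle.otu_table)
print(f"\nsamples with arthropod DNA: {profile.n_samples_positive}")
print(profile.per_order.to_string(index=False))

prey, excluded = designate_prey(profile)
# Orders detected in a single sample are not treated as prey taxa.
print("\nprey orders:", sorted(prey))
print("excluded:", excluded)
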