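"""Simulate a small BXD-like recombinant inbred panel.

Builds two founders, breeds three epochs of strains with different
inbreeding depths, and prints how mutations accumulate with generation
count — the panel-level signal the discovery pipeline relies on.
"""

from strmutator import (
    BreedingPlan,
    MutationModelParams,
    generate_founders,
    render_panel,
    simulate_panel,
)

panel, marker_map = generate_founders(
    n_chromosomes=2, n_markers_per_chrom=100, n_strs_per_chrom=400, seed=1
)
model = MutationModelParams(
    expansion_prob_B=0.6,
    expansion_prob_D=0.4,
    mutator_locus=marker_map.df["marker"].iloc[50],
)
plan = BreedingPlan(
    [("epoch1", 10, 25), ("epoch2", 10, 50), ("epoch3", 10, 100)], seed=2
)
genomes, metadata = simulate_panel(panel, marker_map, plan, model)
tables, truth = render_panel(genomes, panel, marker_map, metadata, seed=3)

print(f"{len(genomes)} strains, {marker_map.n_markers} markers, "
      f"{len(panel.str_reference)} STR loci")
per_epoch = truth.merge(metadata, on="strain_id").groupby("epoch").size() / 10
print("\nmean fixed mutations per strain by epoch:")
print(per_epoch.to_string())
print("\nDeeper epochs carry more homozygous new mutations: mutation count "
      "grows with generations of inbreeding, so generation count is used "
      "as a covariate downstream.")
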