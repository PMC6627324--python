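"""Editing frequencies and group statistics on a synthetic editome.

Simulates two groups of species whose C-to-U editing levels differ
3.5-fold (the kind of contrast seen between bryophyte lineages), predicts
the editome of every species against the shared reference, and summarizes
per-gene editing frequencies: Kruskal-Wallis per gene, Dunn/BH post-hoc,
and the overall group scale factor.
"""

from editome import (
    GroupSpec,
    SimulationConfig,
    build_frequency_table,
    compare_groups_per_gene,
    group_scale_factor,
    predict_editome,
    simulate_dataset,
)

config = SimulationConfig(
    n_genes=10,
    gene_length_range=(100, 300),
    groups={"rich": GroupSpec(6, 2.8, 0.03), "poor": GroupSpec(6, 0.8, 0.07)},
    gene_rate_sigma=0.5,  # some genes consistently editing-rich, some poor
    seed=11,
)
truth = simulate_dataset(config)
profile = predict_editome(truth.species.values(), truth.reference)

lengths = {
    (sid, g): truth.species[sid][g].length
    for sid in truth.species
    for g in truth.species[sid].records
}
table = build_frequency_table(profile, lengths, "C2U", truth.groups)

factor = group_scale_factor(table, "rich", "poor")
print(f"configured editing-level contrast : {2.8 / 0.8:.2f}x")
print(f"estimated  group scale factor     : {factor:.2f}x")
print()
print("gene   H      p       mean(rich)%  mean(poor)%")
for comp in compare_groups_per_gene(table):
    print(
        f"{comp.gene:<6} {comp.h:5.2f}  {comp.p:7.4f} "
        f"{comp.group_means['rich']:10.2f} {comp.group_means['poor']:12.2f}"
    )
# Genes with small p differ significantly between groups; the scale factor
# recovers the configured 3.5x overall contrast from the predictions alone.
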