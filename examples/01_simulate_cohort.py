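"""Simulate a synthetic breast-cancer cohort with planted regulators.

Builds a small two-subtype cohort (luminal A and basal-like) in which
each subtype is driven by planted regulator TFs with coexpressed target
modules, then prints what was planted.  Every other example starts from
a cohort like this one.
"""

from subreg import PlantedModel, generate_annotation, generate_expression_compendium

model = PlantedModel.random(
    n_genes=2000,
    n_tfs=200,
    n_regulators_per_subtype=5,
    n_targets_per_regulator=40,
    seed=1,
)
annotation = generate_annotation(model)
datasets = generate_expression_compendium(model, n_datasets=5, samples_per_dataset=30)

print(f"genome: {model.n_genes} genes on {annotation['chrom'].nunique()} chromosomes, "
      f"{model.n_tfs} flagged as TFs")
for subtype in model.subtypes:
    regs = model.regulators_per_subtype[subtype]
    n_targets = len(model.module_genes(subtype))
    print(f"{subtype}: regulators {regs} driving {n_targets} module genes")
expr, labels = datasets[0]
print(f"dataset 0: {expr.shape[0]} genes x {expr.shape[1]} samples "
      f"({dict(labels.value_counts())})")
# The module genes are coexpressed through a shared latent factor and
# shifted upward by one log-unit in their own subtype's samples.
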