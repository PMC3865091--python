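"""Generate a synthetic paired miRNA/protein study with planted structure.

The design mimics a three-group chronic-ethanol drinking study (7 naive,
7 Air-2BC, 7 CIE-2BC mice). miRNA features come as replicate array spots on
the intensity scale; proteins as log-abundance gel spots. Two miRNA modules
repress two protein modules, so the omics are anti-correlated by design.
"""

from comodnet import (
    default_mirna_modules,
    default_protein_modules,
    default_repression_map,
    generate_design,
    simulate_annotation_tables,
    simulate_paired_omics,
)

design = generate_design(n_per_group=7, seed=42)
print(design.table.groupby("group")[["eoc", "drinking"]].mean().round(2))
# eoc is the ordinal escalation-of-consumption code (0/1/2); drinking is the
# simulated g/kg intake, zero for naive mice and rising with dependence.

mirna_mods = default_mirna_modules()     # 8 modules x 25 features
protein_mods = default_protein_modules()  # 6 modules x 20 features
repression = default_repression_map()     # 2 planted miRNA->protein links

mirna, protein = simulate_paired_omics(
    design, mirna_mods, protein_mods, repression, seed=42,
    n_mirna_features=500, n_protein_features=250,
)
print(f"miRNA spots:   {mirna.values.shape} ({mirna.scale} scale, 4 replicates/feature)")
print(f"protein spots: {protein.values.shape} ({protein.scale} scale)")

targets, ppi = simulate_annotation_tables(
    repression, mirna_mods, protein_mods, n_decoy_targets=50, ppi_density=0.01, seed=43
)
print(f"target predictions: {len(targets)} rows ({targets['is_planted'].sum()} planted)")
print(f"PPI edges: {len(ppi)} ({ppi['is_planted'].sum()} within planted modules)")
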