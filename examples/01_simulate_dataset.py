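"""Generate a synthetic 2-genotype x 2-stage count dataset with planted truth.

Builds a small study (WT vs dKO, ESC vs RA-differentiated, 3 replicates per
cell), prints the design and the planted class composition, and shows the
ground-truth ledger that downstream recovery scoring uses.
"""

from mirtraj import SimulationConfig, simulate_dataset

config = SimulationConfig(n_genes=1000, n_mirnas=80, n_regulator_mirnas=8,
                          targets_per_mirna=10, seed=7)
dataset = simulate_dataset(config)

print("design (first rows):")
print(dataset.design.head(6).to_string(index=False))
print(f"\nmRNA counts: {dataset.mrna_counts.shape[0]} genes x "
      f"{dataset.mrna_counts.shape[1]} samples; "
      f"miRNA counts: {dataset.mirna_counts.shape[0]} x "
      f"{dataset.mirna_counts.shape[1]}")

print("\nplanted gene classes (true_class counts):")
print(dataset.truth.gene_truth["true_class"].value_counts().to_string())
print(f"\nplanted regulator miRNAs: {len(dataset.truth.regulator_ids)}")
print(f"target-map edges: {len(dataset.target_map)} "
      f"({int(dataset.truth.edges['functional'].sum())} functional, "
      f"{int((~dataset.truth.edges['functional']).sum())} decoys)")
# Functional edges couple a target's expected count to its regulator's
# standardized latent abundance, planting negative miRNA-target correlations;
# decoy edges point at genes with no planted effects.
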