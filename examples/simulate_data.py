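"""Generate the two kinds of planted-truth synthetic expression data.

Builds a 5 disease + 8 control design at a reduced gene count, once with
planted independent expression modes (the ICA track's ground truth) and
once with planted nonnegative metagene modules (the NMF track's ground
truth), and prints what was planted where.
"""

from genefactor import default_labels, simulate_ica_dataset, simulate_nmf_dataset

labels = default_labels()  # 5 "AD" + 8 "control" samples
print(f"groups: {labels.groups}, samples: {len(labels.sample_ids)}")

ica_data, ica_truth = simulate_ica_dataset(
    n_genes=1000, labels=labels, n_modes=4, frac_significant=0.02,
    signal_z=4.0, noise_sd=0.5, seed=1,
)
print(f"\nICA-style matrix: {ica_data.values.shape} (genes x samples)")
print(f"planted modes: {ica_truth.mode_matrix.shape[0]}, "
      f"phenotype-discriminating mode index: {ica_truth.phenotype_mode_index}")
for i, sig in enumerate(ica_truth.significant_gene_sets):
    ups = sum(1 for d in sig.values() if d == "up")
    print(f"  mode {i}: {len(sig)} significant genes "
          f"({ups} up, {len(sig) - ups} down)")

nmf_data, nmf_truth = simulate_nmf_dataset(
    n_genes=1000, labels=labels, k=2, module_size=50, noise_sd=0.5, seed=1,
)
print(f"\nNMF-style matrix: {nmf_data.values.shape}, "
      f"min value {nmf_data.values.min():.3f} (nonnegative by construction)")
for j, module in enumerate(nmf_truth.metagene_modules):
    print(f"  metagene {j}: module of {len(module)} genes")

# The mixing column of the phenotype mode separates the groups by sign:
col = ica_truth.mixing_matrix[:, ica_truth.phenotype_mode_index]
print(f"\nphenotype mixing column: {col.round(1)}")
print("(+1 for every disease sample, -1 for every control sample — this is "
      "the signal the component scorer must find after decomposition)")
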