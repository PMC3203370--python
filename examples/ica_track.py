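"""The ICA track: consensus FastICA, component scoring, gene selection.

Simulates a dataset with four planted independent expression modes (one
phenotype-linked), decomposes it with multi-restart FastICA, ranks the
mixing-matrix columns by how well they separate disease from control, and
extracts the significant genes of the winning component at |z| >= 2.5.
"""

import warnings

from genefactor import (
    RunConfig,
    default_labels,
    fastica_consensus,
    score_components,
    select_discriminating_components,
    select_genes_ica,
    simulate_ica_dataset,
    standardize_samples,
)

warnings.simplefilter("ignore")  # non-converged noise dimensions are expected

labels = default_labels()
matrix, truth = simulate_ica_dataset(
    n_genes=2000, labels=labels, n_modes=4, signal_z=4.0, noise_sd=0.5, seed=2,
)

config = RunConfig(seed=2, ica_n_restarts=25)
result = fastica_consensus(standardize_samples(matrix), config)
print(f"mixing matrix A: {result.mixing.shape}, "
      f"expression modes S: {result.sources.shape}")
print(f"restarts pooled: {result.restart_count}, "
      f"component stability range: "
      f"[{result.stability.min():.3f}, {result.stability.max():.3f}]")

scores = score_components(result.mixing, labels, matrix.sample_ids)
chosen = select_discriminating_components(scores)
top = next(s for s in scores if s.rank == 1)
print(f"\ntop-ranked component: {top.component} "
      f"(|t| = {abs(top.t_statistic):.2f}, "
      f"sign separation = {top.sign_separation:.2f})")
print(f"auto-selected discriminating components: {chosen}")

table = select_genes_ica(result, chosen, config.loading_threshold, labels)
ups = (table.direction == "up").sum()
print(f"\nsignificant genes at |z| >= {config.loading_threshold}: "
      f"{len(table)} ({ups} up-regulated in {labels.groups[0]}, "
      f"{len(table) - ups} down)")

planted = truth.significant_ids(truth.phenotype_mode_index)
hits = len(set(table.gene_id) & planted)
print(f"planted significant genes recovered: {hits}/{len(planted)}")
print("(up/down means higher/lower in the disease group after the mode is "
      "oriented by its mixing weights — ICA's sign ambiguity is resolved)")
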