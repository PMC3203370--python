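# genefactor

Two-track matrix factorization for identifying phenotype-associated genes in
bulk expression data. Given a genes × samples expression matrix and a
two-group phenotype annotation (e.g. disease vs. control), `genefactor`
decomposes the data with two complementary unsupervised models, ranks the
latent components by how well they discriminate the groups, extracts
significant genes by a standardized-loading threshold, and integrates the two
gene lists into one candidate set. It targets small two-condition microarray
or RNA designs — the motivating case is a hippocampal study with 5 severe
disease and 8 control samples over 6398 genes — and ships a planted-truth
simulator so every stage has a recovery test.

## The two models

**Track 1 — consensus FastICA.** The transposed matrix is modeled as a linear
mixture of statistically independent *expression modes*:

    Xᵀ = A S

where `Xᵀ` is samples × genes, the rows of `S` are independent expression
modes (one loading per gene), and the mixing matrix `A` (m × m) holds the
weight of each mode in each sample profile. Estimation is the fixed-point
FastICA scheme with the `tanh(a₁u)` contrast and symmetric decorrelation,
after per-sample standardization and whitening. Because FastICA depends on
its random start, many restarts are pooled: components are matched across
runs by absolute correlation and scored for stability (mean |r| to matched
partners), and the most stable run is returned. A column of `A` whose entries
differ in sign and magnitude between the two phenotype groups marks a
discriminating mode; this is scored with a Welch t statistic plus a
sign-separation fraction. Genes with |z| ≥ 2.5 on a discriminating mode
(loadings standardized across genes) are called significant, with the sign
giving up/down regulation once the mode is oriented toward the disease group.

**Track 2 — non-smooth NMF (nsNMF).** The nonnegative matrix is factored as

    V ≈ W S_θ H,    S_θ = (1 − θ) I + (θ/k) 11ᵀ

with metagenes `W` (genes × k), encodings `H` (k × samples), and the
smoothing matrix `S_θ` interposed so that multiplicative KL-divergence
updates push sparseness onto both factors (θ = 0 recovers classical NMF;
θ → 1 smooths maximally). The best of many random restarts (lowest final
generalized Kullback–Leibler divergence) is kept. Samples are classified by
their most highly expressed metagene; genes with standardized loading
z ≥ 2.5 on a metagene are called significant, with direction read from the
raw group means. Sorting genes by a metagene and samples by its encoding
vector biclusters the matrix, collecting each co-regulated module at one
extreme.

Finally the two gene lists are intersected and unioned, with per-gene
provenance and up/down conflicts flagged — the two models make different
assumptions (independence vs. nonnegative sparseness), so their modest
overlap is itself informative and the union is the integrated candidate set.

## Worked example

```bash
python examples/ica_track.py
```

```
mixing matrix A: (13, 13), expression modes S: (13, 2000)
restarts pooled: 25, component stability range: [0.939, 0.998]

top-ranked component: 3 (|t| = 10.16, sign separation = 1.00)
auto-selected discriminating components: [3]

significant genes at |z| >= 2.5: 46 (22 up-regulated in AD, 24 down)
planted significant genes recovered: 40/40
```

The simulator planted four independent modes in a 2000-gene, 5 + 8-sample
matrix; one mode's mixing weights have opposite signs in the two groups. The
consensus decomposition recovers all modes, the scorer ranks the planted
phenotype mode first (its mixing column separates the groups perfectly, sign
separation 1.00), and thresholding that mode's standardized loadings at 2.5
recovers all 40 planted significant genes among 46 calls. The other examples
(`simulate_data.py`, `nsnmf_track.py`, `full_pipeline.py`) walk the NMF
track and the end-to-end pipeline the same way.

The `genefactor` CLI exposes each stage (`simulate`, `preprocess`, `ica`,
`nsnmf`, `select`, `integrate`) and a `run-all` orchestrator driven by a
YAML config; `run-all` writes every intermediate table plus a manifest with
per-file checksums, and a rerun with the same config reproduces every output
bitwise.

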