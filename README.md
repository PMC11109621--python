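# scmFormer

A multi-task, masked-attention transformer for paired single-cell
multimodal data (RNA + protein, RNA + chromatin, triple-omics).  It
learns per-modality latent representations that are aligned across
modalities (integration) and can predict an unmeasured modality from a
measured one (generation), together with the standard evaluation
metrics (FOSCTTM, kNN label transfer, per-feature correlations) and a
seeded synthetic paired-data generator so the whole system is testable
at desk scale.

## Method overview

Each cell's preprocessed expression vector is partitioned into
sub-vectors of length `s` that act as attention tokens, with learned
positional and modality embeddings added.  The decoder uses
**scm-attention**: ReLU-activated Q/K/V projections, scaled dot-product
scores, a causal mask hiding future sub-vectors, and ReLU in place of
softmax.  Pre-norm residual blocks (multi-head attention + two-layer
feed-forward) are followed by average pooling per modality and affine
reconstruction heads.  Training minimizes

```
loss = lambda * sum_m MSE(reconstruction_m, input_m) + MSE(latent_m1, latent_m2)
```

for integration (pairwise mean for three modalities), and plain
reconstruction MSE against the measured target for generation.

The model is implemented on NumPy with a small built-in reverse-mode
autodiff engine (`scmformer._tensor`) and Adam — no GPU or deep-learning
framework required.

## CLI

```bash
# write a synthetic paired dataset (MTX + CSV + labels)
scmformer simulate --preset small --seed 0 --out sim/

# paired integration: latents, loss trace, model, metrics report
scmformer integrate --rna sim/rna.csv --protein sim/protein.csv \
    --labels sim/labels.csv --epochs 20 --seed 0 --out run/

# cross-modality generation (RNA -> protein)
scmformer generate --train-rna sim/rna.csv --train-protein sim/protein.csv \
    --query-rna sim/rna.csv --out gen/

# metrics between two latent CSVs
scmformer evaluate --latents-a run/latent_rna.csv \
    --latents-b run/latent_protein.csv --labels sim/labels.csv \
    --out report.json
```

Inputs may be dense CSV, a 10x-style MTX directory
(`matrix.mtx` + `barcodes.tsv` + `features.tsv`), or H5AD.  Every run
writes a `manifest.json` with the effective configuration, seed and
SHA-256 hashes of all inputs.

## Package layout

- `scmformer.data_model` — matrix containers, MTX/CSV/H5AD readers, pairing, model (de)serialization
- `scmformer.preprocess` — library-size + log normalization, CLR for protein, TF-IDF for ATAC, HVG selection, PCA dimension alignment
- `scmformer.embedding` — sub-vector patching and positional/modality coding
- `scmformer.scm_model` — scm-attention, decoder layers, pooling, reconstruction heads
- `scmformer.training` — losses, Adam, integration/generation training loops
- `scmformer.metrics` — FOSCTTM, kNN transfer, accuracy/macro-F1, correlation metrics
- `scmformer.synthetic_data` — seeded paired-data simulator
- `scmformer.cli` — `scmformer` command group
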