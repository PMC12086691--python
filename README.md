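# spotfactor

Joint non-negative matrix factorization of spatial transcriptomics data and
paired histology image features.

Given a non-negative spot×gene expression matrix `Y_rna` and a non-negative
spot×feature image matrix `Y_img` over the same spots, `spotfactor` solves

```
min_{W, H_rna, H_img >= 0}
    alpha * ||Y_rna - W @ H_rna||_F^2  +  (2 - alpha) * ||Y_img - W @ H_img||_F^2
```

by accelerated hierarchical alternating least squares (A-HALS), yielding a
shared spot×factor matrix `W` and two modality-specific loading matrices.
The modality weight `alpha` (default 1.0, range [0, 2]) trades the two blocks
off against each other; `alpha = 2` is an expression-only fit and `alpha = 0`
an image-only fit. By default each block is divided by its own Frobenius norm
before fitting so that `alpha = 1` genuinely weights the modalities equally.

Included machinery:

- **Initialization** — seeded half-normal random draws, or deterministic
  plain NNDSVD on the weighted concatenated matrix.
- **Rank selection** — 4-block bi-cross-validation on the expression matrix:
  the held-out corner block is predicted from the complementary blocks via
  pseudo-inverses of the factorization of the opposite corner.
- **Image features** — multiscale square patches centred at spot locations,
  summarized as per-channel pixel-intensity histograms (counts in equal-width
  bins); user-supplied non-negative spot-wise features are also accepted.
- **Post-processing** — k-means or Leiden graph clustering of the factors,
  ARI/AMI/Fowlkes–Mallows agreement with annotations, contingency tables,
  top-gene ranking per factor, factor–gene Pearson correlation, and
  expression-matched gene-set scoring.
- **Synthetic data** — a generator of paired expression/image bundles with
  planted shared factors, region-painted RGB images, and on-disk bundles in
  the standard Matrix Market + positions + scale-factor dialects.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the slower end-to-end property checks
(solver monotonicity, oracle equivalence against multiplicative-update NMF,
BCV rank recovery, planted-factor recovery, histogram conservation).

## Command line

All randomness flows from explicit `--seed` flags; every command writes a
`run_metadata.json` capturing its parameters.

```sh
# synthetic bundle: counts (Matrix Market), positions, scalefactors, image
spotfactor simulate --out bundle/ --m 400 --n 500 --f 30 --k 4 --seed 1

# histogram features from the H&E image at the spot locations
spotfactor features --image bundle/image.png \
    --positions bundle/spatial/tissue_positions.csv \
    --scalefactors bundle/spatial/scalefactors_json.json \
    --out features.csv

# rank selection by bi-cross-validation
spotfactor select-k --matrix bundle/ --k-min 2 --k-max 10 --out bcv/

# joint fit (alpha in [0, 2]; 2.0 = expression only)
spotfactor fit --matrix bundle/ --features features.csv \
    --k 4 --alpha 1.0 --seed 1 --out model/

# clustering, evaluation against annotations, factor-gene correlation
spotfactor cluster --model model/ --method kmeans --n-clusters 4 --out labels.csv
spotfactor evaluate --labels labels.csv --annotations bundle/annotations.csv --out eval/
spotfactor evaluate --matrix bundle/ --features features.csv \
    --annotations bundle/annotations.csv --alphas 0.5,1.0,1.5,2.0 --k 4 --out sweep/
spotfactor correlate --model model/ --matrix bundle/ --gene gene_0001 --out corr.csv
```

The expression reader accepts a bundle directory (`matrix.mtx[.gz]` +
barcodes/features lists, either on-disk orientation, auto-detected) or a
dense delimited table; position tables may be the header or headerless
six-column dialect.

## Python API sketch

```python
from spotfactor import FitConfig, jnmf_fit, simulate_joint_data, select_rank

expr, feats, truth = simulate_joint_data(m=200, n=300, f=30, k=5, seed=0)
k = select_rank(expr.values, range(2, 10), folds=5, seed=0).k_selected
model = jnmf_fit(expr, feats, FitConfig(alpha=1.0, k=k, seed=0))
model.W          # spots x k, unit-norm columns
model.H_rna      # k x genes
model.H_img      # k x image features
```
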