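# phenocell

Identify the cells behind a sample-level phenotype. `phenocell`
integrates a single-cell RNA-seq expression matrix (which has cells but
usually no clinical outcomes) with a bulk expression cohort (which has
outcomes but no cellular resolution) and selects the subpopulation of
cells whose expression pattern tracks the phenotype — a diagnosis or
treatment-response label, or survival times. It is aimed at
computational biologists asking questions like *which tumor cells drive
the malignant phenotype?* or *which T-cell states predict immunotherapy
response?*

## Method

1. **Preprocess.** Bulk counts are duplicate-averaged and
   log2(x+1)-transformed. Single-cell counts are filtered (genes
   expressed in too few cells are dropped), library-size normalized to
   ln(1 + 10⁴·c/T), and embedded by PCA of the scaled highly variable
   genes.
2. **Group cells.** A shared-nearest-neighbor graph (Jaccard weights
   over k = 20 neighborhoods in the first 10 PCs) is partitioned by the
   Leiden algorithm, maximizing the resolution-scaled modularity

   Q = (1/2m) Σᵢⱼ (Aᵢⱼ − γ·kᵢkⱼ/2m) δ(cᵢ, cⱼ),   γ = 0.6 by default.

   The s communities become the cell groups, sizes p₁…pₛ.
3. **Integrate.** Every bulk sample i is correlated (Pearson, over the
   genes shared by both matrices) with every cell j, giving the n × N
   design matrix X whose rows xᵢ split into group blocks xᵢ⁽ˡ⁾.
4. **Select cells.** A sparse group lasso is fit over the cells:

   min_β (1/n)·l(β) + λ[(1−α)·Σₗ √pₗ·‖β⁽ˡ⁾‖₂ + α·‖β‖₁],

   where l is the logistic negative log-likelihood (binary phenotype)
   or the Breslow negative log partial likelihood (survival). The group
   penalty selects whole cell communities; the ℓ1 term keeps sparsity
   inside them. (α, λ) are chosen by 5-fold cross-validation over an α
   grid and a 20-point λ path per α.
5. **Classify.** Cells with positive fitted coefficients are associated
   with the higher-encoded phenotype (case / worse survival), negative
   coefficients with the lower-encoded one, zeros are background.

The solver, its λ-path construction, KKT diagnostics and the
cross-validation loop are implemented in this package (numba-compiled
blockwise proximal descent); Leiden optimization is delegated to
`leidenalg`.

## Worked example

Generate a synthetic cohort with a planted phenotype-associated cell
group, then run the full pipeline:

```bash
phenocell simulate --n-genes 500 --n-cells 500 --n-samples 60 \
    --n-groups 5 --effect 3 --seed 11 --outdir data
phenocell run --sc data/sc_counts.tsv --bulk data/bulk_counts.tsv \
    --phenotype data/phenotype.tsv --mode binary \
    --min-cells 10 --seed 11 --outdir out
```

which prints

```
Leiden: 5 groups, Q=0.8799
alpha*=0.4 lambda*=0.006943: 100 positive, 87 negative, 313 background cells
```

The Leiden step recovered the five simulated cell groups (modularity
0.88); cross-validation picked α\* = 0.4, λ\* ≈ 0.0069; the fit labels
100 cells positive — here exactly the 100 cells of the planted group
(`truth.json` records the ground truth) — and 87 cells of other groups
negative, i.e. relatively depleted in case samples. `out/cells.tsv`
lists each cell's group, coefficient and label:

```
cell_id     group_id  coefficient   label
cell_00000  1         0.5569061969  positive
cell_00001  1         1.235895054   positive
...
```

`out/run_summary.json` captures (α\*, λ\*), the group sizes, modularity
and the seed, so a rerun with the same inputs reproduces the output
byte-for-byte.

The same workflow runs on real data: `--sc` accepts a MatrixMarket
`.mtx` with `genes.tsv`/`barcodes.tsv` sidecars or a dense TSV/CSV
(genes × cells), `--bulk` a genes × samples table, `--phenotype` a
sample table with a binary label or time/status columns. Library use
mirrors the CLI (`phenocell.run_pipeline`, or the sklearn-style
estimators `SparseGroupLassoCV`, `SparseGroupLassoClassifier`,
`SparseGroupLassoCox`, `SNNLeiden` for the individual stages).

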