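# phenogate

Signature-driven cell-type annotation for single-cell-resolved spatial
omics (multiplexed antibody imaging such as CODEX/PhenoCycler, and
probe-based spatial transcriptomics such as Xenium or MERFISH).

Clustering-then-annotating workflows struggle on these data: segmentation
noise and boundary bleed-through blur marker profiles, and unsupervised
clusters rarely align with the cell types a panel was designed to capture.
`phenogate` instead scores every cell directly against expert marker
signatures and learns, per cell type, a data-driven positivity threshold —
no reference dataset and no manual gating required.

## Method

Given a normalized cell-by-feature matrix `A` (n cells × m markers) and a
signature matrix `S` (m markers × t cell types, weights `w ∈ (0, 1]`):

1. **Cell Type Relevance (CTR) scores** — `Γ = A · S`; cell *i*'s score for
   type *j* is the weighted sum of its signature-marker values.
2. **Micro-clustering** — a shared-nearest-neighbor graph on the top
   principal components of `A` is partitioned by Louvain community
   detection, with the resolution searched so the mean cluster size lands
   between 0.1% and 0.5% of cells. Each micro-cluster is small enough to be
   nearly homogeneous.
3. **Segmented regression** — for each type, the micro-cluster median CTRs
   `z` are regressed on their ranks `r` with a continuous piecewise-linear
   model `z = α₀ + β₀r + Σᵢ βᵢ(r − φᵢ)₊`, allowing g = 1–3 breakpoints;
   the minimum-AIC model wins. Clusters ranked at or below the lowest
   breakpoint form the low-relevance group, those at or above the highest
   breakpoint the high-relevance group.
4. **Optimal threshold** — `θ = argmin |{i ∈ C_L : τᵢ > θ}| +
   |{i ∈ C_H : τᵢ < θ}|`, the misclassification-minimizing split between
   the two groups' member cells, found by exact grid search.
5. **Categorization and deconvolution** — cells strictly above exactly one
   `θ` are *clean*; above several, *mixed*; above none, *unknown*. Each
   mixed cell takes the modal label of its k = 10 nearest clean anchors,
   measured only in its candidate types' signature markers.

The package also ships the proportion-weighted benchmark metrics
(weighted recall/precision/F1, pooled accuracy), marker-enrichment
statistics (log₂ fold change + one-sided Wilcoxon, BH-adjusted), Delaunay
cell-cell interaction analysis with a per-tissue distance-percentile edge
filter, and a seeded synthetic-data generator with doublets and
spillover for testing.

## Worked example

```python
from phenogate import SyntheticSpec, generate, SignatureAnnotator, evaluate_labels

spec = SyntheticSpec(n_cells=2000, seed=1)     # 8 types, two rare at 1%
mat, sig, truth = generate(spec)

est = SignatureAnnotator(signature=sig, seed=1).fit(mat)
print(est.assignment_.counts())
report = evaluate_labels(est.assignment_, truth.set_index("cell_id")["label"])
print(f"weighted F1 = {report.weighted_f1:.3f}, "
      f"weighted recall = {report.weighted_recall:.3f}")
```

prints

```
{'clean': 766, 'mixed_resolved': 1224, 'unknown': 10}
weighted F1 = 0.993, weighted recall = 0.990
```

766 cells exceeded exactly one type's threshold, 1224 exceeded several and
were resolved by KNN against the clean anchors, and 10 exceeded none and
stay "Unknown"; against the generator's ground truth the labeling reaches a
weighted F1 of 0.99.

The same workflow is available from the shell:

```bash
phenogate simulate --out sim/
phenogate annotate --features sim/features.csv --signatures sim/signatures.csv \
    --seed 1 --out run/
phenogate evaluate --pred run/annotation.csv --ref sim/truth.csv --out report.json
phenogate neighborhood --annotation run/annotation_xy.csv --out nbhd/
```

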