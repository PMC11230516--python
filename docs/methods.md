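# Methods

## Data model and normalization

The cell-by-feature matrix `A` holds one row per segmented cell and one
column per marker. Antibody intensities (proteomics) are z-scored per
marker using the sample (n−1) standard deviation, matching common
single-cell practice; zero-variance markers become all-zero columns
(with a warning) rather than being dropped, so signature alignment never
silently loses a marker. Transcript counts are library-size normalized —
each cell's counts are scaled to a fixed total (default 10,000) and
`log1p`-transformed with the natural log. The log base and scale factor
are conventions, not identified by the data; both are exposed as
configuration. Multimodal data are column-concatenated after
normalization; a marker name measured in both modalities is kept as two
features with `prot:`/`rna:` prefixes, never merged, because protein and
RNA abundance of the same gene are distinct measurements.

The signature matrix `S` encodes expert knowledge: `s_ij = w ∈ (0, 1]` if
marker *i* defines type *j*, else 0. Every type must have at least one
signature marker; a marker in no signature is allowed (it still
participates in clustering) but triggers a warning.

## Micro-clustering

Cells are partitioned by Louvain community detection (igraph's multilevel
algorithm; a Leiden backend is available behind the same interface) on a
shared-nearest-neighbor graph built from the top 30 principal components
with 20 neighbors and Jaccard edge weights pruned below 1/15 — the
defaults of the Seurat-style pipeline this stage emulates. The clustering
resolution is searched — geometric bracketing (×2 / ÷2 from 1.0) followed
by bisection on a log scale, capped at 25 evaluations — until the mean
cluster size n/k enters the target band, 0.1%–0.5% of cells by default
(equivalently k between 200 and 1000). If the band is unreachable the
closest partition is returned with `in_band=False` and a warning. A single
seed flows into PCA, graph construction, and the community-detection RNG,
making the partition reproducible bit-for-bit.

The micro-clusters are deliberately much finer than cell types: each one
approximates a locally homogeneous population whose median CTR is a
low-noise summary, and whose internal CTR spread carries the within-type
variability the threshold search needs.

## Threshold learning

For each type, micro-cluster median CTRs `z` are ranked (ties broken by
cluster index, so ranks are a deterministic permutation of 1..k) and fit
with the continuous hinge model

    z(r) = α₀ + β₀ r + Σᵢ βᵢ (r − φᵢ)₊ ,   g ∈ {1, 2, 3}.

Breakpoints live on the half-integer grid 2.5, …, k−1.5 with at least two
rank points per segment. Half-integer positions mean no rank ever equals a
breakpoint, which makes low/high group membership (`r ≤ φ₁`, `r ≥ φ_g`)
unambiguous — including for g = 1, where the two groups partition the
clusters exactly. The price is that a kink lying exactly on an integer
rank is fit with a small residual (the best half-integer neighbor), which
is negligible relative to noise in practice.

Least squares over breakpoint candidates is exact and fast: with points
sorted by rank, every entry of the normal equations is a closed form in
suffix sums of r, r², z and rz, so each candidate tuple costs O(g²)
regardless of k. Candidate enumeration is exhaustive when the tuple count
is tractable (all g = 1 fits, and g = 2 up to k ≈ 500); beyond that a
deterministic coarse grid is enumerated and the best tuple refined by
per-breakpoint coordinate descent over the full grid until no improvement.
On all tested instances the refinement reaches the exhaustive optimum;
either path is deterministic.

Model size is chosen by minimal AIC in the Gaussian form
`k·ln(SSE/k) + 2·(2 + 4g)`, ties toward fewer breakpoints. Each breakpoint
is charged four effective parameters: one for its slope change and three
for the knot location itself. A grid-optimized knot is not a fixed
regressor — the search adaptively places it where it absorbs the most
residual variance — and charging adaptively selected hinge knots roughly
three degrees of freedom is the established convention for such models
(the same costing used in adaptive-spline GCV). Charging only one degree
of freedom per knot makes the penalty nearly equal to the expected chance
reduction, and model selection degenerates to a coin flip on noisy
single-kink curves.

The threshold itself is the exact minimizer of
`|{i ∈ C_L : τᵢ > θ}| + |{i ∈ C_H : τᵢ < θ}|` over all real θ: because the
objective is a step function jumping only at observed scores, checking the
midpoints between consecutive sorted unique scores of `C_L ∪ C_H` (plus
one candidate below the minimum and one above the maximum) is exhaustive.
Ties go to the smallest candidate. Degenerate situations — an empty
relevance group, or all pooled scores identical — yield θ = +∞ in the
pipeline (no positive calls for that type) plus a warning, rather than an
arbitrary gate. Positivity is the strict comparison `τ > θ`.

A cell type whose signature markers carry no signal in the tissue is not
reliably detectable as degenerate: the micro-clustering organizes cells
along *all* markers, including pure-noise ones, so even a noise marker
produces a non-flat median curve and a formally valid threshold. In
synthetic tests such a ghost type captures a bounded minority of cells
(~10%) while the true types' labels remain correct; users should curate
panels rather than rely on absent types self-flagging. The genuinely flat
case (e.g. a constant marker) is detected and produces zero calls.

## Deconvolution of mixed cells

Mixed cells are grouped by their exact candidate set ξ and each group is
processed independently, so results do not depend on processing order.
For a group, the feature space is restricted to the union of the
candidate types' signature markers — this subspace restriction is what
removes the irrelevant-marker noise that made the cell ambiguous — and
each mixed cell receives the modal label of its k = 10 nearest clean
anchors (cells clean for any type in ξ) by Euclidean distance. Modal ties
break toward the label with the smaller mean neighbor distance, then by
signature column order. If fewer than k anchors exist, k is reduced; if
no anchors exist at all, the cells stay "Unknown" with category
`unresolved_mixed`. Clean labels are never modified.

## Evaluation metrics

Per-type confusion counts are computed over the cells shared by the
predicted and reference labelings; a predicted "Unknown" is always a false
negative for the cell's reference type, never a true positive. Reference
labels can be excluded by list (for reference categories like
"dirt"/"undefined" that are not comparable cell types). Weighted recall,
precision and F1 weight each type by its reference proportion; accuracy is
pooled over all per-type counts. Types at ≥ 1% of the reference are
reported as dominant, below as rare. Precision/recall with a zero
denominator score 0 with a warning.

Marker enrichment strength is computed for markers unique to exactly one
signature type: the log₂ ratio of the mean value in cells assigned to that
type versus cells assigned to any other type (a configurable pseudocount,
default 0.01, guards zero means; on z-scored data a negative group mean
makes the ratio undefined and is reported as NaN), plus a one-sided
Wilcoxon rank-sum test (greater) with Benjamini–Hochberg adjustment across
the tested markers.

## Neighborhood analysis

Cells with coordinates and a known label (never "Unknown") are Delaunay-
triangulated; unique undirected edges longer than the 97th percentile of
that tissue's own edge-length distribution are discarded as improbable
contacts (edges exactly at the cutoff are kept). The interaction matrix
counts surviving edges per unordered type pair; an A–A edge increments the
diagonal once. When a sample column is present, each sample is processed
against its own percentile.

## Synthetic data

The generator is a fixture factory, not an emulator of any real panel.
Proteomics mode: background values ~ Normal(0, noise_sd), and each cell's
signature markers are shifted by `signal_shift` standard deviations scaled
by the signature weight (default shift 3 sd — strong but realistic
separation for a curated antibody panel). Transcriptomics mode: Poisson
counts with background rate 0.5 and signature rate `0.5 · 2^(shift·w)`.
The default population is 10,000 cells in eight types, two of them at 1%
abundance, with 20 markers assigned round-robin (so every type owns 2–3
unique markers). Doublets (a configurable fraction of cells receiving a
second type's signal) model imperfectly segmented mixed cells; spillover
adds a fraction of the nearest spatial neighbor's signal to model boundary
bleed-through. Coordinates are uniform or per-type Gaussian blobs.

What the generator does *not* reproduce: correlated marker noise,
intensity batch effects across tissues, heavy-tailed antibody background,
segmentation-size covariates, or spatially structured abundance. Tests
passing on these fixtures therefore demonstrate the algorithm's
correctness and its behavior under idealized mixing/bleed-through, not
performance on any real tissue.

## Problem sizes and determinism

The shipped verification runs use 100 random instances for the threshold
oracle, 100 replicates of k = 200 rank curves for breakpoint recovery, and
the default 10,000-cell panel (with and without 10% doublets) for the
end-to-end and deconvolution studies — sizes chosen so the whole suite
re-runs in well under a minute per study on one CPU while keeping
Monte-Carlo error small relative to the margins asserted. Every stochastic
stage (generation, PCA, graph building, community detection, subsampling)
derives from a single user-supplied seed; identical seeds give
hash-identical outputs.

## Known limitations

* Signature quality bounds everything: the method cannot discover types
  the panel does not encode, and absent types are not self-flagging (see
  above).
* The resolution search assumes cluster count responds monotonically to
  the resolution parameter; strong violations fall back to the closest
  achieved partition, flagged.
* Thresholds are transductive — learned on the dataset being annotated.
  `predict` on new data gates with the fitted thresholds and deconvolves
  against the fitted anchors, which is only sensible when the new data
  share the panel and normalization.
* Micro-cluster medians assume micro-clusters are type-homogeneous; at
  very low n (a few hundred cells) the band forces tiny clusters and the
  median curves get noisy.
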