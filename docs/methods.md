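# Methods

This note documents the models, parameter choices and numerical conventions
behind `spotica`, and what the synthetic benchmark does and does not
demonstrate about real data.

## Normalization

Spot-level counts are overdispersed and depth-dominated. We model each gene's
counts as negative binomial with an offset mean tied to spot depth,
μ_ig = n_i · p_g, where n_i is spot i's total count and p_g gene g's share of
all counts, and variance μ + μ²/θ_g. The working representation is the
Pearson residual clipped to ±√(n_spots). This is the analytic
(closed-form) variant of regularized NB normalization: rather than fitting a
per-gene GLM, the depth effect enters as an exact offset and only θ_g is
estimated. The two approaches target the same statistic; the analytic form
is deterministic, fast, and has no convergence failures, which matters
because the decomposition, not the normalization, is the substance of this
package.

θ_g is estimated by method of moments, θ̂_g = Σμ² / Σ((x−μ)² − μ), floored at
10⁻⁴ and capped at 10⁸ (a non-positive denominator means no detectable
overdispersion and maps to the cap, i.e. Poisson-like). Raw estimates at
spot-level depths are noisy, so log θ̂ is smoothed by Gaussian-kernel
regression against log₁₀ gene mean with Silverman's rule-of-thumb bandwidth:
genes of similar abundance share statistical strength, mirroring standard
practice for this family of normalizations.

Genes detected in fewer than 5 spots are dropped by default
(`min_spots_per_gene=1` restores a strict all-genes policy); moment
estimates below that detection level are meaningless. No highly-variable-gene
selection is applied — the decomposition consumes the full retained
transcriptome.

## Decomposition and curation

The residual matrix Z (spots × genes) is factored Z ≈ A·S by ICA with genes
as the observation dimension: rows of S are unit-variance gene-loading
vectors whose mutual statistical independence (equivalently, maximal
non-Gaussianity) is the estimation criterion, and A carries the per-spot
mixing weights. Defaults are k = 100 components and 600 iterations with
FastICA; extended infomax and JADE are alternative backends behind the same
contract (FastICA is the reference path — the backends agree on
well-separated sources but are not numerically interchangeable). k = 100
deliberately over-decomposes: surplus components either capture noise (and
fail curation) or split one signal in two (and can be re-merged), whereas
under-decomposition irreversibly mixes signals. Runs are deterministic per
seed; the seed is stored in the workspace because individual loadings differ
between ICA restarts even though the contributor-gene structure is stable.

Curation operates on the gene-loading side:

* **Kurtosis filter.** Plain (non-excess) kurtosis m₄/m₂² of each loading
  vector; components at or below 3 — the Gaussian value — are flagged out.
  A leptokurtic loading distribution means a small set of genes drives the
  component, which is what makes it interpretable as a cell type or program.
  Filtering only flags; nothing is deleted, every step is reversible.
* **Sign correction.** ICA signs are arbitrary. Each component is oriented
  so that the side of its loading distribution with the largest absolute
  value is positive (the paired weight column is negated jointly, leaving
  A·S unchanged; exact |min| = |max| ties keep the current orientation — a
  measure-zero case). Marker genes then sit in the positive tail and
  positive spot weights read as presence.
* **Contributor genes.** Genes with loading z-score magnitude ≥ 3 within
  their component (population standard deviation), ordered by |z|.
* **Merging.** Components sharing an annotation are recombined by addition
  of their weight columns (and loading rows). Merged components are flagged
  `derived`: the reconstruction A·S is always computed over the original
  factorization, so merging is bookkeeping, not arithmetic on the model.

## Compositions

Within a spot, the absolute scale of IC weights is not meaningful but their
ratios track cell-type ratios. Negative weights are zeroed; positive weights
are divided by the spot's positive total; entries below the high-pass
threshold (default 0.05) are zeroed as noise and the row re-closed.
Re-closure after the high-pass keeps every row on the simplex, which the
ILR transform and RMSE require. Spots with no positive weight become
all-zero rows, are flagged, and are excluded (and counted) wherever a
composition is consumed.

The ILR transform uses the fixed Helmert-contrast orthonormal basis,
ilr_A(x) = √(A/(A+1)) · ln(g(x₁..x_A)/x_{A+1}). Any orthonormal basis gives
the same distances and the same overall RMSE; per-dimension RMSE values are
basis-dependent and should be read under this convention. Zeros are replaced
by 10⁻⁶ and the row re-closed before transforming.

## Evaluation protocol

Simulating perfect annotation: each component is assigned to the cell type
whose reference mean-expression profile has the highest Pearson r with the
component's gene loadings (ties go to the first type index, logged).
Assignments below r = 0.3 are flagged low-confidence and excluded from
aggregation by default — the null distribution of r between random loadings
and marker profiles stays well below that. Same-annotated components are
summed, contributions under the abundance filter (default 0.10) removed,
rows re-closed, and both sides ILR-transformed with the same basis and zero
replacement. RMSE_A = √(Σᵢ(y_Ai − ŷ_Ai)²/N) per ILR dimension; the overall
RMSE is the root mean square over all dimensions and spots.

Two predictors are compared with a one-tailed Diebold–Mariano test on their
per-spot losses. The per-observation loss is the mean squared ILR error of a
spot (a per-spot quantity is required; the overall RMSE itself is a single
number). Spots are exchangeable, not serially ordered, so the lag-0 sample
variance is used — no autocorrelation correction. Degenerate cases (zero
variance of the loss differential) are flagged rather than silently scored.

## Pseudospot binning

Transcript tables are binned on a regular square grid with half-open
intervals [x₀+i·m, x₀+(i+1)·m): a molecule exactly on a boundary belongs to
the higher-index bin and is never double-counted; with no minimum-count
filter the output conserves the input count exactly. The origin defaults to
the floor of the data's minimum coordinates and is exposed because an
instrument-frame origin can shift bin contents slightly. Defaults: 40 µm
bins with a <5-transcript filter for MERSCOPE; 24 µm (200 px at 0.12 µm/px)
with no filter for CosMX. Pseudospot coordinates are geometric bin centers,
for plotting parity with array-based spots. Multi-sample binning bins each
sample separately, prefixes spot ids with the sample id, records
`sample_of_origin`, and zero-fills the union gene panel.

## Synthetic benchmark

The generator emulates a multi-region mixture benchmark: 5 contiguous
regions, 2–10 cells per spot (uniform), per-region Dirichlet priors over 8
cell types in which a subset of types dominates each region and dominant
sets overlap between regions, and NB counts (shared θ = 10) around cell-type
reference profiles with per-cell log-normal library-size factors (σ = 0.35).
Ground truth (cell counts, proportions, region labels, priors, profiles) is
recorded exactly.

Reference profiles are a log-normal baseline (σ = 0.5) shared across types,
with each type's disjoint block of 25 marker genes (of 2000) up-regulated
8-fold, and a per-type log-normal expression scale (σ = 0.3) because real
cell types differ in total transcript content. Two calibration choices
deserve note, both made so the stand-in benchmark is *identifiable the way a
real reference is*, not to make it easy. First, dominance is balanced and
degenerate draws are rejected: every type must be dominant somewhere, no
type everywhere, and no two types may share an identical region-dominance
pattern — a type violating these is spatially (near-)uniform or a clone of
another and no spatial method, reference-free or not, could resolve it.
Second, the baseline σ is moderate: with a much heavier baseline the shared
baseline dominates profile variance and even a perfect marker-indicator
loading correlates with the raw profile at only r ≈ 0.4, a degeneracy real
references do not have.

What the benchmark does **not** emulate: platform noise (optical crowding,
segmentation error), doublets, gradual type hierarchies, genes down- rather
than up-regulated in a type, and spatial structure finer than region blocks.
Passing here shows the pipeline recovers well-posed mixtures; it does not
bound performance on tissues with continuous gradients or highly correlated
subtypes.

## Known limitations

* **One type is the compositional background.** Spot data are closed: a
  spot's type proportions sum to one, and depth normalization removes the
  total. The depth-normalized signal of K types therefore spans only K−1
  independent directions, and one type — the effective background — appears
  only as the shared negative tail of the other types' components, never as
  a dedicated component. On the 8-type benchmark the pipeline consistently
  recovers 7 of 8 types by signature matching (best r 0.6–0.8 each) with the
  background type near r ≈ 0; its marker signal is demonstrably present in
  the residuals (r ≈ 0.94 against its true proportions) but is distributed
  across the other components. Per-type expression-scale differences soften
  the closure but, at realistic magnitudes, do not break it. This is a
  property of reference-free decomposition of closed data, not of a
  particular ICA backend.
* Compositions are read-share compositions: types with more transcripts per
  cell are over-represented relative to cell-count proportions.
* Modularity clustering on a kNN/SNN graph has a granularity set jointly by
  the resolution parameter and the neighborhood size; cluster counts are not
  comparable across different `neighbors` settings.
* The DM test's normal reference assumes enough spots (n ≥ 30 enforced) and
  exchangeability; spatially autocorrelated losses will make it liberal.
* ICA loadings differ in detail between seeds; contributor-gene lists and
  annotations are stable, and the pinned seed makes any single analysis
  exactly reproducible.
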