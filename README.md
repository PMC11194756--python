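# spotica

Reference-free deconvolution of spatial transcriptomics data by independent
component analysis (ICA).

Spatial capture technologies measure gene expression in spots (Visium-style
arrays) or in individual molecules (MERSCOPE, CosMX) that can be binned into
pseudospots. Each spot covers a handful of cells, so its expression profile
is a mixture of cell-type signals. Most deconvolution tools unmix these
profiles against a single-cell reference atlas; `spotica` instead treats
deconvolution as blind source separation: spots are sensors, cell types and
biological activities are sources, and ICA recovers the sources directly from
the data.

## The method

Given a spot × gene count matrix **X**:

1. **Normalization.** Counts are modelled per gene as negative binomial with
   offset means μ<sub>ig</sub> = n<sub>i</sub>·p<sub>g</sub> (n<sub>i</sub> =
   spot depth, p<sub>g</sub> = gene's pooled fraction) and regularized
   per-gene overdispersion θ<sub>g</sub>. The working matrix is the clipped
   Pearson residual z<sub>ig</sub> = (x<sub>ig</sub> − μ<sub>ig</sub>) /
   √(μ<sub>ig</sub> + μ<sub>ig</sub>²/θ<sub>g</sub>), on **all** genes — no
   highly-variable-gene selection.
2. **ICA.** The residual matrix is decomposed as **Z** ≈ **A**·**S**, where
   the rows of **S** (k × genes, k = 100 by default, 600 iterations, FastICA)
   are independent unit-variance gene-loading vectors and **A** (spots × k)
   holds per-spot mixing weights.
3. **Curation.** Only leptokurtic components (plain kurtosis m₄/m₂² > 3 of
   the loading vector) are kept; each component is sign-corrected so the
   heavy tail of its loading distribution is positive; its signature is the
   set of contributor genes with loading |z-score| ≥ 3. Components can be
   annotated (ORA of contributor genes against GMT libraries), merged by
   addition, or discarded — all reversibly.
4. **Composition.** Within a spot, negative weights are zeroed and positive
   weights divided by their total; relative abundances below a high-pass
   threshold (0.05 by default) are removed and the row re-closed. The result
   is a per-spot composition over components or, after annotation, cell
   types.
5. **Evaluation.** Against a simulated ground truth, components are matched
   to cell types by Pearson correlation of loadings with reference profiles,
   summed by annotation, and scored in isometric log-ratio (ILR) space:
   RMSE<sub>A</sub> = √(Σ<sub>i</sub>(y<sub>Ai</sub> − ŷ<sub>Ai</sub>)²/N)
   per ILR dimension A, with a one-tailed Diebold–Mariano test comparing
   per-spot losses between predictors.

The package also bins imaging-based transcript tables into pseudospot
matrices (40 µm default for MERSCOPE with a <5-transcript filter, 24 µm =
200 px for CosMX), clusters spots on an SNN graph of the curated latent
space, embeds them with UMAP, renders kernel-density maps of selected
signals, and subsets workspaces by cluster, density, or spot id.

## Worked example

```python
import spotica as sp

# a synthetic benchmark with known ground truth
ref = sp.make_reference(n_types=8, n_genes=2000, markers_per_type=25, seed=0)
spots, truth = sp.simulate_spots(ref, n_spots=1500, n_regions=5,
                                 cells_range=(2, 10), seed=0)

nm = sp.normalize(spots)                      # NB Pearson residuals
d = sp.run_ica(nm, k=30, seed=0)              # 30 components
sp.filter_by_kurtosis(d)                      # keep leptokurtic components
sp.sign_correct(d)
comp = sp.to_composition(d, high_pass=0.05)   # per-spot compositions
report = sp.evaluate_deconvolution(d, comp, ref, truth, abundance_filter=0.10)

print(f"{int(d.kept.sum())}/30 components kept")
print(f"mean matching r: {report.feature_map['r'].mean():.2f}")
print(f"ILR RMSE: {report.rmse_overall:.2f}  (DM p vs uniform: {report.dm_p:.3g})")
```

Output:

```
28/30 components kept
mean matching r: 0.19
ILR RMSE: 4.16  (DM p vs uniform: 0)
```

28 of 30 components pass the kurtosis filter; the matched components
correlate with the true cell-type profiles (the mean is pulled down by noise
components that match nothing); and the recovered compositions sit far below
the uniform-composition baseline (RMSE ≈ 6.3) with a Diebold–Mariano p-value
that underflows to 0.

The same pipeline is available from the shell:

```sh
spotica simulate --n-spots 1500 --out sim/
spotica run --out run/          # simulate → normalize → ica → curate → evaluate
spotica bin --input tx.csv --dialect merscope --bin-size 40 --out ws.zip
```

## Layout

| module | contents |
|---|---|
| `spotica.io` | Space Ranger triplet reader, transcript tables, GMT, workspace archive |
| `spotica.binning` | pseudospot grid binning, multi-sample merging |
| `spotica.preprocess` | NB Pearson-residual normalization |
| `spotica.decomposition` | ICA, kurtosis filter, sign correction, contributors, merging |
| `spotica.composition` | positive-weight compositions, ILR transform |
| `spotica.annotation` | local ORA, component annotation |
| `spotica.synthetic` | benchmark generator with ground truth |
| `spotica.evaluation` | signature matching, ILR-RMSE, Diebold–Mariano |
| `spotica.downstream` | SNN clustering, UMAP, density maps, subsetting |
| `spotica.cli` | `spotica` command-line interface |

See `docs/methods.md` for the modelling choices and their rationale.
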