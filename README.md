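# follistat

Spatial point-pattern analysis of cell arrangements in lymphoid follicles.

Germinal centers (GC) in benign lymphoid tissue and the neoplastic follicles
of follicular lymphoma (FL) both contain B cells interspersed with
microenvironmental "bystander" cells — T cells (CD3), follicular T-helper
cells (PD1), follicular dendritic cells (CD21) and macrophages (CD68). Their
abundance is routinely reported, but their *arrangement* carries information
too: cells that interact tend to sit closer together than chance predicts.
`follistat` turns multiplexed fluorescence micrographs into per-cell-type
point patterns and asks, for each cell type and tissue compartment (light
zone LZ, dark zone DZ, or whole FL follicle), whether the cells are
**clustered**, **completely spatially random (CSR)**, or **regular**.

The package is aimed at image-analysis and computational-pathology
researchers who want a fully testable version of this pipeline: every stage
can be exercised on synthetic data with known ground truth, with no external
image downloads.

## What it computes

1. **Synthetic follicles** (`follistat.synthetic`) — elliptical follicle
   masks split into LZ/DZ, planted point processes (homogeneous Poisson =
   CSR; Thomas cluster; hard-core), and rendered fluorescence channels
   (nuclear disks or membrane rings, Gaussian PSF, Poisson shot noise) with
   ground-truth coordinates.
2. **Denoising** (`follistat.preprocess`) — channel-wise total-variation
   denoising under the Poisson noise model: minimize
   `J(u) = Σ [u − f log u] + λ · TV_ε(u)` by projected gradient descent
   with a monotone-descent guarantee.
3. **Segmentation** (`follistat.segment`) — nuclei by threshold +
   distance-transform watershed + size filter; membrane-marker positivity
   per nucleus from the median marker intensity in an annulus around the
   nucleus centroid.
4. **Spatial statistics** (`follistat.spatial`) — densities (cells/mm²)
   with Welch t-tests; Ripley's K,
   `K̂(r) = (A / n(n−1)) Σ_{i≠j} w_ij 1[d_ij ≤ r]`,
   and the pair correlation function
   `ĝ(r) = Σ_{i≠j} w_ij κ_h(r − d_ij) / (2πr λ̂² A)`
   (Epanechnikov kernel, Stoyan bandwidth `h = 0.15/√λ̂`), both with
   translation edge correction computed from the window's set covariance on
   the binary mask; pooled min/median/max envelopes across follicles;
   Monte-Carlo CSR envelopes conditional on n; and the
   clustered / csr / regular classification. Under CSR, `K(r) = πr²` and
   `g(r) = 1`; `g > 1` at radius r means an excess of same-type neighbors
   at that distance.
5. **Orchestration** (`follistat.report`, CLI `follistat`) — a seeded,
   bit-reproducible experiment runner with CSV/JSON/PNG outputs.

## Worked example

The built-in demo experiment simulates nine zoned GC follicles with
CSR-arranged B and T cells and nine FL follicles whose T cells follow a
Thomas cluster process with a 5 µm offspring dispersal:

```python
import follistat as fs

report = fs.run_pipeline(fs.demo_config(outdir="demo", seed=3))
for (group, comp, cell), entry in report["curves"].items():
    print(group, comp, cell, entry["majority_call"])
```

prints

```
GC LZ B csr
GC LZ CD3 csr
GC DZ B csr
GC DZ CD3 csr
FL FL B csr
FL FL CD3 clustered
```

i.e. every cell type is indistinguishable from random in the benign zones,
while the FL T cells exit their CSR envelope — their g(r) rises well above 1
at short range, the planted 5–10 µm cluster scale. `demo/densities.csv`
holds per-follicle densities, `demo/density_tests.csv` the pairwise Welch
comparisons, `demo/classification.csv` the per-follicle and majority calls,
and `fs.plot_results(report)` writes g(r) panels (grey min–max envelope,
thick median line) and density box plots.

The same pipeline runs from the shell:

```sh
follistat simulate --out f1 --process thomas --no-render --seed 4
follistat stats --points f1/points.csv --mask f1/mask_GC.tif \
          --out f1/curve.csv --envelope 99 --seed 1
# -> n=…, density=…/mm^2 and: classification vs CSR envelope: clustered
```

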