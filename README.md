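# geometab

Spatially resolved NMR metabolomics for field-scale crop surveys.

`geometab` implements the full analysis chain that turns georeferenced 1D
¹H-NMR spectra of plant extracts into maps of metabolic variation across an
agricultural field:

1. **Spectral processing** — exponential apodization (0.3 Hz), zero-filled
   FFT, automatic or manual phase correction, asymmetric-least-squares
   baseline correction, and chemical-shift calibration to the DSS reference
   singlet at 0.015 ppm.
2. **Targeted quantification** — each catalogued metabolite resonance is
   modelled as a Lorentzian multiplet (singlet `s`, doublet `d`, doublet of
   doublets `dd`, or five-line 1:4:6:4:1 pattern `5m`) with a tied centre,
   linewidth and total area; overlapping multiplets — e.g. the crowded
   polysaccharide/sucrose anomeric cluster at 5.38–5.44 ppm — are
   deconvolved jointly by nonlinear least squares. Built-in catalogs cover
   durum-wheat shoot and blooming-spike extracts.
3. **Metabolic indexes** — the site × metabolite matrix is standardized
   (z<sub>ij</sub> = (x<sub>ij</sub> − μ<sub>j</sub>)/σ<sub>j</sub>) and collapsed to one scalar per site,
   MI<sub>i</sub> = Σ<sub>j</sub> w<sub>j</sub> z<sub>ij</sub>, with three weighting schemes: equal weights
   (mean), coefficient-of-variation weights w<sub>j</sub> ∝ CoV<sub>j</sub> = σ<sub>j</sub>/μ<sub>j</sub>, or the
   first principal component of the standardized matrix.
4. **Geostatistics** — WGS84 → UTM projection (order-6 Krüger series),
   empirical semivariograms (20 equal-width bins) with exponential-model
   fits γ(h) = c₀ + c·(1 − e^(−h/ℓ)), ordinary kriging with prediction
   variance, global Moran's I and local Moran (LISA) under
   triangular-kernel spatial weights with adaptive k = 7 nearest-neighbour
   bandwidths, thin-plate-spline interpolation as the deterministic
   fallback when the variogram is flat, and distribution diagnostics
   (histogram, KDE, normal Q–Q).

A synthetic-data module generates the whole study from scratch — jittered
quasi-grid sampling positions with 3 m GPS error, Gaussian random fields
with exponential covariance, spatially clustered bimodal mixtures, and
synthetic FIDs containing the full signal catalog — so every stage of the
pipeline can be exercised and validated against known ground truth.

## Worked example

Simulate a 48-site survey of a 400 × 200 m wheat field in which acetic
acid has a spatially clustered bimodal distribution (standardized modes
near −0.5 and 2.0, the low mode holding 70% of the sites), quantify every
spectrum, and test the spatial structure:

```python
import numpy as np
from geometab import (BimodalSpec, FieldSpec, MetabolicIndex, Variogram,
                      build_kernel_weights, make_survey, morans_i,
                      quantify_dataset, wheat_shoots_catalog)
from geometab.nmr import process_fid

catalog = wheat_shoots_catalog()
field = FieldSpec(n_sites=48, extent_m=(400, 200), corr_length_m=50,
                  nugget=0.09, seed=17)
survey = make_survey(field, catalog,
                     bimodal_for={"acetic acid": BimodalSpec(cluster_length_m=90.0)})

spectra = {site: process_fid(fid, phi0_deg=0, phi1_deg=0)
           for site, fid in survey["fids"].items()}
quant = quantify_dataset(spectra, catalog)          # 48 × 21 area matrix

mi = MetabolicIndex(quant.matrix, scheme="pca").fit()
weights = build_kernel_weights(survey["xy_m"], k=7)
print(morans_i(quant.matrix["acetic acid"].to_numpy(), weights,
               n_perm=999, seed=5).summary())
print(morans_i(mi.index.to_numpy(), weights, n_perm=999, seed=5).summary())
```

which prints

```
Moran's I = +0.4576 (E[I] = -0.0213 under no spatial correlation); two-sided permutation p = 0.0010 (999 permutations)
Moran's I = +0.5568 (E[I] = -0.0213 under no spatial correlation); two-sided permutation p = 0.0010 (999 permutations)
```

The planted acetic-acid clusters are strongly spatially autocorrelated
(I ≫ E[I], p at the permutation floor of 1/(999+1)), and the structure
carries through to the PC1 metabolic index computed from all 21
metabolites. `Variogram(survey["xy_m"], mi.index.to_numpy()).fit()` then
supplies the exponential variogram model for `ordinary_krige`, and
`local_moran` maps the HH/LL cluster cores site by site.

The same chain runs end-to-end from files via the CLI:

```sh
geometab run --config pipeline.yaml     # spectra -> quantification -> MI -> maps
geometab project 40.82 16.08            # WGS84 -> UTM zone 34N (EPSG:32634)
geometab moran sites.csv acetic_acid --k 7
```

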