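# gortlai

LAI retrieval from full-waveform LiDAR fused with spectral canopy cover.

The package implements a physically based leaf-area-index (LAI) pipeline for
large-footprint waveform LiDAR combined with a per-pulse fractional
vegetation cover (FVC) covariate from multispectral imagery:

1. **Waveform preparation** — background-noise removal against the per-shot
   mean noise level (`sigmean`) and Gaussian smoothing
   (`gortlai.waveform_prep`).
2. **Gaussian decomposition** — amplitude-weighted EM fitting of the echo as
   a superposition of Gaussians, optionally with each peak position
   constrained to a box around its initial estimate so close echoes are not
   merged during optimization; optional least-squares refinement
   (`gortlai.decomposition`).
3. **Energy partitioning** — the lowest component is the ground return; the
   rest are canopy.  Analytic ±3σ component integrals give the ground energy
   Rg, the total canopy energy Rv(0), the cumulative canopy profile Rv(z) and
   the 80%-canopy-energy height (`gortlai.canopy_energy`).
4. **Reflectivity-ratio fusion** — per-pulse canopy/ground reflectivity
   ratio from the GORT cover equation,
   `rho_v/rho_g = Rv(z)/(FVC*Rg) - Rv(0)/Rg`, gridded onto 0.002° cells with
   a ±3 sd trimmed mean per cell (`gortlai.ratio_fusion`).
5. **LAI inversion** — closed-form GORT inversion
   `LAI = (C/G) * ln(1 + Rv(0)/(ratio*Rg))` with clumping index C = 1.58 and
   projection coefficient G = 0.5 by default, plus fixed-ratio and NDVI
   regression baselines (`gortlai.lai_model`).
6. **Synthetic scenes** — a forward simulator emitting pulse tables and
   matched FVC/NDVI with known ground truth, so the whole chain is testable
   offline (`gortlai.synthetic_scene`), and evaluation metrics
   (`gortlai.evaluation`).

## CLI

The console script `gortlai` chains the pipeline over CSV tables
(`rxwave` is a quoted semicolon-separated amplitude list):

```sh
gortlai simulate --config scene.toml --out pulses.csv --truth truth.csv
gortlai decompose --pulses pulses.csv --out comps.csv --energy energy.csv [--no-constraints]
gortlai ratio --comps comps.csv --pulses pulses.csv [--fvc-raster fvc.tif] --out ratios.csv
gortlai grid --ratios ratios.csv --cell 0.002 --out grid.csv --summary grid.json
gortlai invert --comps comps.csv --pulses pulses.csv --grid grid.csv \
    [--fixed-ratio 2.5] [--per-pulse --ratios ratios.csv] \
    --clumping 1.58 --gfactor 0.5 --out lai.csv [--geotiff lai.tif]
gortlai evaluate --est lai.csv --ref truth.csv --out report.json
```

Configuration files (TOML or YAML) mirror `gortlai.config.RunConfig`; all
defaults reproduce the published parameter choices (C = 1.58, G = 0.5,
0.002° cells, 80% canopy-energy height, ±3σ integration, ±3 sd trimming).
GeoTIFF sampling/writing is handled via tifffile (north-up WGS84 rasters).

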