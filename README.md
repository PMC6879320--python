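# ndi — nanodomain imaging analysis

Quantitative image and fluctuation analysis for studying nanoscale
clustering of membrane proteins — in particular GPI-anchored proteins,
whose nanoclustering is driven by cortical actin activity downstream of
integrin adhesion. The package is aimed at quantitative microscopists who
acquire polarized TIRF, confocal FCS, or Laurdan data and need a tested,
scriptable pipeline from raw channel images to calibrated physical
quantities.

## What it computes

**Emission anisotropy (homoFRET) mapping.** From paired polarized channels,
after background subtraction, affine channel registration and G-factor
correction:

    r = (Ipa − g·Ipe) / (Ipa + 2·g·Ipe)

Lower r means more homoFRET, i.e. more nanoclustering. Includes ROI
statistics (photon-weighted, from summed channel intensities),
intensity-binned anisotropy curves, photobleaching analysis (r vs I/I0 with
linear extrapolation to the monomer anisotropy at complete bleaching),
whole-cell spreading kinetics aligned to the peak area change, and
line-scan kymographs.

**FCS model fitting.** Multi-tau autocorrelation of intensity traces, trace
QC (drift/burst rejection), and weighted least-squares fitting of the
triplet × two-component diffusion model

    G(τ) = (1/N)·[1 + T/(1−T)·e^(−τ/τT)]·[f·(1+τ/τD1)⁻¹(1+τ/(S²τD1))^(−1/2) + (1−f)·(1+τ/τD2)⁻¹]

with the structure factor S fixed to 0.2 by default (free fits converge
there).

**Laurdan generalized polarization.** Per-pixel membrane order
GP = (ICh1 − G·ICh2)/(ICh1 + G·ICh2), with the G-factor calibrated in
closed form against the conventional Laurdan-in-DMSO reference
GP_ref = 0.207.

**Spatial statistics.** Blob segmentation of vinculin clusters / paxillin
adhesions, adhesion area tables, anisotropy extraction inside blob masks,
the nanopattern on/inter-pattern ROI scheme, peak-aligned line profiles and
cluster-centered average images.

**Synthetic data.** Every analysis has a ground-truthed generator that
inverts its formula exactly (plus Poisson/read camera noise), so the whole
pipeline is verifiable without microscope data. See `docs/methods.md` for
models, parameter defaults and limitations.

## Worked example

Simulate a photobleaching series of a partially clustered membrane
(initial anisotropy 0.19, monomer anisotropy 0.23) and recover the monomer
value by extrapolating the binned r-vs-I/I0 curve to complete bleaching:

```python
import numpy as np
from ndi import polarimetry as pol, homofret, synthetic as syn

pset, truth = syn.make_bleach_series(
    n_frames=30, r_start=0.19, r_mono=0.23, shape=(256, 256), seed=0
)
pset = pol.subtract_background(pset)
rng = np.random.default_rng(7)
regions = [
    pol.Region.rectangle(int(r), int(c), 20, 20)   # ~2x2 um ROIs
    for r, c in zip(rng.integers(0, 236, 10), rng.integers(0, 236, 10))
]
curve = homofret.bleach_analysis(pset, 1.0, regions, n_bins=10)
print(f"slope     = {curve.slope:.4f}")
print(f"intercept = {curve.intercept:.4f}")
print(f"asymptote = {curve.asymptote:.4f}")
```

Output:

```
slope     = 0.0413
intercept = 0.1895
asymptote = 0.2308
```

The positive slope is the homoFRET signature (anisotropy rises as bleaching
dilutes clusters); the intercept recovers the pre-bleach anisotropy of the
clustered membrane; the asymptote recovers the monomer limiting anisotropy
(truth 0.23) — a flat curve would instead indicate a monomer-only membrane.

## Command line

`ndi` exposes the pipelines as subcommands sharing a YAML config
(`ndi defaults` prints every default):

```
ndi synth --scene bleach --seed 1 --out scene/
ndi aniso --pa img_pa.tif --pe img_pe.tif --gfactor g.tif --rois rois.json --out out/
ndi bleach --pa ... --pe ... --rois rois.json --out out/
ndi fcs fit --acf curve.csv --fix S=0.2
ndi gp --ch1 ch1.tif --ch2 ch2.tif --gp-mes 0.35 --out out/
ndi blobs / profile / pattern-rois / spread / kymo / run ...
```

Every run directory contains a `manifest.json` (config snapshot, input
digests, package version, seed) for bit-identical reproduction.

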