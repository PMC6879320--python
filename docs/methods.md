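# Methods

This note documents the models implemented in `ndi`, the choices made where
the underlying measurement protocols leave the numerics open, and what the
synthetic-data generators do and do not emulate.

## Emission anisotropy from polarized image pairs

A fluorophore population excited with linearly polarized light is imaged
simultaneously in channels parallel (`Ipa`) and perpendicular (`Ipe`) to the
excitation polarization. The steady-state emission anisotropy per pixel is

    r = (Ipa − Ipe′) / (Ipa + 2·Ipe′),   Ipe′ = g · Ipe

where `g` is the pixelwise detection-sensitivity ratio of the two channels
(`G-factor`), measured as `Ipa/Ipe` on an isotropic fluorescein solution.
homoFRET between like fluorophores in a nanocluster depolarizes emission, so
lower `r` reports more clustering. `r` is bounded in [−0.5, 1] for any
nonnegative channels and positive `g`; `r = 0` iff `Ipa = Ipe′`, `r = 1` iff
`Ipe′ = 0`.

Processing order: background subtraction (buffer image or scalar; negatives
clipped to zero — camera offset noise would otherwise push `r` outside its
physical range), channel registration, G-factor correction, thresholded
anisotropy map. A 2-D averaging filter (window 3 or 5) may be applied to the
`r` field for rendering; it never feeds quantification, which either reads
the unsmoothed field or recomputes `r` from summed channel intensities.

**Registration.** The perpendicular channel is aligned to the parallel one
by maximizing normalized cross-correlation over translation + rotation +
isotropic scale, started from the phase-correlation translation estimate
(Powell simplex-free optimization, bilinear interpolation, zero border
fill). Precomputed transforms can be supplied instead. Degenerate (constant)
references return the identity with a warning flag rather than failing. For
bleach series the transform is estimated on the first (un-bleached) frame
and applied to all frames; for spreading movies the last (fully spread)
frame is used.

**ROI statistics.** Region anisotropy is photon-weighted: channel
intensities are summed over the region and the formula applied to the sums.
On a uniform region this equals the pixel-mean alternative (available behind
`pixel_mean=True` for sensitivity analysis); on non-uniform regions it
weights bright pixels more, matching how intensities extracted from ~2×2 μm
membrane ROIs combine. ROI curves can be binned by total intensity
(`Ipa + 2·Ipe′`); a value on a shared bin edge goes to the lower bin, the
final bin is closed.

**Open numerical choices made here.** Intensity threshold default 0 (maps)
— the measurement protocol prescribes thresholding without a number, so
thresholds are always explicit parameters; G-factor dark-pixel floor at 1%
of the median reference `Ipe`, imputed with the median `g` and flagged;
pixel size default 50/512 ≈ 0.0977 μm/px (512-pixel EMCCD field of ~50 μm at
100× magnification); coordinates 0-based, rectangles half-open.

## Photobleaching nanocluster analysis

Bleaching stochastically destroys fluorophores, diluting clusters into
effective monomers: with nanoclusters present the ROI anisotropy rises
linearly as intensity falls, converging to the monomer limiting anisotropy
(~0.23 for the YFP probe); a monomer-only membrane stays flat. Per ROI and
frame the photon-weighted anisotropy and total intensity are computed,
intensities normalized to the ROI's first frame (`I/I0`), pairs pooled
across ROIs, binned in 10 equal-width `I/I0` bins over (0, 1], and an
ordinary least-squares line `r = a·(1 − I/I0) + r0` fitted to bin means with
centers in [0.2, 1.0], extrapolated to `I/I0 = 0` (asymptote `a + r0`). The
bin count and fit window are package decisions — the underlying protocol
describes binning and a linear rise without prescribing either; the window
excludes deeply-bleached bins where shot noise dominates.

## Spreading kinetics and kymographs

Per frame, the cell is segmented from the total-intensity image (largest
above-threshold connected component, Otsu default), its area taken as pixel
count × pixel-size², and the whole-cell anisotropy computed from channel
sums over the mask. Whole-cell anisotropy is insensitive to eroding up to
20 px from the cell edge on uniform cells (guarded by a test), so edge
scattering artifacts do not drive the kinetics. Frame-to-frame changes
Δarea and Δr are stamped at the later frame; the "normalized" anisotropy
change divides Δr by the trace's full anisotropy range (a definition this
package fixes, recorded in output metadata; the raw Δr is also emitted).
Traces from several cells are aligned to each trace's peak Δarea (3-point
median smoothed, earliest tie) — the hallmark of the rapid-expansion (P1)
phase — and averaged in time bins with SEM. Kymographs sample intensity and
anisotropy along a 3-pixel-wide line per frame, averaging channels across
the width before applying the anisotropy formula.

## FCS model

Autocorrelation curves are fitted over lags 5·10⁻⁶–2 s to

    G(τ) = (1/N) · G_T(τ) · G_D(τ)
    G_T(τ) = 1 + (T/(1−T)) · exp(−τ/τ_T)
    G_D(τ) = f·(1+τ/τ_D1)⁻¹·(1+τ/(S²τ_D1))^(−1/2) + (1−f)·(1+τ/τ_D2)⁻¹

with `N` the mean particle number, `T`/`τ_T` the dark-state fraction and
lifetime, `f` the fast 3-D-diffusing fraction (free probe, τ_D1 bounded to
0.3–3 ms), `1−f` the slow 2-D pool (actin-bound probe, τ_D2 bounded to
10–200 ms; bounds relaxable), and `S` the structure factor (axial/lateral
detection-volume ratio). Free fits converge `S` to about 0.2, so it is
fixed there by default to constrain the parameter count. Amplitude identity:
`G(0⁺) = (1/N)·(1/(1−T))`.

Fitting is Levenberg–Marquardt least squares (lmfit), weighted by inverse
per-lag SD when the curve carries repeat SDs, otherwise unweighted on the
quasi-log grid. Initialization: `N = 1/G(first lag)`, `τ_T = 50 μs`,
`τ_D1 = 1 ms`, `τ_D2 = 45 ms`, `f = 0.5`, `T = 0.1`, overridable. The
ordering convention `τ_D1 < τ_D2` is enforced post-fit by component swap
(only reachable when bounds are relaxed; note the two components have
different functional forms, so a swap is flagged). Per-trace and averaged
fitting are both available (`average_curves`), since acquisition typically
yields several 10 s traces per cell.

The correlator is a multi-tau scheme, 16 lags per octave, covering one
dwell to a tenth of the trace duration; fluctuations are taken about each
binning level's mean and normalized by the squared trace mean. Trace QC
fails on linear drift exceeding 10% of the mean intensity over the trace,
or any 100 ms rolling mean exceeding mean + 5 SD (sporadic bursts);
thresholds configurable — the discard protocol is qualitative, so these
constants are package choices.

## Laurdan generalized polarization

Membrane lipid order is quantified per pixel as

    GP = (I_Ch1 − G·I_Ch2) / (I_Ch1 + G·I_Ch2)

from an ordered-phase channel Ch1 (435/40 nm) and disordered-phase channel
Ch2 (504/37 nm). The instrument factor is calibrated against Laurdan in
DMSO of conventional GP_ref = 0.207:

    G = (GP_ref + GP_ref·GP_mes − GP_mes − 1) / (GP_mes + GP_ref·GP_mes − GP_ref − 1)

where GP_mes is the reference GP measured at G = 1, taken here as the
intensity-weighted mean over the reference image (equivalently, GP of the
summed channels; the aggregation is a package choice). This calibration is
a closed-form inverse: re-applying the derived G to the same reference
returns GP_ref exactly, which the test suite asserts at 1e-12. ROI GP uses
summed channel intensities, mirroring the anisotropy convention.

## Blob segmentation and spatial correlation

Punctate structures (vinculin clusters, paxillin adhesions) are segmented
by Gaussian smoothing (σ = 1 px default), Otsu thresholding, and — when the
gradient filter is enabled — threshold refinement to the median smoothed
intensity over high-gradient pixels near the initial boundary (the gradient
magnitude peaks at the true object edge, placing the cut at the half-height
boundary; the original segmentation routine is unpublished, so this is a
re-specification). Thresholding decisions run on the min-max-normalized
image, making Otsu-mode segmentation exactly invariant to intensity
scaling. Holes are filled; components under 4 px dropped.

Nanopattern ROIs: pattern lines are located from the intensity dips they
imprint (column means below median − 2·MAD, with a depth-consistency filter
— a group must reach a quarter of the deepest dip — because at high SNR the
MAD floor alone admits shallow noise wiggles); 1×4 μm rectangles are
centered on lines (long axis along the line) and 2×2 μm squares at
inter-line midpoints. Line profiles perpendicular to the pattern are
max-normalized in the marker channel, aligned on their marker peak, and
averaged in equal-width distance bins (the protocol bins "by normalized
marker level" on the flanks without specifying spacing; a signed distance
axis with equal bins carries the same information and keeps left/right
flanks distinct). Cluster-centered 1×1 μm average images are oriented so
the pattern always lies left (mirror), marker crops max-normalized before
averaging, and anisotropy computed channel-first — average the raw `Ipa`
and corrected `Ipe` crops, then apply the formula, then a 3-pixel mean
filter — consistent with the photon-weighted convention.

## Synthetic data: what it does and does not emulate

Generators invert each analysis formula exactly: `Ipa = I(1+2r)/3`,
`Ipe = I(1−r)/3` (divided by the channel G-factor, optionally warped with
the inverse of a misalignment transform, offset by background), Laurdan
`I_Ch1 = I(1+gp)/2`, `I_Ch2 = I(1−gp)/(2G)`. Camera noise is Poisson shot
noise plus Gaussian read noise (σ = 2 ADU default) on 512×512 frames at
0.0977 μm/px. Noiseless round trips are machine-exact and identical seeds
give bit-identical artifacts (both guarded by tests).

The homoFRET photophysics is deliberately abstracted: nanoclusters are a
depolarized anisotropy value (`r_clust < r_mono`), not a photon-level
energy-transfer simulation, because every analysis operates purely on
channel intensities. Bleach series impose the linear mixing law
`r(I/I0) = r_mono − (r_mono − r_start)·I/I0` with per-frame intensity
retention β = 0.92 (30 frames reach I/I0 ≈ 0.09); spreading movies are a
disk whose area follows a logistic (maximal growth at t\*) and whose
anisotropy falls along a logistic leading t\* by 150 s; FCS curves are the
closed-form model with 1% multiplicative noise on a log-spaced grid at
multi-tau density (~16 points/octave over 5·10⁻⁶–2 s), with the per-lag SD
attached so the fitter's weighted route is exercised; blinking traces are a
two-state telegraph emitter with Poisson counting, whose closed-form ACF
`((1−p)/p)·exp(−τ(k_on+k_off))` serves as an independent oracle.

Consequently, passing tests demonstrate estimator correctness and
calibration identities under the stated noise model — they do not
demonstrate robustness to real-cell nuisances (membrane topography,
endosomal structures, TIRF scattering halos, focus drift), which the
protocols handle by ROI placement and edge exclusion. Cell-derived absolute
numbers (anisotropy differences between adhesion conditions, SLB diffusion
constants, GP differences between mutant lines) depend on raw microscope
data and are outside what synthetic scenes can certify.

## Problem sizes and numerical tolerances

Default test scenes use 32–256 px frames; the photobleach recovery uses
30-frame 256×256 series with ten 20×20 px ROIs over 10 seeds, and FCS
recovery 20–50 curves of ~300 lag points — sizes chosen so the full suite
runs in well under a minute while leaving estimator standard errors far
below the asserted tolerances. Anisotropy/GP round trips assert 1e-12
(double precision through linear formulas); registration recovery 0.2 px /
0.1°; noisy recoveries assert the tolerances stated alongside each test.
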