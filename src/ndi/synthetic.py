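"""Ground-truthed synthetic inputs for every analysis stage.

Each generator is the exact forward inverse of its analysis formula in the
noiseless limit: polarized channels are built from a chosen anisotropy field
via Ipa = I(1+2r)/3, Ipe = I(1-r)/3 (then divided by the channel G-factor,
optionally misaligned, offset by background, and degraded with Poisson shot
noise and Gaussian read noise); Laurdan channels invert the GP formula; FCS
curves come from the closed-form model, and blinking traces from a two-state
telegraph emitter whose autocorrelation is known in closed form.

The homoFRET photophysics is deliberately abstracted: nanoclusters are
represented by a depolarized anisotropy (r_clust < r_mono) rather than
simulated photon-by-photon, because every analysis here operates purely on
channel intensities. Every generator returns its :class:`SceneTruth` and is
bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ndi.fcs import ACFCurve, FCSParams, IntensityTrace, model_eval
from ndi.polarimetry import DEFAULT_PIXEL_SIZE_UM, AffineTransform, PolarizedImageSet
from ndi.spatial import PatternLayout

#: default camera read noise, ADU rms
DEFAULT_READ_NOISE = 2.0
#: default frame geometry (EMCCD field, ~50 x 50 um at 100x)
DEFAULT_SHAPE = (512, 512)


@dataclass
class SceneTruth:
    """Ground-truth record accompanying every simulated input."""

    kind: str
    seed: int | None
    params: dict = field(default_factory=dict)
    arrays: dict = field(default_factory=dict)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _camera(
    ideal: np.ndarray,
    rng: np.random.Generator | None,
    background: float = 0.0,
    read_noise_sd: float = DEFAULT_READ_NOISE,
) -> np.ndarray:
    """Photon-to-ADU conversion: offset, shot noise, Gaussian read noise."""
    img = np.asarray(ideal, dtype=float) + background
    if rng is None:
        return img
    img = rng.poisson(np.clip(img, 0, None)).astype(float)
    return img + rng.normal(0.0, read_noise_sd, size=img.shape)


def channels_from_anisotropy(
    r: np.ndarray | float, intensity: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the anisotropy formula: total intensity + r -> (Ipa, Ipe)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= -0.5) or np.any(r >= 1.0):
        raise ValueError("true anisotropy must lie in (-0.5, 1)")
    intensity = np.asarray(intensity, dtype=float)
    return intensity * (1 + 2 * r) / 3.0, intensity * (1 - r) / 3.0


def make_polarized_scene(
    r_field: np.ndarray | float,
    intensity: np.ndarray | float,
    shape: tuple[int, int] | None = None,
    gfactor: np.ndarray | float = 1.0,
    misalignment: AffineTransform | None = None,
    background: float = 0.0,
    noise: bool = True,
    read_noise_sd: float = DEFAULT_READ_NOISE,
    seed: int | None = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval: float = 0.0,
) -> tuple[PolarizedImageSet, SceneTruth]:
    """Render a single polarized frame pair from a true anisotropy field.

    The perpendicular channel is divided by ``gfactor`` (the pipeline's
    G-factor correction multiplies it back) and, when ``misalignment`` is
    given, warped with its inverse so that applying the transform re-aligns
    the channels. Scalars broadcast over ``shape``.
    """
    if shape is not None:
        r_field = np.broadcast_to(np.asarray(r_field, dtype=float), shape).copy()
        intensity = np.broadcast_to(np.asarray(intensity, dtype=float), shape).copy()
    r_field = np.asarray(r_field, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    ipa, ipe = channels_from_anisotropy(r_field, intensity)
    ipe = ipe / np.asarray(gfactor, dtype=float)
    if misalignment is not None:
        ipe = misalignment.inverse().warp(ipe)
    rng = np.random.default_rng(seed) if noise else None
    ipa_n = _camera(ipa, rng, background, read_noise_sd)
    ipe_n = _camera(ipe, rng, background, read_noise_sd)
    pset = PolarizedImageSet(
        ipa=ipa_n,
        ipe=ipe_n,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        background_ipa=background,
        background_ipe=background,
    )
    truth = SceneTruth(
        kind="polarized_scene",
        seed=seed if noise else None,
        params=dict(
            gfactor=gfactor if np.ndim(gfactor) == 0 else "field",
            background=background,
            read_noise_sd=read_noise_sd,
            noise=noise,
            pixel_size=pixel_size,
        ),
        arrays=dict(r=r_field, intensity=intensity),
    )
    return pset, truth


def speckle_image(
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    smooth_sigma: float = 3.0,
    base: float = 100.0,
    amplitude: float = 80.0,
) -> np.ndarray:
    """Smooth random speckle, a generic registration/segmentation test field."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.normal(size=shape), smooth_sigma)
    img = (img - img.min()) / np.ptp(img)
    return base + amplitude * img


def make_bleach_series(
    n_frames: int = 30,
    r_start: float = 0.19,
    r_mono: float = 0.23,
    beta: float = 0.92,
    intensity0: float = 600.0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    background: float = 0.0,
    noise: bool = True,
    read_noise_sd: float = DEFAULT_READ_NOISE,
    seed: int | None = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval: float = 0.2,
) -> tuple[PolarizedImageSet, SceneTruth]:
    """Photobleaching series with the homoFRET signature.

    Frame k keeps the fraction beta**k of the initial intensity and its
    anisotropy follows the linear mixing law

        r(i_rel) = r_mono - (r_mono - r_start) * i_rel

    so a clustered membrane (r_start < r_mono) rises linearly toward the
    monomer anisotropy as bleaching dilutes the clusters, and a monomer-only
    membrane (r_start = r_mono) stays flat.
    """
    rng = np.random.default_rng(seed) if noise else None
    i_rel = beta ** np.arange(n_frames)
    r_true = r_mono - (r_mono - r_start) * i_rel
    ipa_frames, ipe_frames = [], []
    for k in range(n_frames):
        ipa, ipe = channels_from_anisotropy(
            np.full(shape, r_true[k]), np.full(shape, intensity0 * i_rel[k])
        )
        ipa_frames.append(_camera(ipa, rng, background, read_noise_sd))
        ipe_frames.append(_camera(ipe, rng, background, read_noise_sd))
    pset = PolarizedImageSet(
        ipa=np.stack(ipa_frames),
        ipe=np.stack(ipe_frames),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        background_ipa=background,
        background_ipe=background,
    )
    truth = SceneTruth(
        kind="bleach_series",
        seed=seed if noise else None,
        params=dict(
            r_start=r_start, r_mono=r_mono, beta=beta, intensity0=intensity0,
            background=background, read_noise_sd=read_noise_sd,
        ),
        arrays=dict(i_rel=i_rel, r=r_true),
    )
    return pset, truth


def make_fcs_curve(
    params: FCSParams,
    noise_sd: float = 0.01,
    seed: int | None = 0,
    lags: np.ndarray | None = None,
) -> tuple[ACFCurve, SceneTruth]:
    """Model autocorrelation with multiplicative Gaussian noise.

    Default lags: log-spaced points spanning 5e-6 to 2 s (the fitted lag
    window) at the density of a 16-lags-per-octave multi-tau correlator
    (about 300 points over the ~18.6 octaves). ``noise_sd`` scales each
    point's Gaussian perturbation relative to its value (heteroscedastic, as
    real correlator noise roughly is), and the per-lag SD is attached to the
    curve.
    """
    if lags is None:
        n_pts = int(round(16 * np.log2(2.0 / 5e-6)))
        lags = np.logspace(np.log10(5e-6), np.log10(2.0), n_pts)
    g = model_eval(params, lags)
    sd = None
    if noise_sd > 0 and seed is not None:
        rng = np.random.default_rng(seed)
        sd = noise_sd * np.abs(g)
        g = g * (1.0 + noise_sd * rng.standard_normal(g.shape))
    curve = ACFCurve(lags=lags, g=g, sd=sd)
    truth = SceneTruth(
        kind="fcs_curve", seed=seed, params=dict(noise_sd=noise_sd, **params.as_dict())
    )
    return curve, truth


def make_blinking_trace(
    k_on: float = 500.0,
    k_off: float = 500.0,
    rate: float = 2e5,
    dwell: float = 1e-5,
    duration: float = 10.0,
    seed: int | None = 0,
) -> tuple[IntensityTrace, SceneTruth]:
    """Two-state telegraph emitter with Poisson photon counting.

    The emitter switches off->on at rate ``k_on`` and on->off at ``k_off``
    (1/s); while on it emits ``rate`` photons/s, counted in ``dwell``-second
    bins over a 10 s trace by default. The closed-form autocorrelation is
    G(tau) = ((1-p)/p) exp(-tau (k_on + k_off)) with p = k_on/(k_on+k_off).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration / dwell))
    state = np.zeros(n, dtype=bool)
    p_on = k_on / (k_on + k_off)
    t = 0.0
    on = bool(rng.random() < p_on)
    while t < duration:
        sojourn = rng.exponential(1.0 / (k_off if on else k_on))
        if on:
            i0 = int(t / dwell)
            i1 = min(n, int(np.ceil((t + sojourn) / dwell)))
            state[i0:i1] = True
        t += sojourn
        on = not on
    counts = rng.poisson(rate * dwell * state)
    trace = IntensityTrace(counts=counts.astype(float), dwell=dwell)
    truth = SceneTruth(
        kind="blinking_trace",
        seed=seed,
        params=dict(
            k_on=k_on, k_off=k_off, rate=rate, dwell=dwell, duration=duration,
            p_on=p_on, acf_amplitude=(1 - p_on) / p_on, acf_tau=1.0 / (k_on + k_off),
        ),
    )
    return trace, truth


def make_gp_scene(
    gp_field: np.ndarray | float,
    intensity: np.ndarray | float,
    shape: tuple[int, int] | None = None,
    gfactor: float = 1.0,
    background: float = 0.0,
    noise: bool = True,
    read_noise_sd: float = DEFAULT_READ_NOISE,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Two-channel Laurdan images of known GP.

    Inverts the GP formula: ICh1 = I(1+gp)/2, ICh2 = I(1-gp)/(2 G), so
    recomputing GP with the same G returns the field exactly (noiseless).
    """
    if shape is not None:
        gp_field = np.broadcast_to(np.asarray(gp_field, dtype=float), shape).copy()
        intensity = np.broadcast_to(np.asarray(intensity, dtype=float), shape).copy()
    gp = np.asarray(gp_field, dtype=float)
    if np.any(np.abs(gp) >= 1):
        raise ValueError("true GP must lie in (-1, 1)")
    intensity = np.asarray(intensity, dtype=float)
    ch1 = intensity * (1 + gp) / 2.0
    ch2 = intensity * (1 - gp) / (2.0 * gfactor)
    rng = np.random.default_rng(seed) if noise else None
    ch1 = _camera(ch1, rng, background, read_noise_sd)
    ch2 = _camera(ch2, rng, background, read_noise_sd)
    truth = SceneTruth(
        kind="gp_scene",
        seed=seed if noise else None,
        params=dict(gfactor=gfactor, background=background, read_noise_sd=read_noise_sd),
        arrays=dict(gp=gp, intensity=intensity),
    )
    return ch1, ch2, truth


def make_pattern_scene(
    shape: tuple[int, int] = (200, 240),
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    spacing_um: float = 2.0,
    dip_depth: float = 0.5,
    dip_width_px: int = 2,
    n_clusters_per_line: int = 4,
    cluster_offset_px: int = 4,
    cluster_sigma_px: float = 1.5,
    cluster_amplitude: float = 400.0,
    base_intensity: float = 300.0,
    r_out: float = 0.21,
    r_contrast: float = 0.05,
    influence_radius_um: float = 0.5,
    noise: bool = True,
    read_noise_sd: float = DEFAULT_READ_NOISE,
    seed: int | None = 0,
) -> tuple[np.ndarray, PolarizedImageSet, PatternLayout, SceneTruth]:
    """Nanopattern scene: vertical dip lines, flanking marker clusters, and a
    polarized image pair whose anisotropy is lowered near the clusters.

    The GPI intensity dips by ``dip_depth`` on the chromium lines (the proxy
    used to locate them); marker (vinculin-like) Gaussian clusters sit
    ``cluster_offset_px`` to alternating sides of each line; the anisotropy
    field equals ``r_out`` except within ``influence_radius_um`` of a cluster
    center, where it is lowered by ``r_contrast`` (extending ~0.5 um around
    clusters by default).
    """
    h, w = shape
    spacing_px = spacing_um / pixel_size
    cols = np.arange(spacing_px, w - spacing_px / 2, spacing_px)
    intensity = np.full(shape, base_intensity)
    for c in cols:
        c0 = int(round(c))
        intensity[:, max(0, c0 - dip_width_px // 2) : c0 + dip_width_px - dip_width_px // 2] *= (
            1 - dip_depth
        )
    rng = np.random.default_rng(seed)
    marker = np.full(shape, 20.0)
    rows_grid = np.linspace(h * 0.15, h * 0.85, n_clusters_per_line)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = []
    for li, c in enumerate(cols):
        for ci, rr in enumerate(rows_grid):
            side = 1 if (li + ci) % 2 == 0 else -1
            cy = rr + rng.uniform(-2, 2)
            cx = c + side * cluster_offset_px
            centers.append((cy, cx))
            marker += cluster_amplitude * np.exp(
                -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * cluster_sigma_px**2))
            )
    r_field = np.full(shape, r_out)
    rad_px = influence_radius_um / pixel_size
    for cy, cx in centers:
        r_field[(yy - cy) ** 2 + (xx - cx) ** 2 <= rad_px**2] = r_out - r_contrast
    pset, _ = make_polarized_scene(
        r_field, intensity, noise=noise, read_noise_sd=read_noise_sd,
        seed=None if seed is None else seed + 1, pixel_size=pixel_size,
    )
    if noise:
        marker = _camera(marker, rng, 0.0, read_noise_sd)
    layout = PatternLayout(
        line_positions=cols, orientation="vertical", spacing_um=spacing_um
    )
    truth = SceneTruth(
        kind="pattern_scene",
        seed=seed,
        params=dict(
            r_out=r_out, r_contrast=r_contrast, influence_radius_um=influence_radius_um,
            spacing_um=spacing_um, dip_depth=dip_depth, pixel_size=pixel_size,
        ),
        arrays=dict(r=r_field, line_columns=cols, cluster_centers=np.array(centers)),
    )
    return marker, pset, layout, truth


def make_spreading_movie(
    n_frames: int = 40,
    frame_interval: float = 15.0,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    area_min_um2: float = 50.0,
    area_max_um2: float = 400.0,
    t_peak: float = 300.0,
    area_tau: float = 40.0,
    r_high: float = 0.21,
    r_low: float = 0.17,
    drop_lead: float = 150.0,
    r_tau: float = 40.0,
    intensity: float = 500.0,
    background: float = 0.0,
    noise: bool = True,
    read_noise_sd: float = DEFAULT_READ_NOISE,
    seed: int | None = 0,
) -> tuple[PolarizedImageSet, SceneTruth]:
    """Spreading movie: a disk cell with sigmoidal area growth and an
    anisotropy drop leading the area-change peak.

    The cell area follows a logistic curve with maximal growth at ``t_peak``
    (the P1 expansion peak); the whole-cell anisotropy follows a falling
    logistic whose steepest descent sits ``drop_lead`` seconds earlier
    (default 150 s), reproducing the nanocluster burst that precedes peak
    expansion.
    """
    rng = np.random.default_rng(seed) if noise else None
    t = np.arange(n_frames) * frame_interval
    area_t = area_min_um2 + (area_max_um2 - area_min_um2) * _sigmoid((t - t_peak) / area_tau)
    r_t = r_high - (r_high - r_low) * _sigmoid((t - (t_peak - drop_lead)) / r_tau)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ipa_frames, ipe_frames = [], []
    for k in range(n_frames):
        radius_px = np.sqrt(area_t[k] / np.pi) / pixel_size
        cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        ipa, ipe = channels_from_anisotropy(
            np.full(shape, r_t[k]), intensity * cell.astype(float)
        )
        ipa_frames.append(_camera(ipa, rng, background, read_noise_sd))
        ipe_frames.append(_camera(ipe, rng, background, read_noise_sd))
    pset = PolarizedImageSet(
        ipa=np.stack(ipa_frames),
        ipe=np.stack(ipe_frames),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        background_ipa=background,
        background_ipe=background,
    )
    truth = SceneTruth(
        kind="spreading_movie",
        seed=seed if noise else None,
        params=dict(
            t_peak=t_peak, drop_lead=drop_lead, area_tau=area_tau, r_tau=r_tau,
            r_high=r_high, r_low=r_low, area_min_um2=area_min_um2,
            area_max_um2=area_max_um2, frame_interval=frame_interval,
        ),
        arrays=dict(t=t, area=area_t, r=r_t),
    )
    return pset, truth
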