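"""Higher-level homoFRET analyses on calibrated anisotropy data.

Photobleaching nanocluster curves: bleaching dilutes clusters into effective
monomers, so with nanoclusters present the ROI anisotropy rises linearly as
intensity falls; extrapolating r versus I/I0 to I/I0 = 0 estimates the
monomer limiting anisotropy (~0.23 for YFP-tagged GPI-anchored proteins),
while a monomer-only membrane stays flat.

Cell-spreading kinetics: whole-cell anisotropy and segmented area per frame,
their frame-to-frame changes, and alignment of several cells to the peak
area change (the hallmark of the rapid-expansion P1 phase).

Kymographs: intensity and anisotropy along a 3-pixel line versus time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import medfilt
from skimage import filters, measure

from ndi.polarimetry import (
    GFactorField,
    PolarizedImageSet,
    Region,
    anisotropy_from_sums,
)

logger = logging.getLogger(__name__)


@dataclass
class BleachCurve:
    """Binned anisotropy-vs-I/I0 curve with its linear extrapolation.

    The fit is r = slope * (1 - i_rel) + intercept on bin means, so the
    intercept is the pre-bleach anisotropy and ``asymptote`` = slope +
    intercept is the extrapolated monomer anisotropy at I/I0 -> 0.
    """

    bin_centers: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    count: np.ndarray
    slope: float
    intercept: float
    asymptote: float
    trajectories: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SpreadingTrace:
    """Per-frame whole-cell area and anisotropy with frame-to-frame changes."""

    t: np.ndarray  # s
    area: np.ndarray  # um^2, NaN on failed frames
    r: np.ndarray
    d_area: np.ndarray  # area[k+1] - area[k], stamped at t[k+1]
    d_r: np.ndarray
    d_r_norm: np.ndarray  # d_r / (max r - min r) of this trace
    alignment_offset: float = 0.0

    @property
    def d_t(self) -> np.ndarray:
        return self.t[1:]


@dataclass
class Kymograph:
    """Line-scan intensity and anisotropy stacked over time (position x time)."""

    intensity: np.ndarray
    r: np.ndarray
    times: np.ndarray
    truncated: bool = False


def bleach_analysis(
    series: PolarizedImageSet,
    g: GFactorField | float,
    regions: Sequence[Region],
    n_bins: int = 10,
    fit_range: tuple[float, float] = (0.2, 1.0),
) -> BleachCurve:
    """Photobleaching homoFRET analysis over ROIs of a registered time series.

    Per ROI and frame the photon-weighted anisotropy and total intensity are
    computed from summed channel intensities; intensities are normalized to
    the ROI's first (un-bleached) frame so (I/I0, r) pairs pool across ROIs
    and cells. Pairs are binned in ``n_bins`` equal-width I/I0 bins over
    (0, 1]; an ordinary least-squares line r = a(1 - I/I0) + r0 is fitted to
    bin means whose centers fall in ``fit_range`` and extrapolated to
    I/I0 = 0. ROIs whose first-frame intensity is not positive are dropped.
    """
    if series.n_frames < 2:
        raise ValueError("bleach analysis needs at least 2 frames")
    gf = g if isinstance(g, GFactorField) else GFactorField(g=g)
    shape = series.frame_shape
    recs = []
    for i, reg in enumerate(regions):
        mask = reg.to_mask(shape)
        if not mask.any():
            logger.warning("ROI %s empty; dropped", reg.label or i)
            continue
        ipa_sums = series.ipa[:, mask].sum(axis=1)
        ipe_sums = gf.correct(series.ipe)[:, mask].sum(axis=1)
        total = ipa_sums + 2 * ipe_sums
        if total[0] <= 0:
            logger.warning("ROI %s has non-positive first-frame intensity; dropped", reg.label or i)
            continue
        for k in range(series.n_frames):
            recs.append(
                dict(
                    roi=reg.label or f"roi_{i}",
                    frame=k,
                    t=k * series.frame_interval,
                    i_rel=total[k] / total[0],
                    r=anisotropy_from_sums(ipa_sums[k], ipe_sums[k]),
                )
            )
    traj = pd.DataFrame(recs)
    if traj.empty:
        raise ValueError("no usable ROI")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    x = traj["i_rel"].to_numpy()
    r = traj["r"].to_numpy()
    keep = (x > 0) & (x <= 1.0) & np.isfinite(r)
    idx = np.clip(np.digitize(x[keep], edges, right=True), 1, n_bins) - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean_r = np.full(n_bins, np.nan)
    sd_r = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        count[b] = sel.sum()
        if count[b]:
            mean_r[b] = r[keep][sel].mean()
            sd_r[b] = r[keep][sel].std()
    fit_sel = (count > 0) & (centers >= fit_range[0]) & (centers <= fit_range[1])
    if fit_sel.sum() < 2:
        raise ValueError("too few populated bins in the fit range")
    a, r0 = np.polyfit(1.0 - centers[fit_sel], mean_r[fit_sel], 1)
    return BleachCurve(
        bin_centers=centers,
        mean_r=mean_r,
        sd_r=sd_r,
        count=count,
        slope=float(a),
        intercept=float(r0),
        asymptote=float(a + r0),
        trajectories=traj,
    )


def segment_cell(
    total_intensity: np.ndarray,
    threshold: float | None = None,
    edge_erosion_px: int = 0,
    pixel_size: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Segment the cell as the largest above-threshold connected component.

    ``threshold`` defaults to Otsu. ``edge_erosion_px`` morphologically
    erodes the mask before statistics (edge-pixel exclusion; whole-cell
    anisotropy is insensitive to 0-20 px of erosion on uniform cells). The
    area (um^2) is reported for the un-eroded cell mask.
    """
    img = np.asarray(total_intensity, dtype=float)
    thr = filters.threshold_otsu(img) if threshold is None else threshold
    mask = img > thr
    if not mask.any():
        raise ValueError(f"empty segmentation at threshold {thr:.4g} (image max {img.max():.4g})")
    labels, _ = ndimage.label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    cell = labels == largest
    area = float(cell.sum()) * pixel_size**2
    if edge_erosion_px > 0:
        cell = ndimage.binary_erosion(cell, iterations=edge_erosion_px)
    return cell, area


def spreading_kinetics(
    series: PolarizedImageSet,
    g: GFactorField | float,
    threshold: float | None = None,
    edge_erosion_px: int = 0,
) -> SpreadingTrace:
    """Whole-cell area and anisotropy per frame of a spreading movie.

    Each frame's total-intensity image is thresholded and the largest
    component taken as the cell; the whole-cell anisotropy comes from the
    channel intensities summed over the (optionally edge-eroded) mask.
    Frames where segmentation fails get NaN and the trace continues. The
    normalized anisotropy change divides the frame-to-frame change by the
    trace's full anisotropy range (recorded in ``d_r_norm``).
    """
    gf = g if isinstance(g, GFactorField) else GFactorField(g=g)
    n = series.n_frames
    area = np.full(n, np.nan)
    r = np.full(n, np.nan)
    ipe_c = gf.correct(series.ipe)
    for k in range(n):
        total = series.ipa[k] + 2 * ipe_c[k]
        try:
            cell, area_k = segment_cell(
                total, threshold=threshold, edge_erosion_px=edge_erosion_px,
                pixel_size=series.pixel_size,
            )
        except ValueError:
            logger.warning("segmentation failed on frame %d", k)
            continue
        area[k] = area_k
        r[k] = anisotropy_from_sums(
            float(series.ipa[k][cell].sum()), float(ipe_c[k][cell].sum())
        )
    d_area = np.diff(area)
    d_r = np.diff(r)
    r_range = np.nanmax(r) - np.nanmin(r)
    d_r_norm = d_r / r_range if r_range > 0 else np.zeros_like(d_r)
    return SpreadingTrace(
        t=series.times, area=area, r=r, d_area=d_area, d_r=d_r, d_r_norm=d_r_norm
    )


def peak_time(trace: SpreadingTrace) -> float:
    """Time of the peak area change (3-point median smoothed, earliest tie)."""
    d = trace.d_area.copy()
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("trace has no finite area change")
    d_f = np.where(finite, d, np.nanmin(d[finite]))
    sm = medfilt(d_f, kernel_size=3) if d_f.size >= 3 else d_f
    return float(trace.d_t[int(np.argmax(sm))])


def align_traces(
    traces: Sequence[SpreadingTrace], bin_width: float
) -> pd.DataFrame:
    """Average several spreading traces after aligning their peak area change.

    Each trace is shifted so its peak area-change time sits at t = 0; the
    pooled frame-to-frame changes are then averaged in ``bin_width``-second
    bins (mean and SEM per bin). Traces with no finite area change are
    excluded and logged.
    """
    used = []
    for i, tr in enumerate(traces):
        try:
            tp = peak_time(tr)
        except ValueError:
            logger.warning("trace %d excluded: no finite area change", i)
            continue
        tr.alignment_offset = -tp
        used.append((tr, tp))
    if not used:
        raise ValueError("no alignable trace")
    t_all, da_all, drn_all = [], [], []
    for tr, tp in used:
        t_all.append(tr.d_t - tp)
        da_all.append(tr.d_area)
        drn_all.append(tr.d_r_norm)
    t = np.concatenate(t_all)
    da = np.concatenate(da_all)
    drn = np.concatenate(drn_all)
    # bin grid centered on 0 so the aligned peaks share the t = 0 bin
    lo = np.floor(t.min() / bin_width - 0.5)
    hi = np.ceil(t.max() / bin_width + 0.5)
    edges = (np.arange(lo, hi + 1) + 0.5) * bin_width
    idx = np.digitize(t, edges)
    rows = []
    for b in range(1, len(edges)):
        sel = (idx == b) & np.isfinite(da)
        if not sel.any():
            continue
        nb = int(sel.sum())
        sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        rows.append(
            dict(
                t_center=0.5 * (edges[b - 1] + edges[b]),
                mean_d_area=float(np.mean(da[sel])),
                sem_d_area=sem(da[sel]),
                mean_d_r_norm=float(np.nanmean(drn[sel])),
                sem_d_r_norm=sem(drn[sel][np.isfinite(drn[sel])]),
                n=nb,
            )
        )
    return pd.DataFrame(rows)


def kymograph(
    series: PolarizedImageSet, g: GFactorField | float, line: Region
) -> Kymograph:
    """Intensity and anisotropy kymograph along a (typically 3-pixel) line.

    Channel intensities are sampled along the line, averaged across its
    width, and stacked over frames; anisotropy comes from the averaged
    channel profiles. A line partially outside the image is truncated to the
    in-bounds segment with a warning.
    """
    if line.kind != "line":
        raise ValueError("kymograph requires a line region")
    gf = g if isinstance(g, GFactorField) else GFactorField(g=g)
    h, w = series.frame_shape
    (r0, c0), (r1, c1) = line.geometry
    truncated = False
    pts = np.linspace([r0, c0], [r1, c1], int(max(abs(r1 - r0), abs(c1 - c0))) + 1)
    inside = (pts[:, 0] >= 0) & (pts[:, 0] <= h - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= w - 1)
    if not inside.all():
        if not inside.any():
            raise ValueError("line entirely outside the image")
        pts = pts[inside]
        truncated = True
        logger.warning("kymograph line truncated to image bounds")
        (r0, c0), (r1, c1) = pts[0], pts[-1]
    inten_rows, r_rows = [], []
    ipe_c = gf.correct(series.ipe)
    for k in range(series.n_frames):
        pa = measure.profile_line(
            series.ipa[k], (r0, c0), (r1, c1), linewidth=line.width,
            mode="constant", reduce_func=np.mean,
        )
        pe = measure.profile_line(
            ipe_c[k], (r0, c0), (r1, c1), linewidth=line.width,
            mode="constant", reduce_func=np.mean,
        )
        total = pa + 2 * pe
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.where(total > 0, (pa - pe) / total, np.nan)
        inten_rows.append(total)
        r_rows.append(rr)
    return Kymograph(
        intensity=np.array(inten_rows).T,
        r=np.array(r_rows).T,
        times=series.times,
        truncated=truncated,
    )
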