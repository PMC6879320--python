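"""Calibrated emission-anisotropy maps from two-channel polarized image stacks.

The measurement model: a fluorophore excited with polarized light is imaged
simultaneously in a channel parallel (``Ipa``) and perpendicular (``Ipe``) to
the excitation polarization. After background subtraction, channel
registration and G-factor correction of the perpendicular channel, the
steady-state emission anisotropy per pixel is

    r = (Ipa - Ipe') / (Ipa + 2 Ipe'),        Ipe' = g * Ipe

where ``g`` is the pixelwise detection-sensitivity ratio measured on an
isotropic dye solution (fluorescein in water). Lower ``r`` indicates more
homoFRET, i.e. more nanoscale clustering of like fluorophores.

ROI-level anisotropies are photon-weighted: channel intensities are summed
over the region first and the anisotropy formula applied to the sums, mirroring
how intensities extracted from ~2x2 um membrane ROIs are combined.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.draw import polygon as _sk_polygon
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

#: default pixel size, um/px (512 px across ~50 um at 100x magnification)
DEFAULT_PIXEL_SIZE_UM = 50.0 / 512.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """2-D affine map in pull (output -> input) convention, pixel units.

    ``matrix`` is the 2x2 linear part acting on (row, col) coordinates and
    ``offset`` the translation; a warped image samples the source at
    ``matrix @ x + offset``.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    warning: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_similarity(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation: Sequence[float] = (0.0, 0.0),
        center: Sequence[float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Build rotation+scale about ``center`` followed by ``translation``.

        ``translation`` is the apparent shift of the image content, i.e. a
        warp with translation (3, -2) makes content that sat at (0, 0) appear
        at (3, -2); the pull offset carries the opposite sign internally.
        """
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        mat = rot / scale
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float)
        offset = c - mat @ c - mat @ t
        return cls(matrix=mat, offset=offset)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.matrix, np.eye(2)) and np.allclose(self.offset, 0.0)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(matrix=inv, offset=-inv @ self.offset)

    def warp(self, image: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Apply to a single 2-D frame (bilinear by default, zero fill)."""
        if self.is_identity:
            return np.array(image, dtype=float, copy=True)
        return ndimage.affine_transform(
            np.asarray(image, dtype=float), self.matrix, self.offset, order=order, cval=cval
        )


@dataclass
class PolarizedImageSet:
    """Paired parallel/perpendicular image stacks with calibration metadata.

    Stacks are stored as float arrays of shape ``(n_frames, h, w)``; 2-D
    inputs are promoted to a single frame. Backgrounds may be scalars or
    images of the frame shape.
    """

    ipa: np.ndarray
    ipe: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = 0.0
    background_ipa: float | np.ndarray = 0.0
    background_ipe: float | np.ndarray = 0.0
    registration: AffineTransform = field(default_factory=AffineTransform.identity)

    def __post_init__(self) -> None:
        self.ipa = _as_stack(self.ipa)
        self.ipe = _as_stack(self.ipe)
        if self.ipa.shape != self.ipe.shape:
            raise ValueError(
                f"ipa/ipe shape mismatch: {self.ipa.shape} vs {self.ipe.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval < 0:
            raise ValueError("frame_interval must be >= 0")
        for name in ("background_ipa", "background_ipe"):
            bg = getattr(self, name)
            if np.ndim(bg) not in (0, 2):
                raise ValueError(f"{name} must be scalar or a 2-D image")
            if np.ndim(bg) == 2 and np.shape(bg) != self.frame_shape:
                raise ValueError(
                    f"{name} shape {np.shape(bg)} does not match frames {self.frame_shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.ipa.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.ipa.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def replace(self, **kw) -> "PolarizedImageSet":
        return dataclasses.replace(self, **kw)


def _as_stack(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 2:
        a = a[None]
    if a.ndim != 3:
        raise ValueError("image stacks must be 2-D or 3-D arrays")
    return a


@dataclass
class GFactorField:
    """Per-pixel (or scalar) Ipa/Ipe sensitivity ratio of the two channels."""

    g: float | np.ndarray
    flagged: np.ndarray | None = None  # pixels imputed at the dark-pixel floor

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if not np.all(np.isfinite(g)) or not np.all(g > 0):
            raise ValueError("G-factor must be finite and strictly positive")
        self.g = float(g) if g.ndim == 0 else g

    def correct(self, ipe: np.ndarray) -> np.ndarray:
        """Return the G-factor corrected perpendicular channel g * Ipe."""
        return np.asarray(ipe, dtype=float) * self.g


@dataclass
class AnisotropyMap:
    """Pixelwise anisotropy with its intensity mask.

    ``r`` is NaN exactly where ``mask`` is false. ``r_raw`` is the unsmoothed
    field; ``r`` carries the optional rendering filter. Quantification must
    read ``r_raw`` (or better, recompute from summed channel intensities).
    """

    r: np.ndarray
    r_raw: np.ndarray
    total_intensity: np.ndarray
    mask: np.ndarray
    smoothing_window: int = 1


@dataclass
class Region:
    """A quantification region: rectangle, line, polygon or label mask.

    Coordinates are 0-based (row, col) pixels; rectangles are half-open
    ``(row0, col0, height, width)``. Lines carry a ``width`` in pixels
    (averaged across, as for 3-pixel kymograph lines).
    """

    kind: str
    geometry: object
    label: str = ""
    width: int = 1

    @classmethod
    def rectangle(cls, row0: int, col0: int, height: int, width: int, label: str = "") -> "Region":
        if height < 1 or width < 1:
            raise ValueError("rectangle height/width must be >= 1 pixel")
        return cls("rectangle", (int(row0), int(col0), int(height), int(width)), label)

    @classmethod
    def line(cls, start, end, width: int = 1, label: str = "") -> "Region":
        return cls("line", (tuple(start), tuple(end)), label, width=int(width))

    @classmethod
    def polygon(cls, vertices, label: str = "") -> "Region":
        return cls("polygon", [tuple(v) for v in vertices], label)

    @classmethod
    def from_mask(cls, mask: np.ndarray, label: str = "") -> "Region":
        return cls("label-mask", np.asarray(mask, dtype=bool), label)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        if self.kind == "rectangle":
            r0, c0, h, w = self.geometry
            if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
                raise ValueError(f"rectangle {self.geometry} outside image bounds {shape}")
            out[r0 : r0 + h, c0 : c0 + w] = True
        elif self.kind == "polygon":
            rr, cc = _sk_polygon(
                [v[0] for v in self.geometry], [v[1] for v in self.geometry], shape
            )
            out[rr, cc] = True
        elif self.kind == "label-mask":
            if self.geometry.shape != shape:
                raise ValueError("label-mask shape does not match image")
            out = self.geometry.copy()
        elif self.kind == "line":
            (r0, c0), (r1, c1) = self.geometry
            n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
            rr = np.round(np.linspace(r0, r1, n)).astype(int)
            cc = np.round(np.linspace(c0, c1, n)).astype(int)
            half = self.width // 2
            # widen perpendicular to the dominant axis
            if abs(r1 - r0) >= abs(c1 - c0):
                for d in range(-half, self.width - half):
                    sel = (cc + d >= 0) & (cc + d < shape[1]) & (rr >= 0) & (rr < shape[0])
                    out[rr[sel], cc[sel] + d] = True
            else:
                for d in range(-half, self.width - half):
                    sel = (rr + d >= 0) & (rr + d < shape[0]) & (cc >= 0) & (cc < shape[1])
                    out[rr[sel] + d, cc[sel]] = True
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def subtract_background(pset: PolarizedImageSet) -> PolarizedImageSet:
    """Remove the stored backgrounds pixelwise, clipping negatives to zero.

    Idempotent in the sense that the returned set carries zero backgrounds,
    so applying it again is a no-op.
    """
    ipa = np.clip(pset.ipa - np.asarray(pset.background_ipa, dtype=float), 0.0, None)
    ipe = np.clip(pset.ipe - np.asarray(pset.background_ipe, dtype=float), 0.0, None)
    return pset.replace(ipa=ipa, ipe=ipe, background_ipa=0.0, background_ipe=0.0)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _crop_margin(img: np.ndarray, frac: float = 0.1) -> np.ndarray:
    mr = max(1, int(img.shape[0] * frac))
    mc = max(1, int(img.shape[1] * frac))
    return img[mr:-mr, mc:-mc]


def estimate_registration(
    ref_ipa: np.ndarray,
    ref_ipe: np.ndarray,
    mode: str = "similarity",
) -> AffineTransform:
    """Estimate the affine transform mapping the ipe frame onto the ipa frame.

    Intensity-based: normalized cross-correlation is maximized over
    translation + rotation + isotropic scale (``mode='similarity'``) or
    translation only (``mode='translation'``), starting from the
    phase-correlation translation estimate. Degenerate (constant) inputs
    return the identity with a warning flag instead of raising.
    """
    ipa = np.asarray(ref_ipa, dtype=float)
    ipe = np.asarray(ref_ipe, dtype=float)
    if ipa.shape != ipe.shape:
        raise ValueError("reference images must share a shape")
    if np.ptp(ipa) == 0 or np.ptp(ipe) == 0:
        return AffineTransform(warning="degenerate (constant) reference image")

    shift, _, _ = phase_cross_correlation(ipa, ipe, upsample_factor=20)
    center = (np.asarray(ipa.shape, dtype=float) - 1) / 2.0

    def score(params: np.ndarray) -> float:
        ty, tx, theta, logs = params
        t = AffineTransform.from_similarity(
            rotation_deg=theta, scale=np.exp(logs), translation=(ty, tx), center=center
        )
        warped = t.warp(ipe)
        return -_ncc(_crop_margin(ipa), _crop_margin(warped))

    x0 = np.array([shift[0], shift[1], 0.0, 0.0])
    if mode == "translation":
        def score_t(p):
            return score(np.array([p[0], p[1], 0.0, 0.0]))

        res = optimize.minimize(score_t, x0[:2], method="Powell", options={"xtol": 1e-4})
        best = np.array([res.x[0], res.x[1], 0.0, 0.0])
    elif mode == "similarity":
        res = optimize.minimize(score, x0, method="Powell", options={"xtol": 1e-4})
        best = res.x
    else:
        raise ValueError(f"unknown registration mode {mode!r}")

    if not res.success and -res.fun <= _ncc(_crop_margin(ipa), _crop_margin(ipe)):
        return AffineTransform(warning="registration optimization failed")
    t = AffineTransform.from_similarity(
        rotation_deg=best[2],
        scale=np.exp(best[3]),
        translation=(best[0], best[1]),
        center=center,
    )
    # never return a transform that scores worse than doing nothing
    if -score(best) < _ncc(_crop_margin(ipa), _crop_margin(ipe)) - 1e-9:
        return AffineTransform(warning="registration did not improve similarity")
    return t


def apply_registration(
    pset: PolarizedImageSet, t: AffineTransform, reference_frame: int = 0
) -> PolarizedImageSet:
    """Warp every ipe frame with the same transform (bilinear, zero fill).

    ``reference_frame`` is recorded only as provenance of where the transform
    was estimated; the warp itself is frame-independent.
    """
    if not np.all(np.isfinite(t.matrix)) or not np.all(np.isfinite(t.offset)):
        raise ValueError("transform must be finite")
    if t.is_identity:
        return pset.replace(registration=t)
    ipe = np.stack([t.warp(frame) for frame in pset.ipe])
    return pset.replace(ipe=ipe, registration=t)


def compute_gfactor(
    fluorescein_ipa: np.ndarray,
    fluorescein_ipe: np.ndarray,
    floor_frac: float = 0.01,
) -> GFactorField:
    """Pixelwise G-factor Ipa/Ipe from a background-subtracted image of an
    isotropic dye (fluorescein in water).

    Pixels whose Ipe falls below ``floor_frac`` of the median Ipe are imputed
    with the median G of the valid pixels and flagged, to avoid division
    blow-ups at dark pixels.
    """
    ipa = np.asarray(fluorescein_ipa, dtype=float)
    ipe = np.asarray(fluorescein_ipe, dtype=float)
    if ipa.shape != ipe.shape:
        raise ValueError("fluorescein channel images must share a shape")
    floor = floor_frac * np.median(ipe)
    valid = ipe > max(floor, 0.0)
    if not valid.any():
        raise ValueError("entire Ipe reference image is below the dark-pixel floor")
    g = np.empty_like(ipa)
    g[valid] = ipa[valid] / ipe[valid]
    med = np.median(g[valid])
    g[~valid] = med
    if not np.all(g > 0):
        g[g <= 0] = med
    return GFactorField(g=g, flagged=~valid)


def compute_anisotropy(
    pset: PolarizedImageSet,
    g: GFactorField | float = 1.0,
    threshold: float = 0.0,
    smoothing_window: int = 1,
) -> AnisotropyMap:
    """Per-pixel anisotropy map r = (Ipa - g Ipe) / (Ipa + 2 g Ipe).

    Pixels with total intensity Ipa + 2 g Ipe <= ``threshold`` are masked
    (NaN). ``smoothing_window`` (odd; 3 or 5 for presentation maps) applies a
    2-D averaging filter to the returned ``r`` for rendering only — ``r_raw``
    stays unsmoothed and is what quantification should use.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    gf = g if isinstance(g, GFactorField) else GFactorField(g=g)
    ipe_c = gf.correct(pset.ipe)
    total = pset.ipa + 2.0 * ipe_c
    mask = total > threshold
    if not mask.any():
        warnings.warn("intensity threshold leaves an empty mask", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_raw = np.where(mask, (pset.ipa - ipe_c) / total, np.nan)
    if smoothing_window > 1:
        r = np.empty_like(r_raw)
        for k in range(r_raw.shape[0]):
            filled = np.where(mask[k], r_raw[k], 0.0)
            num = ndimage.uniform_filter(filled, smoothing_window)
            den = ndimage.uniform_filter(mask[k].astype(float), smoothing_window)
            with np.errstate(invalid="ignore"):
                r[k] = np.where(mask[k], num / den, np.nan)
    else:
        r = r_raw.copy()
    return AnisotropyMap(
        r=r, r_raw=r_raw, total_intensity=total, mask=mask, smoothing_window=smoothing_window
    )


def anisotropy_from_sums(ipa_sum: float, ipe_corr_sum: float) -> float:
    """Photon-weighted anisotropy from summed channel intensities."""
    total = ipa_sum + 2.0 * ipe_corr_sum
    if total <= 0:
        return np.nan
    return (ipa_sum - ipe_corr_sum) / total


def roi_anisotropy(
    pset: PolarizedImageSet,
    g: GFactorField | float,
    regions: Sequence[Region],
    frame: int = 0,
    pixel_mean: bool = False,
) -> pd.DataFrame:
    """Per-region anisotropy statistics from a single frame.

    The region anisotropy is computed from the region's summed Ipa and summed
    G-corrected Ipe (photon-weighted), not the mean of pixel anisotropies;
    set ``pixel_mean=True`` for the pixel-averaged alternative (sensitivity
    analysis only). ``sd_r`` is always the SD of pixel anisotropies within the
    region. Empty regions are rejected individually and logged; the rest are
    kept.

    Returns a DataFrame with columns label, mean_r, sd_r, total_intensity,
    n_pixels.
    """
    gf = g if isinstance(g, GFactorField) else GFactorField(g=g)
    ipa = pset.ipa[frame]
    ipe_c = gf.correct(pset.ipe[frame])
    total = ipa + 2.0 * ipe_c
    with np.errstate(divide="ignore", invalid="ignore"):
        r_pix = np.where(total > 0, (ipa - ipe_c) / total, np.nan)

    rows = []
    for i, reg in enumerate(regions):
        mask = reg.to_mask(ipa.shape)
        n = int(mask.sum())
        if n == 0:
            logger.warning("region %s (%d) is empty; skipped", reg.label, i)
            continue
        ipa_sum = float(ipa[mask].sum())
        ipe_sum = float(ipe_c[mask].sum())
        vals = r_pix[mask]
        vals = vals[np.isfinite(vals)]
        mean_r = (
            float(np.mean(vals)) if pixel_mean else anisotropy_from_sums(ipa_sum, ipe_sum)
        )
        rows.append(
            dict(
                label=reg.label or f"roi_{i}",
                mean_r=mean_r,
                sd_r=float(np.std(vals)) if vals.size else np.nan,
                total_intensity=ipa_sum + 2.0 * ipe_sum,
                n_pixels=n,
            )
        )
    df = pd.DataFrame(rows, columns=["label", "mean_r", "sd_r", "total_intensity", "n_pixels"])
    df.attrs["intensity_units"] = "summed Ipa + 2 g Ipe over region"
    return df


def bin_by_intensity(
    stats: pd.DataFrame, bins: int | Sequence[float] = 5
) -> pd.DataFrame:
    """Bin ROI anisotropies by total intensity (Ipa + 2 Ipe).

    ``bins`` is either a bin count (equal-width edges spanning the data) or an
    explicit ascending edge array. A value on a shared right edge goes to the
    lower bin; the final bin is closed on the right. Empty bins report count 0
    and NaN mean.
    """
    if len(stats) < 1:
        raise ValueError("at least one ROI is required")
    x = stats["total_intensity"].to_numpy(dtype=float)
    r = stats["mean_r"].to_numpy(dtype=float)
    if np.isscalar(bins):
        lo, hi = x.min(), x.max()
        if lo == hi:  # all ROIs identical intensity: single degenerate bin
            edges = np.array([lo, hi + 1e-12])
        else:
            edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly ascending")
    idx = np.digitize(x, edges, right=True)
    idx[(idx == 0) & (x == edges[0])] = 1
    rows = []
    for b in range(1, len(edges)):
        sel = idx == b
        rows.append(
            dict(
                bin_left=edges[b - 1],
                bin_right=edges[b],
                bin_center=0.5 * (edges[b - 1] + edges[b]),
                mean_r=float(np.mean(r[sel])) if sel.any() else np.nan,
                sd_r=float(np.std(r[sel])) if sel.any() else np.nan,
                count=int(sel.sum()),
            )
        )
    return pd.DataFrame(rows)
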