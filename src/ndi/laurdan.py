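"""Laurdan generalized-polarization (GP) membrane-order mapping.

Laurdan's emission red-shifts by ~50 nm in disordered, polar lipid
environments. Ratiometric imaging in an ordered-phase channel Ch1 (435/40 nm)
and a disordered-phase channel Ch2 (504/37 nm) quantifies lipid order as

    GP = (I_Ch1 - G * I_Ch2) / (I_Ch1 + G * I_Ch2)

The instrument factor G is calibrated against a Laurdan-in-DMSO reference of
conventional GP_ref = 0.207:

    G = (GP_ref + GP_ref*GP_mes - GP_mes - 1) / (GP_mes + GP_ref*GP_mes - GP_ref - 1)

where GP_mes is the reference GP measured at G = 1. Applying the calibrated
G to the same reference returns GP_ref exactly (closed-form inverse).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ndi.polarimetry import Region

logger = logging.getLogger(__name__)

GP_REF_DMSO = 0.207  # conventional Laurdan-in-DMSO reference GP


@dataclass
class GPCalibration:
    gp_ref: float
    gp_mes: float
    gfactor: float

    def __post_init__(self) -> None:
        if not (-1 < self.gp_ref < 1 and -1 < self.gp_mes < 1):
            raise ValueError("GP values must lie in (-1, 1)")
        if not np.isfinite(self.gfactor) or self.gfactor <= 0:
            raise ValueError("G-factor must be finite and positive")


@dataclass
class GPMap:
    gp: np.ndarray  # NaN where masked
    ch1: np.ndarray
    ch2: np.ndarray
    mask: np.ndarray
    gfactor: float = 1.0


def calibrate_gfactor(gp_mes: float, gp_ref: float = GP_REF_DMSO) -> GPCalibration:
    """Derive the channel G-factor from the measured reference GP."""
    if not (-1 < gp_mes < 1 and -1 < gp_ref < 1):
        raise ValueError("GP values must lie in (-1, 1)")
    denom = gp_mes + gp_ref * gp_mes - gp_ref - 1
    if abs(denom) < 1e-12:
        raise ValueError("degenerate calibration: denominator ~ 0")
    g = (gp_ref + gp_ref * gp_mes - gp_mes - 1) / denom
    return GPCalibration(gp_ref=gp_ref, gp_mes=gp_mes, gfactor=g)


def measure_reference_gp(ch1: np.ndarray, ch2: np.ndarray) -> float:
    """Intensity-weighted GP of a reference image at G = 1.

    Equivalent to the GP of the summed channel intensities, which weights
    each pixel's GP by its total brightness.
    """
    s1 = float(np.sum(ch1))
    s2 = float(np.sum(ch2))
    if s1 + s2 <= 0:
        raise ValueError("reference image has no signal")
    return (s1 - s2) / (s1 + s2)


def compute_gp(
    ch1: np.ndarray,
    ch2: np.ndarray,
    cal: GPCalibration | float = 1.0,
    threshold: float = 0.0,
) -> GPMap:
    """Per-pixel GP map; pixels with I_Ch1 + G I_Ch2 <= threshold are NaN."""
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel images must share a shape")
    g = cal.gfactor if isinstance(cal, GPCalibration) else float(cal)
    denom = a + g * b
    mask = denom > threshold
    if not mask.any():
        warnings.warn("GP threshold leaves an empty mask", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        gp = np.where(mask, (a - g * b) / denom, np.nan)
    return GPMap(gp=gp, ch1=a, ch2=b, mask=mask, gfactor=g)


def roi_gp(
    ch1: np.ndarray,
    ch2: np.ndarray,
    cal: GPCalibration | float,
    regions: Sequence[Region],
) -> pd.DataFrame:
    """Per-region GP from summed channel intensities (photon-weighted).

    Columns: label, mean_gp, sd_gp (SD of pixel GPs), total_intensity,
    n_pixels. Empty regions are rejected individually and logged.
    """
    gmap = compute_gp(ch1, ch2, cal)
    g = gmap.gfactor
    rows = []
    for i, reg in enumerate(regions):
        mask = reg.to_mask(gmap.ch1.shape)
        n = int(mask.sum())
        if n == 0:
            logger.warning("region %s (%d) is empty; skipped", reg.label, i)
            continue
        s1 = float(gmap.ch1[mask].sum())
        s2 = float(gmap.ch2[mask].sum())
        denom = s1 + g * s2
        vals = gmap.gp[mask]
        vals = vals[np.isfinite(vals)]
        rows.append(
            dict(
                label=reg.label or f"roi_{i}",
                mean_gp=(s1 - g * s2) / denom if denom > 0 else np.nan,
                sd_gp=float(np.std(vals)) if vals.size else np.nan,
                total_intensity=denom,
                n_pixels=n,
            )
        )
    return pd.DataFrame(rows, columns=["label", "mean_gp", "sd_gp", "total_intensity", "n_pixels"])
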