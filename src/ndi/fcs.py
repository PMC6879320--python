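"""Fluorescence correlation spectroscopy: correlator, model and fitting.

The fitted model is a triplet-blinking term multiplying a two-component
diffusion term,

    G(tau) = (1/N) * G_T(tau) * G_D(tau)
    G_T(tau) = 1 + (T/(1-T)) * exp(-tau/tau_T)
    G_D(tau) = f * (1+tau/tau_D1)^-1 * (1+tau/(S^2 tau_D1))^-1/2
             + (1-f) * (1+tau/tau_D2)^-1

with N the mean number of moving particles in the confocal volume, T the
dark-state fraction, tau_T its lifetime, f the fraction of the fast,
three-dimensionally diffusing pool (free probe near the membrane, tau_D1 on
the 0.3-3 ms scale), 1-f the slow two-dimensional pool (probe bound to actin
filaments, tau_D2 on the 10-200 ms scale), and S the structure factor (axial
to lateral extent of the detection volume). Free fits converge S to about
0.2, so it is fixed there by default to constrain the parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
from scipy.ndimage import uniform_filter1d

DEFAULT_S = 0.2

#: default fit bounds keep the component identities (fast 3-D free pool vs
#: slow 2-D actin-bound pool) on their characteristic timescale windows
DEFAULT_BOUNDS = {
    "n": (1e-3, 1e6),
    "t_dark": (0.0, 0.8),
    "tau_t": (1e-6, 1e-3),
    "f_fast": (0.0, 1.0),
    "tau_d1": (0.3e-3, 3e-3),
    "tau_d2": (10e-3, 200e-3),
    "s": (0.02, 2.0),
}


@dataclass
class IntensityTrace:
    """Photon counts (or intensity) sampled at a fixed dwell time."""

    counts: np.ndarray
    dwell: float  # s per sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float).ravel()
        if self.counts.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.dwell <= 0:
            raise ValueError("dwell time must be > 0")

    @property
    def duration(self) -> float:
        return self.counts.size * self.dwell

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.counts.size) * self.dwell


@dataclass
class ACFCurve:
    """Autocorrelation G(tau) on a positive, strictly increasing lag grid."""

    lags: np.ndarray
    g: np.ndarray
    sd: np.ndarray | None = None
    zero_variance: bool = False

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape:
            raise ValueError("lags and g must match")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


@dataclass
class FCSParams:
    """Parameters of the triplet x two-component diffusion model."""

    n: float
    t_dark: float = 0.0
    tau_t: float = 50e-6
    f_fast: float = 1.0
    tau_d1: float = 1e-3
    tau_d2: float = 50e-3
    s: float = DEFAULT_S

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("N must be > 0")
        if not 0 <= self.t_dark < 1:
            raise ValueError("dark-state fraction must lie in [0, 1)")
        if self.tau_t <= 0 or self.tau_d1 <= 0 or self.tau_d2 <= 0 or self.s <= 0:
            raise ValueError("timescales and structure factor must be > 0")
        if not 0 <= self.f_fast <= 1:
            raise ValueError("fast fraction must lie in [0, 1]")
        if self.tau_d1 >= self.tau_d2:
            raise ValueError("ordering convention requires tau_d1 < tau_d2")

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("n", "t_dark", "tau_t", "f_fast", "tau_d1", "tau_d2", "s")
        }


@dataclass
class FCSFit:
    """Fit result: best parameters, uncertainties and diagnostics."""

    params: FCSParams
    stderr: dict[str, float | None] = field(default_factory=dict)
    rss: float = np.nan
    fixed: tuple[str, ...] = ()
    success: bool = False
    swapped: bool = False
    message: str = ""


def model_eval(p: FCSParams, lags: np.ndarray | Sequence[float]) -> np.ndarray:
    """Evaluate G(tau) at the given lags."""
    tau = np.asarray(lags, dtype=float)
    return _model(
        tau, p.n, p.t_dark, p.tau_t, p.f_fast, p.tau_d1, p.tau_d2, p.s
    )


def _model(tau, n, t_dark, tau_t, f_fast, tau_d1, tau_d2, s):
    g_t = 1.0 + (t_dark / (1.0 - t_dark)) * np.exp(-tau / tau_t)
    g_d = f_fast * (1.0 + tau / tau_d1) ** -1 * (1.0 + tau / (s**2 * tau_d1)) ** -0.5
    g_d = g_d + (1.0 - f_fast) * (1.0 + tau / tau_d2) ** -1
    return (1.0 / n) * g_t * g_d


def multi_tau_lags(dwell: float, max_lag: float, lags_per_octave: int = 16) -> list[tuple[int, int]]:
    """Lag schedule of a multi-tau correlator: (lag in samples, binning level).

    Level 0 covers lags 1..2m at the base dwell; each further level halves the
    sampling rate and covers lags m+1..2m of the binned trace.
    """
    m = lags_per_octave
    sched = [(k, 0) for k in range(1, 2 * m + 1)]
    level = 1
    while True:
        step = 2**level
        added = False
        for k in range(m + 1, 2 * m + 1):
            if k * step * dwell <= max_lag:
                sched.append((k, level))
                added = True
        if not added:
            break
        level += 1
    return sched


def autocorrelate(
    trace: IntensityTrace, lags_per_octave: int = 16, max_lag: float | None = None
) -> ACFCurve:
    """Normalized intensity autocorrelation on a multi-tau (quasi-log) grid.

    G(tau) = <dI(t) dI(t+tau)> / <I>^2 with dI = I - <I>, estimated per
    binning level; lags span one dwell up to duration/10 by default. A
    zero-variance trace returns an all-zero curve with a flag.
    """
    x = trace.counts
    mean = x.mean()
    if mean <= 0:
        raise ValueError("trace mean intensity must be > 0")
    if max_lag is None:
        max_lag = trace.duration / 10.0
    if np.ptp(x) == 0:
        sched = multi_tau_lags(trace.dwell, max_lag, lags_per_octave)
        lags = np.array(sorted({k * 2**lv for k, lv in sched})) * trace.dwell
        return ACFCurve(lags=lags, g=np.zeros_like(lags), zero_variance=True)

    levels = {0: x}
    sched = multi_tau_lags(trace.dwell, max_lag, lags_per_octave)
    out: dict[float, float] = {}
    for k, lv in sched:
        if lv not in levels:
            prev = levels[lv - 1]
            n2 = prev.size // 2
            levels[lv] = prev[: 2 * n2].reshape(n2, 2).mean(axis=1)
        y = levels[lv]
        if k >= y.size:
            continue
        d = y - y.mean()
        num = float(np.dot(d[:-k], d[k:]) / (y.size - k))
        tau = k * 2**lv * trace.dwell
        out[tau] = num / mean**2
    lags = np.array(sorted(out))
    return ACFCurve(lags=lags, g=np.array([out[t] for t in lags]))


def average_curves(curves: Sequence[ACFCurve]) -> ACFCurve:
    """Average repeat curves sharing a lag grid; per-lag SD is attached."""
    lags = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags):
            raise ValueError("curves must share a lag grid to be averaged")
    gs = np.vstack([c.g for c in curves])
    return ACFCurve(lags=lags, g=gs.mean(axis=0), sd=gs.std(axis=0, ddof=1) if len(curves) > 1 else None)


def qc_trace(
    trace: IntensityTrace,
    drift_frac: float = 0.1,
    burst_k: float = 5.0,
    burst_window: float = 0.1,
) -> tuple[bool, list[str]]:
    """Pass/fail screening for drift and sporadic intense bursts.

    Fails when the fitted linear trend changes the intensity by more than
    ``drift_frac`` of the mean over the trace duration, or when any rolling
    mean (window ``burst_window`` seconds) exceeds mean + ``burst_k`` * SD.
    """
    x = trace.counts
    t = trace.times
    reasons: list[str] = []
    mean = x.mean()
    sd = x.std()
    slope = np.polyfit(t, x, 1)[0] if sd > 0 else 0.0
    if abs(slope) * trace.duration > drift_frac * mean:
        reasons.append("drift")
    w = max(1, int(round(burst_window / trace.dwell)))
    if sd > 0 and w < x.size:
        rolling = uniform_filter1d(x, size=w, mode="nearest")
        if np.any(rolling > mean + burst_k * sd):
            reasons.append("burst")
    return (len(reasons) == 0, reasons)


def _auto_init(curve: ACFCurve) -> FCSParams:
    g0 = max(float(curve.g[0]), 1e-6)
    return FCSParams(
        n=1.0 / g0,
        t_dark=0.1,
        tau_t=50e-6,
        f_fast=0.5,
        tau_d1=1e-3,
        tau_d2=45e-3,
        s=DEFAULT_S,
    )


def fit_acf(
    curve: ACFCurve,
    fixed: Sequence[str] = ("s",),
    init: FCSParams | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    lag_range: tuple[float, float] = (5e-6, 2.0),
) -> FCSFit:
    """Weighted least-squares fit of the FCS model to an autocorrelation curve.

    ``fixed`` names parameters held at their init values (the structure
    factor S by default). Weights are inverse per-lag SD when the curve
    carries repeat SDs, otherwise unweighted (the quasi-log lag grid already
    balances timescales). The component ordering tau_d1 < tau_d2 is enforced
    post-fit by swapping if the bounds were relaxed enough to allow crossing.
    Non-convergence is flagged and the best iterate returned.
    """
    sel = (curve.lags >= lag_range[0]) & (curve.lags <= lag_range[1])
    lags = curve.lags[sel]
    g = curve.g[sel]
    p0 = init or _auto_init(curve)
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    n_free = 7 - len(set(fixed))
    if lags.size < n_free + 2:
        raise ValueError("not enough lag points for the number of free parameters")

    params = lmfit.Parameters()
    for name, value in p0.as_dict().items():
        lo, hi = bnds[name]
        params.add(name, value=float(np.clip(value, lo, hi)), min=lo, max=hi,
                   vary=name not in fixed)

    weights = None
    if curve.sd is not None:
        sd = curve.sd[sel]
        weights = 1.0 / np.where(sd > 0, sd, np.nanmax(sd[sd > 0]) if (sd > 0).any() else 1.0)

    def residual(pars):
        v = pars.valuesdict()
        res = _model(lags, v["n"], v["t_dark"], v["tau_t"], v["f_fast"],
                     v["tau_d1"], v["tau_d2"], v["s"]) - g
        return res * weights if weights is not None else res

    result = lmfit.minimize(residual, params, method="leastsq")
    v = result.params.valuesdict()
    stderr = {k: result.params[k].stderr for k in v}
    swapped = False
    if v["tau_d1"] >= v["tau_d2"]:
        v["tau_d1"], v["tau_d2"] = v["tau_d2"], v["tau_d1"]
        stderr["tau_d1"], stderr["tau_d2"] = stderr["tau_d2"], stderr["tau_d1"]
        v["f_fast"] = 1.0 - v["f_fast"]
        swapped = True
        v["tau_d1"] = min(v["tau_d1"], v["tau_d2"] * (1 - 1e-9))
    fitted = FCSParams(**v)
    return FCSFit(
        params=fitted,
        stderr=stderr,
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        fixed=tuple(fixed),
        success=bool(result.success),
        swapped=swapped,
        message=result.message,
    )
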