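"""Cap dynamics readouts: trace alignment/normalization, rolling expansion
rate, phase classification, exponential growth fitting, fold changes.

Traces are aligned to the first elongation frame (when centrosomes separate)
and then tracked back a fixed lookback (180 s by default) to cap initiation;
the area and intensity-SD series are normalized to their values at that
initiation point, so normalized area and heterogeneity both start at 1.

Phase labels are assigned by explicit, configurable rules standing in for the
by-eye calls of the original workflow:

* expansion — initial run with normalized expansion rate > theta_grow;
* stabilization — the subsequent run with |rate| <= theta_stab;
* elongation — at the supplied anchor, or when the smoothed eccentricity
  exceeds theta_ecc for >= 3 consecutive points;
* fragmentation — when the area declines for >= 3 consecutive steps and the
  normalized heterogeneity falls below theta_het of its running maximum
  (heterogeneity drops by roughly a quarter of its maximum as caps break up).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .errors import (AlignmentError, ClassificationError, FitError,
                     NormalizationError, ParameterError)
from .segmentation import CapTrack

__all__ = [
    "AlignedTrace", "PhaseAnnotation", "GrowthFit",
    "align_and_normalize", "rolling_expansion_rate", "classify_phases",
    "fit_growth_curve", "fit_expansion_exponential", "fold_change",
]


@dataclass
class AlignedTrace:
    """A cap's time series, aligned so that t = 0 is cap initiation."""

    cap_id: int
    time_s: np.ndarray
    area_um2: np.ndarray
    norm_area: np.ndarray
    mean_int: np.ndarray
    sd_int: np.ndarray
    norm_het: np.ndarray
    ecc: np.ndarray
    frame_interval_s: float
    anchor_time_s: float | None = None  # elongation onset on the aligned axis

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.time_s) > 0):
            raise ParameterError("trace time points must strictly increase")


@dataclass(frozen=True)
class PhaseAnnotation:
    """Per-point phase labels plus phase-start times (canonical order)."""

    labels: np.ndarray              # one of the four phase names per point
    boundaries: dict[str, float]    # phase -> start time (s); only present phases

    @property
    def phases_present(self) -> list[str]:
        return list(self.boundaries)


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth fit Y = a * exp(k * X)."""

    amplitude: float
    rate: float
    r_value: float       # Pearson r between observed and fitted values
    r_squared: float
    x_unit: str          # "frame" or "s"
    rss: float
    n_points: int

    def to_dict(self) -> dict:
        return {"amplitude": self.amplitude, "rate": self.rate,
                "r_value": self.r_value, "r_squared": self.r_squared,
                "x_unit": self.x_unit, "rss": self.rss, "n_points": self.n_points}


def _track_frame(track) -> pd.DataFrame:
    if isinstance(track, CapTrack):
        return track.data
    return track


def align_and_normalize(track, elongation_onset: int, *, frame_interval_s: float,
                        lookback_s: float = 180.0, cap_id: int | None = None
                        ) -> AlignedTrace:
    """Align a track to (elongation onset - lookback) and normalize.

    t = 0 is placed ``lookback_s`` before the elongation-onset frame (cap
    initiation); the area series is divided by the area there and the
    intensity-SD series by the SD there. Frames before t = 0 are dropped.
    """
    df = _track_frame(track).sort_values("frame").reset_index(drop=True)
    frames = df["frame"].to_numpy(int)
    lookback_frames = int(round(lookback_s / frame_interval_s))
    t0_frame = elongation_onset - lookback_frames
    if t0_frame < frames.min() or elongation_onset > frames.max():
        raise AlignmentError(
            f"track spans frames [{frames.min()}, {frames.max()}]; cannot align "
            f"to onset {elongation_onset} with {lookback_s} s lookback")
    if t0_frame not in frames:
        raise AlignmentError(f"anchor frame {t0_frame} missing from the track")
    sel = df[frames >= t0_frame].reset_index(drop=True)
    i0 = int(np.flatnonzero(sel["frame"].to_numpy(int) == t0_frame)[0])
    area = sel["area_um2"].to_numpy(float)
    sd = sel["sd_int"].to_numpy(float)
    if area[i0] <= 0:
        raise NormalizationError("area at t = 0 is zero; cannot normalize")
    if sd[i0] <= 0:
        raise NormalizationError("intensity SD at t = 0 is zero; cannot normalize")
    time_s = (sel["frame"].to_numpy(int) - t0_frame) * frame_interval_s
    if cap_id is None:
        cap_id = int(getattr(track, "track_id", sel.get("cap_id", pd.Series([0])).iloc[0]))
    return AlignedTrace(
        cap_id=cap_id,
        time_s=time_s.astype(float),
        area_um2=area,
        norm_area=area / area[i0],
        mean_int=sel["mean_int"].to_numpy(float),
        sd_int=sd,
        norm_het=sd / sd[i0],
        ecc=sel["ecc"].to_numpy(float) if "ecc" in sel else np.zeros(len(sel)),
        frame_interval_s=frame_interval_s,
        anchor_time_s=(elongation_onset - t0_frame) * frame_interval_s,
    )


def _window_slopes(t: np.ndarray, y: np.ndarray, window_s: float) -> np.ndarray:
    half = window_s / 2.0 + 1e-9
    out = np.empty_like(y, dtype=float)
    for i in range(len(t)):
        m = np.abs(t - t[i]) <= half
        if m.sum() < 2:
            # shrink to the nearest two samples
            m = np.zeros_like(m)
            lo = max(i - 1, 0)
            hi = min(i + 1, len(t) - 1)
            m[lo:hi + 1] = True
        tt, yy = t[m], y[m]
        tbar = tt.mean()
        out[i] = float(((tt - tbar) * (yy - yy.mean())).sum()
                       / ((tt - tbar) ** 2).sum())
    return out


def rolling_expansion_rate(trace: AlignedTrace, *, window_s: float = 30.0
                           ) -> pd.DataFrame:
    """Rolling-window least-squares expansion rate.

    Per time point, the slope of area vs. time over the centered window
    (shrunk at the trace edges), emitted in absolute (um^2/s) and normalized
    (1/s) units.
    """
    dt = float(np.min(np.diff(trace.time_s)))
    if window_s < 2 * dt:
        raise ParameterError(
            f"window {window_s} s spans fewer than 2 samples at {dt} s intervals")
    return pd.DataFrame({
        "time_s": trace.time_s,
        "rate_um2_s": _window_slopes(trace.time_s, trace.area_um2, window_s),
        "rate_norm_s": _window_slopes(trace.time_s, trace.norm_area, window_s),
    })


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average with shrinking edges."""
    out = np.empty_like(y, dtype=float)
    for i in range(len(y)):
        out[i] = y[max(0, i - 1): i + 2].mean()
    return out


def classify_phases(trace: AlignedTrace, *, theta_grow: float = 0.01,
                    theta_stab: float = 0.005, theta_ecc: float = 0.6,
                    theta_het: float = 0.75, window_s: float = 30.0,
                    use_anchor: bool = True) -> PhaseAnnotation:
    """Assign one of the four canonical phases to every time point."""
    n = len(trace.time_s)
    if n < 4:
        raise ParameterError("trace too short to classify (need >= 4 points)")
    rate = rolling_expansion_rate(trace, window_s=window_s)["rate_norm_s"].to_numpy()

    # expansion: initial run with rate above theta_grow
    i_stab = n
    for i in range(n):
        if rate[i] <= theta_grow:
            i_stab = i
            break
    if i_stab == 0:
        i_stab = 0  # no expansion phase detected; trace starts stabilized

    # elongation: anchored, or sustained eccentricity above threshold
    i_el = n
    if use_anchor and trace.anchor_time_s is not None:
        hits = np.flatnonzero(np.isclose(trace.time_s, trace.anchor_time_s))
        i_el = int(hits[0]) if hits.size else int(
            np.argmin(np.abs(trace.time_s - trace.anchor_time_s)))
    else:
        ecc_s = _smooth3(trace.ecc)
        run = 0
        for i in range(max(i_stab, 0), n):
            run = run + 1 if ecc_s[i] > theta_ecc else 0
            if run >= 3:
                i_el = i - 2
                break

    # fragmentation: sustained area decline plus heterogeneity collapse
    i_frag = n
    run_max = np.maximum.accumulate(trace.norm_het)
    d_area = np.diff(trace.area_um2)
    scan_from = i_el if i_el < n else i_stab
    for i in range(scan_from, n - 3):
        if np.all(d_area[i:i + 3] < 0) and trace.norm_het[i] < theta_het * run_max[i]:
            i_frag = i
            break

    bounds = [("expansion", 0), ("stabilization", i_stab),
              ("elongation", i_el), ("fragmentation", i_frag)]
    bounds = [(name, idx) for name, idx in bounds if idx < n]
    idxs = [idx for _, idx in bounds]
    if any(b < a for a, b in zip(idxs, idxs[1:])):
        raise ClassificationError(
            f"phase boundaries out of canonical order: "
            f"{ {name: trace.time_s[idx] for name, idx in bounds} }")

    labels = np.empty(n, dtype=object)
    for k, (name, idx) in enumerate(bounds):
        end = bounds[k + 1][1] if k + 1 < len(bounds) else n
        labels[idx:end] = name
    if bounds and bounds[0][1] > 0:  # points before the first boundary
        labels[:bounds[0][1]] = bounds[0][0]
    return PhaseAnnotation(labels=labels,
                           boundaries={name: float(trace.time_s[idx])
                                       for name, idx in bounds})


def fit_growth_curve(x, y, *, x_unit: str = "frame") -> GrowthFit:
    """Nonlinear least squares of Y = a * exp(k * X).

    The start is taken from a log-linear regression (with a small multi-start
    fallback over k); R is the Pearson correlation between observed and
    fitted values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ParameterError("need >= 4 points for the growth fit")
    if np.any(y <= 0):
        raise ParameterError("growth fit requires positive Y values")

    model = lambda xx, a, k: a * np.exp(k * xx)
    # log-linear start
    coef = np.polyfit(x, np.log(y), 1)
    starts = [(math.exp(coef[1]), coef[0])]
    starts += [(max(y[0], 1e-6), k0) for k0 in (-0.1, 0.0, 0.1, 0.5)]
    best = None
    for a0, k0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # flat k on constant data
                popt, _ = curve_fit(model, x, y, p0=(a0, k0), maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitError("exponential growth fit failed to converge from every start")
    (a, k), rss = best
    fitted = model(x, a, k)
    if np.ptp(fitted) < 1e-14 or np.ptp(y) < 1e-14:
        r = 1.0 if rss < 1e-20 else 0.0
    else:
        r = float(pearsonr(y, fitted).statistic)
    return GrowthFit(amplitude=float(a), rate=float(k), r_value=r,
                     r_squared=r * r, x_unit=x_unit, rss=rss, n_points=len(x))


def fit_expansion_exponential(trace: AlignedTrace, *, span_s: float = 60.0,
                              x_unit: str = "frame") -> GrowthFit:
    """Fit the exponential to the first ``span_s`` seconds of the trace.

    X is expressed in frames of ``frame_interval_s`` by default (matching the
    reported k being per 5 s frame over the 0-60 s window), or in seconds
    with ``x_unit="s"``.
    """
    if x_unit not in ("frame", "s"):
        raise ParameterError("x_unit must be 'frame' or 's'")
    m = trace.time_s <= span_s + 1e-9
    x = trace.time_s[m]
    if x_unit == "frame":
        x = x / trace.frame_interval_s
    return fit_growth_curve(x, trace.norm_area[m], x_unit=x_unit)


def fold_change(trace: AlignedTrace, t_start: float, t_end: float) -> float:
    """Area at t_end divided by area at t_start (nearest-sample lookup)."""
    t = trace.time_s
    half = trace.frame_interval_s / 2.0 + 1e-9
    for tt in (t_start, t_end):
        if tt < t[0] - half or tt > t[-1] + half:
            raise ParameterError(f"time {tt} s outside trace span [{t[0]}, {t[-1]}] s")
    a = trace.area_um2
    return float(a[np.argmin(np.abs(t - t_end))] / a[np.argmin(np.abs(t - t_start))])
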